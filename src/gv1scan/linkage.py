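"""Backcross linkage mapping with LOD scoring and peak interpolation.

In an N2 backcross every animal is heterozygous or homozygous at each locus,
so the recombination fraction between a marker and a fully penetrant binary
trait locus is directly countable: r_hat = R/N, where R is the number of
animals whose phenotype disagrees with the genotype-predicted phenotype and
N the number of informative animals.  Evidence for linkage is the LOD score

    LOD = (N - R) log10(2 (1 - r_hat)) + R log10(2 r_hat),

the log10 likelihood ratio of linkage at r_hat against free recombination
(r = 0.5).  The physical peak is placed by converting the trait-to-marker
recombination fractions at the two markers flanking the best marker into
genetic distances (Haldane's inverse map) and scaling the flanking physical
interval by their ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

HET = "H"  # heterozygous (carries the non-recurrent parental allele)
HOM = "B"  # homozygous for the recurrent parent
MISSING = "-"

# recombination fractions are capped below 0.5 before the inverse map,
# which diverges there; 0.499 corresponds to ~345 cM
_MAX_R_FOR_CM = 0.499


def haldane_cm_to_r(d_cm: float) -> float:
    """Haldane map function: genetic distance (cM) -> recombination fraction."""
    if d_cm < 0:
        raise ValueError("genetic distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def haldane_r_to_cm(r: float) -> float:
    """Inverse Haldane map: recombination fraction -> genetic distance (cM)."""
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    r = min(r, _MAX_R_FOR_CM)
    return -50.0 * math.log(1.0 - 2.0 * r)


@dataclass
class BackcrossDataset:
    """Markers, N2 genotypes and a binary phenotype.

    markers: DataFrame with columns ``name``, ``pos_mb`` and optionally
        ``pos_cm``, sorted by physical position.
    genotypes: (n_animals, n_markers) array of codes ``"H"``/``"B"``/``"-"``.
    phenotype: binary int array per animal (1 = trait-positive).
    """

    markers: pd.DataFrame
    genotypes: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype="U1")
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        if "name" not in self.markers or "pos_mb" not in self.markers:
            raise ValueError("markers need 'name' and 'pos_mb' columns")
        if not self.markers["pos_mb"].is_monotonic_increasing:
            raise ValueError("markers must be sorted by pos_mb")
        n_animals, n_markers = self.genotypes.shape
        if n_animals < 1:
            raise ValueError("need at least one animal")
        if n_markers != len(self.markers):
            raise ValueError("genotype columns do not match marker table")
        if len(self.phenotype) != n_animals:
            raise ValueError("phenotype length does not match animals")
        bad = ~np.isin(self.genotypes, [HET, HOM, MISSING])
        if bad.any():
            raise ValueError(
                f"invalid genotype codes: {sorted(set(self.genotypes[bad]))}"
            )
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    def marker_index(self, name: str) -> int:
        idx = self.markers.index[self.markers["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not in dataset")
        return int(idx[0])


@dataclass
class MarkerLinkage:
    """Linkage summary at one marker."""

    marker: str
    r_hat: float
    R: int
    N: int
    lod: float
    flag: Optional[str] = None  # e.g. "constant_phenotype"


@dataclass
class LinkageResult:
    """Genome-scan output: per-marker table plus the interpolated peak."""

    table: pd.DataFrame  # marker, pos_mb, r_hat, R, N, lod
    peak_mb: float

    @property
    def peak_marker(self) -> str:
        return str(self.table.loc[self.table["lod"].idxmax(), "marker"])


def lod_score(R: int, N: int) -> float:
    """Backcross LOD at r_hat = R/N versus r = 0.5.

    The 1/(2N) floor enters only the R-term, so perfect cosegregation
    (R = 0) gives exactly N log10(2).
    """
    if N == 0 or not 0 <= R <= N / 2:
        raise ValueError(f"invalid counts R={R}, N={N} (phase requires R <= N/2)")
    r_hat = R / N
    lod = (N - R) * math.log10(2.0 * (1.0 - r_hat))
    if R > 0:
        lod += R * math.log10(2.0 * max(r_hat, 1.0 / (2 * N)))
    return lod


def marker_linkage(data: BackcrossDataset, marker: str) -> MarkerLinkage:
    """Recombination fraction and LOD between a marker and the phenotype.

    Animals with a missing genotype at this marker are excluded.  Linkage
    phase is unknown, so the phase minimizing the recombinant count is
    chosen (r_hat <= 0.5 by construction).  A constant phenotype carries no
    linkage information and is reported as LOD 0 with a flag.
    """
    j = data.marker_index(marker)
    geno = data.genotypes[:, j]
    informative = geno != MISSING
    N = int(informative.sum())
    if N == 0:
        raise ValueError(f"marker {marker!r} has no informative animals")
    g = (geno[informative] == HET).astype(int)
    p = data.phenotype[informative]
    if p.min() == p.max():
        return MarkerLinkage(marker, 0.5, N // 2, N, 0.0, flag="constant_phenotype")
    mism = int(np.sum(g != p))
    R = min(mism, N - mism)
    r_hat = R / N
    return MarkerLinkage(marker, r_hat, R, N, lod_score(R, N))


def interpolate_peak(
    pos_a_mb: float, pos_b_mb: float, d_a_cm: float, d_b_cm: float
) -> float:
    """Place the linkage peak inside a flanking physical interval.

    The trait-to-flank genetic distances d_a and d_b are scaled to the
    physical interval: peak = pos_a + d_a / (d_a + d_b) * (pos_b - pos_a).
    The result always lies within [pos_a, pos_b].
    """
    if pos_a_mb >= pos_b_mb:
        raise ValueError("pos_a_mb must be < pos_b_mb")
    if d_a_cm < 0 or d_b_cm < 0:
        raise ValueError("genetic distances must be >= 0")
    total = d_a_cm + d_b_cm
    if total == 0:
        raise ValueError("both flanking distances are zero: peak undefined")
    return pos_a_mb + (d_a_cm / total) * (pos_b_mb - pos_a_mb)


def linkage_scan(data: BackcrossDataset) -> LinkageResult:
    """Per-marker linkage over the whole map plus the interpolated peak.

    The peak is placed between the two markers flanking the maximum-LOD
    marker by converting their trait recombination fractions to genetic
    distances (Haldane's inverse) and interpolating; a maximum at either end
    of the map reports that marker's own position.
    """
    if len(data.markers) < 2:
        raise ValueError("need at least two markers for a scan")
    rows = []
    for name, pos in zip(data.markers["name"], data.markers["pos_mb"]):
        ml = marker_linkage(data, name)
        rows.append(
            dict(marker=name, pos_mb=pos, r_hat=ml.r_hat, R=ml.R, N=ml.N, lod=ml.lod)
        )
    table = pd.DataFrame(rows)
    best = int(table["lod"].idxmax())
    if best == 0 or best == len(table) - 1:
        peak = float(table.loc[best, "pos_mb"])
    else:
        d_a = haldane_r_to_cm(float(table.loc[best - 1, "r_hat"]))
        d_b = haldane_r_to_cm(float(table.loc[best + 1, "r_hat"]))
        if d_a + d_b == 0:
            peak = float(table.loc[best, "pos_mb"])
        else:
            peak = interpolate_peak(
                float(table.loc[best - 1, "pos_mb"]),
                float(table.loc[best + 1, "pos_mb"]),
                d_a,
                d_b,
            )
    return LinkageResult(table=table, peak_mb=peak)
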