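"""Synthetic inputs with the statistical structure the pipeline assumes.

Every analysis stage can be exercised without external data: windowed depth
profiles with engineered copy-number segments on two lineage backgrounds, an
N2 backcross over a marker map with a single trait locus, acceptor contexts
in consensus and broken forms, dotplot segment sets with duplicated and
unique regions, clone sequences sharing engineered end-overlaps, and
two-group negative-binomial count matrices with subclass-specific fold
changes.  All generators are deterministic given a seed.

The defaults reproduce the study conditions: a ~4 Mb profiled region at
10 kb windows and ~100x window depth; an 1,108-animal backcross over nine
markers spanning 13:63.64-67.17 Mb with the trait at 13:66.58 Mb; an
~810 kb homozygous deletion (13:65.79-66.60 Mb) on two C57-lineage strains
extending to ~1.15 Mb on a third; an alternate chromosomal conformation
shared by non-C57-lineage strains; and three samples per group with
polytropic/xenotropic fold changes of 14.5 and 5.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from gv1scan.assembly import AlignmentSegment
from gv1scan.cnv import DepthProfile
from gv1scan.expression import ExpressionMatrix
from gv1scan.linkage import BackcrossDataset, haldane_cm_to_r
from gv1scan.splice import AcceptorSite, reverse_complement

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# depth profiles


@dataclass(frozen=True)
class StrainSpec:
    """Copy-number architecture of one simulated strain.

    cn_segments are (start_bp, end_bp, copy_number) on the shared region,
    non-overlapping and sorted; copy number is 2 outside listed segments.
    """

    name: str
    lineage: str  # e.g. "C57" or "nonC57"
    cn_segments: tuple = ()
    mean_depth: float = 100.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        prev_end = None
        for s, e, cn in self.cn_segments:
            if e <= s:
                raise ValueError(f"empty CN segment ({s}, {e}) in {self.name}")
            if cn < 0 or int(cn) != cn:
                raise ValueError(f"copy number must be a non-negative int, got {cn}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping CN segments in {self.name}")
            prev_end = e

    def copy_number(self, positions: np.ndarray) -> np.ndarray:
        """Copy number at each (window-start) position; default 2."""
        cn = np.full(len(positions), 2, dtype=float)
        for s, e, c in self.cn_segments:
            cn[(positions >= s) & (positions < e)] = c
        return cn


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings for depth-profile generation."""

    region: tuple[str, int, int]  # (chrom, start_bp, end_bp)
    window_bp: int = 10_000
    noise_model: str = "poisson"  # {"poisson", "negative_binomial", "none"}
    dispersion: float = 0.0  # NB variance = mu + dispersion * mu^2
    seed: int = 0

    def __post_init__(self) -> None:
        chrom, start, end = self.region
        if end <= start:
            raise ValueError("zero-width or inverted region")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.window_bp > end - start:
            raise ValueError("window larger than region")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def window_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Equal-width windows; a trailing partial window is dropped."""
        _, start, end = self.region
        n = (end - start) // self.window_bp
        starts = start + self.window_bp * np.arange(n, dtype=np.int64)
        return starts, starts + self.window_bp


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + dispersion*mu^2; dispersion 0 -> Poisson."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
    return out


def gen_depth_profiles(
    specs: Sequence[StrainSpec], cfg: SimConfig
) -> list[DepthProfile]:
    """Simulate per-window read counts for each strain on one window grid.

    The expected count of a window is mean_depth * CN/2.  Each profile's
    library size is fixed at its diploid expectation (mean_depth * number of
    windows), emulating genome-wide normalization: a strain's own CNVs then
    do not bias its depth ratios away from CN/2.
    """
    if len(specs) < 2:
        raise ValueError("need at least two strains (one being the reference)")
    if not any(len(s.cn_segments) == 0 for s in specs):
        raise ValueError("need one all-diploid reference strain")
    chrom = cfg.region[0]
    starts, ends = cfg.window_grid()
    rng = np.random.default_rng(cfg.seed)
    profiles = []
    for spec in specs:
        mu = spec.mean_depth * spec.copy_number(starts) / 2.0
        if cfg.noise_model == "none":
            counts = mu
        elif cfg.noise_model == "poisson":
            counts = rng.poisson(mu)
        else:
            counts = _nb_counts(rng, mu, cfg.dispersion)
        profiles.append(
            DepthProfile(
                strain=spec.name,
                chrom=chrom,
                starts=starts,
                ends=ends,
                counts=np.asarray(counts, dtype=float),
                library_size=spec.mean_depth * len(starts),
            )
        )
    return profiles


# Study-condition strain panel: a 4 Mb region around the candidate interval,
# C57-lineage strains diploid or carrying the engineered deletions, and
# non-C57-lineage strains sharing an alternate chromosomal conformation
# modeled as copy-number segments over most of the region (so a *median*
# distance between profiles separates the lineages).
PANEL_REGION = ("13", 63_500_000, 67_500_000)
DELETION_810KB = (65_790_000, 66_600_000)
DELETION_1150KB = (65_450_000, 66_600_000)
SHARED_CNV_REGION = (65_470_000, 66_960_000)

_ALT_CONFORMATION = (
    (63_500_000, 64_200_000, 1),
    (64_200_000, 64_900_000, 3),
    (65_000_000, 65_470_000, 1),
    (65_470_000, 66_960_000, 4),
    (67_000_000, 67_500_000, 3),
)


def default_strain_panel(mean_depth: float = 100.0) -> list[StrainSpec]:
    """The simulated strain panel: reference first, then C57 and non-C57."""
    c57 = [
        StrainSpec("B6J", "C57", (), mean_depth),  # reference
        StrainSpec("C57L", "C57", (), mean_depth),
        StrainSpec("B6N", "C57", ((*DELETION_810KB, 0),), mean_depth),
        StrainSpec("B10", "C57", ((*DELETION_810KB, 0),), mean_depth),
        StrainSpec("C57BR", "C57", ((*DELETION_1150KB, 0),), mean_depth),
    ]
    non_c57 = [
        StrainSpec(name, "nonC57", _ALT_CONFORMATION, mean_depth)
        for name in ("ZALENDE", "129", "AJ", "BALBc", "CBA")
    ]
    return c57 + non_c57


# ---------------------------------------------------------------------------
# backcross


def gen_backcross(
    markers: Sequence[tuple[str, float, float]],
    trait_pos_cm: float,
    n_animals: int,
    penetrance: float = 1.0,
    seed: int = 0,
) -> BackcrossDataset:
    """Simulate an N2 backcross with one trait locus.

    *markers* are (name, pos_Mb, pos_cM) sorted by cM.  Each animal inherits
    one F1 gamete simulated locus-by-locus along the map, with recombination
    probability between adjacent loci given by Haldane's map function
    (memoryless crossovers).  Genotypes are "H" (heterozygous) or "B"
    (homozygous for the recurrent parent); the phenotype equals the
    trait-locus genotype, mislabeled with probability 1 - penetrance
    symmetrically in both classes.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if not 0.5 < penetrance <= 1.0:
        raise ValueError("penetrance must be in (0.5, 1]")
    cms = [m[2] for m in markers]
    if any(b < a for a, b in zip(cms, cms[1:])):
        raise ValueError("markers must be sorted by cM position")

    # insert the trait locus into the genetic map
    loci = sorted(
        [(name, mb, cm, False) for name, mb, cm in markers]
        + [("__trait__", math.nan, trait_pos_cm, True)],
        key=lambda t: t[2],
    )
    n_loci = len(loci)
    rng = np.random.default_rng(seed)

    rs = np.array(
        [haldane_cm_to_r(loci[i + 1][2] - loci[i][2]) for i in range(n_loci - 1)]
    )
    alleles = np.zeros((n_animals, n_loci), dtype=np.int8)
    alleles[:, 0] = rng.integers(0, 2, size=n_animals)
    switch = rng.random((n_animals, n_loci - 1)) < rs
    for j in range(1, n_loci):
        alleles[:, j] = alleles[:, j - 1] ^ switch[:, j - 1]

    trait_idx = next(i for i, t in enumerate(loci) if t[3])
    pheno = alleles[:, trait_idx].astype(int)
    flip = rng.random(n_animals) < (1.0 - penetrance)
    pheno = pheno ^ flip.astype(int)

    marker_cols = [i for i in range(n_loci) if not loci[i][3]]
    geno = np.where(alleles[:, marker_cols] == 1, "H", "B").astype("U1")
    mtable = pd.DataFrame(
        {
            "name": [loci[i][0] for i in marker_cols],
            "pos_mb": [loci[i][1] for i in marker_cols],
            "pos_cm": [loci[i][2] for i in marker_cols],
        }
    ).sort_values("pos_mb", ignore_index=True)
    # genotype columns follow the cM order used in simulation; reorder to match
    order = np.argsort([loci[i][1] for i in marker_cols], kind="stable")
    geno = geno[:, order]
    return BackcrossDataset(markers=mtable, genotypes=geno, phenotype=pheno)


# nine markers over the flanked interval, ~0.5 cM/Mb; trait at 13:66.58 Mb
DEFAULT_MARKER_MB = (63.64, 64.08, 64.52, 64.96, 65.40, 65.84, 66.28, 66.72, 67.17)
DEFAULT_CM_PER_MB = 0.5
DEFAULT_TRAIT_MB = 66.58


def default_backcross_markers() -> list[tuple[str, float, float]]:
    return [
        (f"M{i + 1}", mb, mb * DEFAULT_CM_PER_MB)
        for i, mb in enumerate(DEFAULT_MARKER_MB)
    ]


def default_trait_pos_cm() -> float:
    return DEFAULT_TRAIT_MB * DEFAULT_CM_PER_MB


# ---------------------------------------------------------------------------
# acceptor sites


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def gen_acceptor_sequences(seed: int = 0, flank: int = 8) -> list[AcceptorSite]:
    """Acceptor contexts in consensus and broken forms, on both strands.

    Returns one consensus-passing site plus sites broken at each constrained
    consensus position (the pyrimidine, the invariant A and G, and the first
    exonic G), each embedded in random flanking sequence, with minus-strand
    copies of the consensus and one broken form.
    """
    rng = np.random.default_rng(seed)
    variants = [
        ("consensus", "TCAGG"),
        ("consensus_T", "ATAGG"),
        ("broken_pyrimidine", "TAAGG"),  # A at the pyrimidine position
        ("broken_branch_A", "TCCGG"),  # -2 A -> C
        ("broken_intronic_G", "TCAAG"),  # -1 G -> A
        ("broken_exonic_G", "TCAGA"),  # +1 exonic G -> A
    ]
    sites: list[AcceptorSite] = []
    for label, core in variants:
        left = _random_seq(rng, flank)
        right = _random_seq(rng, flank)
        seq = left + core + right
        sp = flank + 4
        sites.append(AcceptorSite(seq, sp, "+", label))
        if label in ("consensus", "broken_pyrimidine"):
            sites.append(
                AcceptorSite(
                    reverse_complement(seq), len(seq) - sp, "-", label + "_minus"
                )
            )
    return sites


# ---------------------------------------------------------------------------
# alignment segments


def _check_disjoint(intervals: Sequence[tuple[int, int]], what: str) -> None:
    ivs = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping {what} intervals ({s1},{e1}) and ({s2},{e2})")


def gen_alignment_segments(
    dup_regions: Sequence[tuple[int, int]],
    unique_regions: Sequence[tuple[int, int]],
    base_identity: float = 99.0,
    seed: int = 0,
    region: tuple[int, int] = (0, 2_000_000),
    piece_bp: int = 100_000,
    qname: str = "assembly",
    tname: str = "13",
) -> list[AlignmentSegment]:
    """A dotplot-like segment set with engineered duplications and gaps.

    The reference *region* is tiled by roughly *piece_bp* co-linear
    segments.  Each interval in *dup_regions* (reference axis) gains a
    second, overlapping segment from a distinct query location, so reference
    multiplicity is >= 2 there.  Each interval in *unique_regions* (query
    axis) is kept free of segments, modeling unique assembly sequence with
    no reference counterpart.  Identities are jittered around
    *base_identity*.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("inverted region")
    _check_disjoint(dup_regions, "dup")
    _check_disjoint(unique_regions, "unique")
    for s, e in dup_regions:
        if s < lo or e > hi:
            raise ValueError(f"dup region ({s},{e}) outside reference region")
    rng = np.random.default_rng(seed)

    gaps = sorted(unique_regions)  # reserved query-axis ranges
    segs: list[AlignmentSegment] = []

    t = lo
    q = 0
    gi = 0
    while t < hi:
        while gi < len(gaps) and q >= gaps[gi][0]:
            q = max(q, gaps[gi][1])
            gi += 1
        length = min(int(piece_bp * rng.uniform(0.7, 1.3)), hi - t)
        if gi < len(gaps):
            length = min(length, gaps[gi][0] - q)  # stop at the reserved range
        ident = float(np.clip(rng.normal(base_identity, 0.4), 90.0, 100.0))
        segs.append(
            AlignmentSegment(
                qname, q, q + length, tname, t, t + length, ident,
                "forward" if rng.random() < 0.8 else "reverse",
            )
        )
        t += length
        q += length

    total_q = q
    for s, e in gaps[gi:]:
        total_q = max(total_q, e)
    for s, e in dup_regions:
        # second copy mapped from extra query sequence appended past the end
        length = e - s
        ident = float(np.clip(rng.normal(base_identity, 0.4), 90.0, 100.0))
        segs.append(
            AlignmentSegment(
                qname, total_q, total_q + length, tname, s, e, ident,
                "reverse" if rng.random() < 0.5 else "forward",
            )
        )
        total_q += length
    return segs


# ---------------------------------------------------------------------------
# clone sequences with engineered overlaps


def gen_clone_sequences(
    component_sizes: Sequence[int],
    clone_bp: int = 20_000,
    overlap_bp: int = 5_000,
    seed: int = 0,
) -> tuple[dict[str, str], list[list[str]]]:
    """Clone sequences engineered into known overlap components.

    Each component is an independent random molecule sliced into clones that
    share exact *overlap_bp* end-overlaps with their neighbors; clones from
    different components share no overlap.  Returns (clones, components)
    where components lists the ground-truth clone grouping.
    """
    if any(k < 1 for k in component_sizes):
        raise ValueError("component sizes must be >= 1")
    if overlap_bp >= clone_bp:
        raise ValueError("overlap must be shorter than a clone")
    rng = np.random.default_rng(seed)
    clones: dict[str, str] = {}
    components: list[list[str]] = []
    idx = 0
    for k in component_sizes:
        mol_len = clone_bp + (k - 1) * (clone_bp - overlap_bp)
        mol = _random_seq(rng, mol_len)
        members = []
        for j in range(k):
            name = f"clone{idx:02d}"
            start = j * (clone_bp - overlap_bp)
            seq = mol[start : start + clone_bp]
            if j % 2 == 1:  # alternate orientations to exercise rc joins
                seq = reverse_complement(seq)
            clones[name] = seq
            members.append(name)
            idx += 1
        components.append(members)
    return clones, components


# ---------------------------------------------------------------------------
# expression counts


def gen_expression_counts(
    n_loci_per_class: Mapping[str, int],
    fold_changes: Mapping[str, float],
    n_per_group: int = 3,
    dispersion: float = 0.1,
    seed: int = 0,
    base_mean: float = 100.0,
    pbs_choices: Sequence[str] = ("Pro", "Gln1", "other"),
) -> ExpressionMatrix:
    """Two-group negative-binomial counts with subclass-specific folds.

    Group A loci have per-locus means drawn lognormally around *base_mean*;
    group B means are scaled by the subclass fold change.  Counts are
    negative binomial with variance mu + dispersion*mu^2 (Poisson at
    dispersion 0).  Each locus gets a random PBS annotation.  Library sizes
    are fixed at a shared constant: the simulated loci stand for a small
    slice of a transcriptome whose total is set by everything else, so a
    subclass's own upregulation must not deflate its CPM fold.
    """
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    for sub, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold for {sub} must be > 0")
    rng = np.random.default_rng(seed)
    ids, subs, pbs, rows = [], [], [], []
    for sub, n_loci in n_loci_per_class.items():
        fold = fold_changes.get(sub, 1.0)
        for i in range(n_loci):
            mu_a = base_mean * rng.lognormal(0.0, 0.5)
            mu_b = mu_a * fold
            a = _nb_counts(rng, np.full(n_per_group, mu_a), dispersion)
            b = _nb_counts(rng, np.full(n_per_group, mu_b), dispersion)
            ids.append(f"{sub}_{i:03d}")
            subs.append(sub)
            pbs.append(str(rng.choice(np.array(pbs_choices))))
            rows.append(np.concatenate([a, b]))
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    loci = pd.DataFrame({"subclass": subs, "pbs": pbs}, index=ids)
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples
    )
    libs = pd.Series(1e6, index=samples)
    return ExpressionMatrix(counts=counts, loci=loci, groups=groups, library_sizes=libs)
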