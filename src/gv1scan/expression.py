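"""Per-locus endogenous-retrovirus expression analysis.

Proviral MLV loci are quantified as a counts matrix over samples from two
groups.  Counts are normalized to counts per million (CPM), log2(CPM+1)
group-mean differences give per-locus log2 fold changes, and significance
comes from a group-label permutation test with Benjamini-Hochberg FDR
control.  A locus is called regulated when q < 0.01 and |log2FC| > 1.
Subclass summaries report the mean linear fold change per MLV subclass
(ecotropic, modified-polytropic, polytropic, xenotropic), and loci can be
stratified on tRNA primer-binding-site (PBS) usage with a rank-based
between-group test.  qRT-PCR measurements are normalized to a reference
gene by the 2^-dCt rule, with a cycle cap marking non-amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

SUBCLASSES = ("eMLV", "mpMLV", "pMLV", "xMLV")
PBS_GROUPS = ("Pro", "Gln1", "other", "unknown")

DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_N_PERMUTATIONS = 10_000
QPCR_CYCLE_CAP = 40.0


@dataclass
class ExpressionMatrix:
    """Locus-by-sample counts with subclass/PBS annotations and group labels."""

    counts: pd.DataFrame  # index: locus ids, columns: sample names, int counts
    loci: pd.DataFrame  # index: locus ids; columns: subclass, pbs
    groups: pd.Series  # index: sample names; values in {"A", "B"}
    # per-sample total mapped reads; defaults to the column sums.  ERV loci
    # are a tiny slice of a transcriptome, so a real library size is set by
    # everything else — leaving this at the column sums couples the
    # normalization to the very loci under test (composition bias).
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.loci.index):
            raise ValueError("counts and loci indices differ")
        if set(self.counts.columns) != set(self.groups.index):
            raise ValueError("counts columns and group labels differ")
        self.groups = self.groups.reindex(self.counts.columns)
        if not set(self.groups) <= {"A", "B"}:
            raise ValueError("groups must be labeled 'A'/'B'")
        sizes = self.groups.value_counts()
        if sizes.get("A", 0) < 2 or sizes.get("B", 0) < 2:
            raise ValueError("need >= 2 samples per group")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        bad = set(self.loci["subclass"]) - set(SUBCLASSES)
        if bad:
            raise ValueError(f"unknown subclasses: {sorted(bad)}")
        if self.library_sizes is not None:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
                raise ValueError("library_sizes must be positive for every sample")

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DEResult:
    """Per-locus differential-expression table."""

    table: pd.DataFrame  # index locus; log2fc, p, q, regulated
    q_threshold: float
    lfc_threshold: float
    n_permutations_used: int
    exhaustive: bool


def normalize_cpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6 per sample column.

    The library size is the explicit per-sample total when provided (the
    realistic case for a locus subset), otherwise the column sum, in which
    case every column sums to 1e6 exactly.
    """
    lib = m.library_sizes if m.library_sizes is not None else m.counts.sum(axis=0)
    if (lib <= 0).any():
        zero = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {zero}")
    return m.counts / lib * 1e6


def _log2_cpm(m: ExpressionMatrix) -> np.ndarray:
    return np.log2(normalize_cpm(m).to_numpy() + 1.0)


def de_test(
    m: ExpressionMatrix,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> DEResult:
    """Permutation differential test on log2(CPM+1) group-mean differences.

    The statistic is log2FC = mean_B - mean_A per locus.  Group labels are
    permuted across samples; when the number of distinct relabelings is at
    most *n_permutations* they are enumerated exhaustively (n=3 vs 3 gives
    20, always exhaustive), otherwise that many random relabelings are drawn
    and the add-one correction p = (b+1)/(n+1) applied.  q-values are
    Benjamini-Hochberg over all loci; a locus is regulated when
    q < q_threshold and |log2FC| > lfc_threshold.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    x = _log2_cpm(m)  # loci x samples
    labels = m.groups.to_numpy()
    is_b = labels == "B"
    n_samples = len(labels)
    n_b = int(is_b.sum())

    # contrast weights: +1/nB on B, -1/nA on A
    def weights(mask_b: np.ndarray) -> np.ndarray:
        w = np.where(mask_b, 1.0 / mask_b.sum(), -1.0 / (n_samples - mask_b.sum()))
        return w

    obs = x @ weights(is_b)

    n_distinct = int(comb(n_samples, n_b, exact=True))
    exhaustive = n_distinct <= n_permutations
    if exhaustive:
        masks = np.zeros((n_distinct, n_samples), dtype=bool)
        for r, idx in enumerate(combinations(range(n_samples), n_b)):
            masks[r, list(idx)] = True
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_permutations, n_samples), dtype=bool)
        for r in range(n_permutations):
            masks[r, rng.choice(n_samples, size=n_b, replace=False)] = True

    W = np.stack([weights(mk) for mk in masks])  # perms x samples
    null = x @ W.T  # loci x perms
    exceed = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
    if exhaustive:
        p = exceed / n_distinct  # identity relabeling counts itself: p >= 1/n
    else:
        p = (exceed + 1.0) / (masks.shape[0] + 1.0)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": obs,
            "p": p,
            "q": q,
            "regulated": (q < q_threshold) & (np.abs(obs) > lfc_threshold),
        },
        index=m.counts.index,
    )
    return DEResult(
        table=table,
        q_threshold=q_threshold,
        lfc_threshold=lfc_threshold,
        n_permutations_used=masks.shape[0],
        exhaustive=exhaustive,
    )


def subclass_fold_summary(
    r: DEResult,
    m: ExpressionMatrix,
    significant_only: bool = False,
    geometric: bool = False,
) -> dict[str, float]:
    """Mean linear fold change (2^log2FC) per MLV subclass.

    By default the arithmetic mean over all loci of each subclass; with
    *significant_only* only regulated loci contribute, and with *geometric*
    the geometric mean is reported instead.  Empty subclasses are omitted.
    """
    out: dict[str, float] = {}
    tbl = r.table
    for sub in SUBCLASSES:
        sel = m.loci["subclass"] == sub
        if significant_only:
            sel = sel & tbl["regulated"]
        lfc = tbl.loc[sel[sel].index, "log2fc"].to_numpy()
        if len(lfc) == 0:
            continue
        if geometric:
            out[sub] = float(2.0 ** lfc.mean())
        else:
            out[sub] = float(np.mean(2.0 ** lfc))
    return out


@dataclass
class PbsStratification:
    """Per-PBS-group fold summary and between-group comparison."""

    group_mean_log2fc: dict[str, float]
    p_value: float
    stratified: bool  # True when p < 0.05


def pbs_stratification(
    r: DEResult,
    m: ExpressionMatrix,
    min_group_size: int = 2,
    alpha: float = 0.05,
) -> PbsStratification:
    """Compare per-locus log2FC distributions between PBS usage groups.

    Loci with unknown PBS are excluded; groups with fewer than
    *min_group_size* loci are dropped.  Two groups are compared with a
    two-sided Mann-Whitney U test, more with Kruskal-Wallis.  The analysis
    reports "no stratification" when p >= alpha.
    """
    tbl = r.table
    groups: dict[str, np.ndarray] = {}
    for pbs in ("Pro", "Gln1", "other"):
        ids = m.loci.index[m.loci["pbs"] == pbs]
        vals = tbl.loc[ids, "log2fc"].to_numpy()
        if len(vals) >= min_group_size:
            groups[pbs] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 PBS groups with enough loci to compare")
    arrays = list(groups.values())
    if len(arrays) == 2:
        _, p = mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    else:
        _, p = kruskal(*arrays)
    return PbsStratification(
        group_mean_log2fc={k: float(v.mean()) for k, v in groups.items()},
        p_value=float(p),
        stratified=bool(p < alpha),
    )


@dataclass(frozen=True)
class QpcrResult:
    """2^-dCt relative expression; absent marks the non-amplification cap."""

    value: float
    absent: bool


def qpcr_relative(
    ct_target: float, ct_ref: float, cycle_cap: float = QPCR_CYCLE_CAP
) -> QpcrResult:
    """Relative expression of a target versus a reference gene.

    2^-(ct_target - ct_ref).  A target Ct at or beyond the cycle cap means
    amplification was negligible or absent: the result is 0 with the absent
    flag set.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    if ct_target >= cycle_cap:
        return QpcrResult(0.0, True)
    return QpcrResult(2.0 ** (-(ct_target - ct_ref)), False)
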