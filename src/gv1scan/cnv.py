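"""Windowed read-depth CNV profiling and strain clustering.

A strain's copy-number state over a region is inferred from the ratio of its
library-normalized per-window read counts to those of a diploid reference
strain: the ratio has expectation CN/2, so a heterozygous deletion sits at
0.5, a homozygous deletion at 0 and a duplication at 1.5+.  The ratio track
is median-filtered, mapped to integer states at the midpoints between CN/2
expectations, and merged into contiguous calls.  Strains are compared by the
median absolute error (MAE) between their ratio profiles and clustered
agglomeratively on that distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.ndimage import median_filter
from scipy.spatial.distance import squareform

from gv1scan.intervals import _UNIT_SCALE

# midpoints between consecutive CN/2 expectations 0, 0.5, 1, 1.5, 2
DEFAULT_STATE_BOUNDS = (0.25, 0.75, 1.25, 1.75)
STATE_LABELS = ("0", "1", "2", "3", "4+")

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SMOOTH_WINDOWS = 5
DEFAULT_MIN_CALL_WINDOWS = 5


@dataclass
class DepthProfile:
    """Per-strain read counts over an equal-width window grid (half-open)."""

    strain: str
    chrom: str
    starts: np.ndarray  # int, window start positions
    ends: np.ndarray
    counts: np.ndarray  # non-negative reads per window
    library_size: Optional[float] = None  # defaults to sum of counts

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.starts)
        if not (len(self.ends) == len(self.counts) == n):
            raise ValueError("starts, ends and counts must have equal length")
        if n == 0:
            raise ValueError("empty depth profile")
        widths = self.ends - self.starts
        if np.any(widths <= 0):
            raise ValueError("windows must have positive width")
        if np.unique(widths).size != 1:
            raise ValueError("windows must be equal width")
        if np.any(np.diff(self.starts) < widths[0]):
            raise ValueError("windows must be sorted and non-overlapping")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def window_bp(self) -> int:
        return int(self.ends[0] - self.starts[0])

    def effective_library_size(self) -> float:
        ls = self.library_size if self.library_size is not None else float(self.counts.sum())
        if ls <= 0:
            raise ValueError(f"library size must be positive for {self.strain}")
        return ls


@dataclass
class RatioProfile:
    """Depth ratios versus the reference, on the source window grid."""

    strain: str
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    ratios: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def window_bp(self) -> int:
        return int(self.ends[0] - self.starts[0])


@dataclass(frozen=True)
class CnvCall:
    """A contiguous interval with an inferred copy-number state."""

    chrom: str
    start_bp: int
    end_bp: int
    state: str  # one of STATE_LABELS
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("empty CNV call")
        if self.state not in STATE_LABELS:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain distance matrix with zero diagonal."""

    strains: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strains)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match strain list")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class ClusterResult:
    """Agglomerative clustering output: a tree plus flat groups."""

    strains: list[str]
    linkage_matrix: np.ndarray  # scipy hierarchy encoding
    labels: np.ndarray  # flat group id per strain
    cut_height: float

    def groups(self) -> list[frozenset]:
        out: dict[int, set] = {}
        for name, lab in zip(self.strains, self.labels):
            out.setdefault(int(lab), set()).add(name)
        return [frozenset(v) for v in out.values()]


def _check_same_grid(a, b) -> None:
    if a.chrom != b.chrom or a.n_windows != b.n_windows:
        raise ValueError(
            f"window grids differ: {a.strain}/{a.chrom} has {a.n_windows} windows, "
            f"{b.strain}/{b.chrom} has {b.n_windows}"
        )
    neq = (a.starts != b.starts) | (a.ends != b.ends)
    if np.any(neq):
        i = int(np.argmax(neq))
        raise ValueError(
            f"window grids differ first at index {i}: "
            f"({a.starts[i]}, {a.ends[i]}) vs ({b.starts[i]}, {b.ends[i]})"
        )


def depth_ratio(
    strain: DepthProfile,
    reference: DepthProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RatioProfile:
    """Library-size-normalized per-window depth ratio versus *reference*.

    ratio_i = ((c_i + p) / L_s) / ((r_i + p) / L_r)

    With a diploid reference the ratio has expectation CN_strain / 2.  The
    pseudocount keeps ratios finite over zero-count windows.
    """
    _check_same_grid(strain, reference)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ls = strain.effective_library_size()
    lr = reference.effective_library_size()
    num = (strain.counts + pseudocount) / ls
    den = (reference.counts + pseudocount) / lr
    return RatioProfile(
        strain=strain.strain,
        chrom=strain.chrom,
        starts=strain.starts.copy(),
        ends=strain.ends.copy(),
        ratios=num / den,
    )


def ratio_to_state(ratios: np.ndarray, state_bounds: Sequence[float] = DEFAULT_STATE_BOUNDS) -> np.ndarray:
    """Map each ratio to a copy-number state index (0..4, 4 meaning 4+)."""
    bounds = np.asarray(state_bounds, dtype=float)
    if bounds.ndim != 1 or len(bounds) != len(STATE_LABELS) - 1 or np.any(np.diff(bounds) <= 0):
        raise ValueError("state_bounds must be an increasing sequence of 4 cutpoints")
    return np.digitize(ratios, bounds)


def segment_ratio(
    profile: RatioProfile,
    smooth_windows: int = DEFAULT_SMOOTH_WINDOWS,
    state_bounds: Sequence[float] = DEFAULT_STATE_BOUNDS,
    min_call_windows: int = DEFAULT_MIN_CALL_WINDOWS,
) -> list[CnvCall]:
    """Segment a ratio track into copy-number calls.

    The track is median-filtered with an odd width of *smooth_windows*, each
    window is assigned the state whose CN/2 expectation band contains it, and
    adjacent same-state windows are merged.  Only non-diploid calls spanning
    at least *min_call_windows* windows are reported, suppressing
    single-window noise excursions.
    """
    if profile.n_windows == 0:
        raise ValueError("empty profile")
    if smooth_windows < 1 or smooth_windows % 2 == 0:
        raise ValueError("smooth_windows must be a positive odd integer")
    if profile.n_windows < smooth_windows:
        raise ValueError(
            f"profile has {profile.n_windows} windows, fewer than smooth_windows={smooth_windows}"
        )
    smoothed = median_filter(profile.ratios, size=smooth_windows, mode="nearest")
    states = ratio_to_state(smoothed, state_bounds)

    calls: list[CnvCall] = []
    run_start = 0
    n = len(states)
    for i in range(1, n + 1):
        if i == n or states[i] != states[run_start]:
            st = int(states[run_start])
            length = i - run_start
            if STATE_LABELS[st] != "2" and length >= min_call_windows:
                calls.append(
                    CnvCall(
                        chrom=profile.chrom,
                        start_bp=int(profile.starts[run_start]),
                        end_bp=int(profile.ends[i - 1]),
                        state=STATE_LABELS[st],
                        mean_ratio=float(profile.ratios[run_start:i].mean()),
                    )
                )
            run_start = i
    return calls


def interval_span(start_bp: float, end_bp: float, unit: str = "bp") -> float:
    """Exact interval span scaled to *unit* (``bp``, ``kb`` or ``Mb``)."""
    if end_bp <= start_bp:
        raise ValueError(f"inverted interval {start_bp}-{end_bp}")
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r}")
    return (end_bp - start_bp) / _UNIT_SCALE[unit]


def mae_distance(a: RatioProfile, b: RatioProfile, stat: str = "median") -> float:
    """Absolute-error distance between two ratio profiles on one grid.

    ``stat="median"`` gives the median absolute error, a distance robust to
    localized CNV blocks; ``stat="mean"`` gives the conventional mean
    absolute error.
    """
    _check_same_grid(a, b)
    diffs = np.abs(a.ratios - b.ratios)
    if stat == "median":
        return float(np.median(diffs))
    if stat == "mean":
        return float(np.mean(diffs))
    raise ValueError(f"unknown stat {stat!r}")


def mae_matrix(profiles: Sequence[RatioProfile], stat: str = "median") -> DistanceMatrix:
    """All-pairs MAE distances between ratio profiles."""
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least two profiles")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mae_distance(profiles[i], profiles[j], stat=stat)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix([p.strain for p in profiles], vals)


def cluster_strains(
    d: DistanceMatrix,
    linkage_rule: str = "average",
    cut_height: Optional[float] = None,
    n_groups: int = 2,
) -> ClusterResult:
    """Agglomerative clustering of strains on a distance matrix.

    Merging follows the chosen linkage rule with scipy's deterministic
    lowest-index tie-breaking.  Flat groups come from cutting the tree at
    *cut_height*, or, when that is None, at the height giving *n_groups*
    groups (default 2 — the top split).
    """
    if linkage_rule not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage rule {linkage_rule!r}")
    condensed = squareform(d.values, checks=True)
    Z = _scipy_linkage(condensed, method=linkage_rule)
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
        height = float(cut_height)
    else:
        labels = fcluster(Z, t=n_groups, criterion="maxclust")
        height = float(Z[-(n_groups - 1), 2]) if n_groups > 1 else float("inf")
    return ClusterResult(
        strains=list(d.strains),
        linkage_matrix=Z,
        labels=np.asarray(labels),
        cut_height=height,
    )
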