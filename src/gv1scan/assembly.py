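"""Assembly-versus-reference segment analysis and clone scaffolding.

Dotplot-style analysis of precomputed alignment segments between an
assembly (query) and a reference chromosome (target): segments are filtered
to >=1 kb blocks at >=98% identity, duplicated reference regions show up as
windows overlapped by two or more segments, and unique assembly sequence as
query ranges with no segment at all.  Clone sequences have their cloning
vector excised and are then joined into scaffolds greedily by end-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from gv1scan.intervals import complement_intervals, merge_intervals
from gv1scan.splice import reverse_complement

DEFAULT_MIN_SEGMENT_BP = 1000
DEFAULT_MIN_SEGMENT_IDENTITY = 98.0
DEFAULT_MIN_OVERLAP_BP = 1000
DEFAULT_MIN_OVERLAP_IDENTITY = 98.0
DEFAULT_MIN_FRAGMENT_BP = 1000


@dataclass(frozen=True)
class AlignmentSegment:
    """One query-to-reference alignment block (0-based half-open)."""

    qname: str
    qstart: int
    qend: int
    tname: str
    tstart: int
    tend: int
    identity: float  # percent in [0, 100]
    orientation: str = "forward"  # {"forward", "reverse"}

    def __post_init__(self) -> None:
        if self.qend <= self.qstart:
            raise ValueError(f"empty query interval in {self.qname}")
        if self.tend <= self.tstart:
            raise ValueError(f"empty target interval on {self.tname}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"invalid orientation {self.orientation!r}")

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart


@dataclass
class ScaffoldSet:
    """Ordered clone chains after end-overlap joining."""

    scaffolds: list[dict]  # each: {"clones": [...], "length": int, "sequence": str|None}
    unplaced: list[str] = field(default_factory=list)

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffolds)


def filter_segments(
    segs: Sequence[AlignmentSegment],
    min_len_bp: int = DEFAULT_MIN_SEGMENT_BP,
    min_identity: float = DEFAULT_MIN_SEGMENT_IDENTITY,
) -> list[AlignmentSegment]:
    """Keep segments with query span >= min_len_bp AND identity >= min_identity.

    Both thresholds are inclusive; input order is preserved.  Idempotent.
    """
    return [
        s
        for s in segs
        if s.query_span >= min_len_bp and s.identity >= min_identity
    ]


def reference_multiplicity(
    segs: Sequence[AlignmentSegment],
    window_bp: int,
    region: Optional[tuple[int, int]] = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-window count of segments covering each reference position.

    Returns, per target name, (window_starts, counts) over windows of
    *window_bp*; a count of a window is the number of distinct segments
    overlapping it.  *region* fixes the windowed extent (defaults to 0 up to
    the furthest segment end, rounded up to a whole window).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_target: dict[str, list[AlignmentSegment]] = {}
    for s in segs:
        by_target.setdefault(s.tname, []).append(s)
    for tname, tsegs in by_target.items():
        if region is None:
            lo, hi = 0, max(s.tend for s in tsegs)
        else:
            lo, hi = region
        n_win = -(-(hi - lo) // window_bp)
        starts = lo + window_bp * np.arange(n_win, dtype=np.int64)
        counts = np.zeros(n_win, dtype=np.int64)
        for s in tsegs:
            first = max(0, (s.tstart - lo) // window_bp)
            last = min(n_win, -(-(s.tend - lo) // window_bp))
            counts[first:last] += 1
        out[tname] = (starts, counts)
    return out


def duplicated_regions(
    multiplicity: Mapping[str, tuple[np.ndarray, np.ndarray]],
    window_bp: int,
    min_count: int = 2,
) -> list[tuple[str, int, int]]:
    """Maximal runs of reference windows covered by >= min_count segments.

    Returned as BED-style (tname, start, end) tuples.
    """
    out: list[tuple[str, int, int]] = []
    for tname in sorted(multiplicity):
        starts, counts = multiplicity[tname]
        dup = counts >= min_count
        i = 0
        n = len(dup)
        while i < n:
            if dup[i]:
                j = i
                while j < n and dup[j]:
                    j += 1
                out.append((tname, int(starts[i]), int(starts[j - 1]) + window_bp))
                i = j
            else:
                i += 1
    return out


def query_unique_regions(
    segs: Sequence[AlignmentSegment], query_lengths: Mapping[str, int]
) -> list[tuple[str, int, int]]:
    """Query ranges with no alignment segment, as BED-style tuples.

    The complement of the union of all segments' query intervals, per query,
    merged and sorted.  A segment exceeding its declared query length raises.
    """
    by_query: dict[str, list[tuple[int, int]]] = {q: [] for q in query_lengths}
    for s in segs:
        if s.qname not in query_lengths:
            raise ValueError(f"segment query {s.qname!r} has no declared length")
        if s.qend > query_lengths[s.qname]:
            raise ValueError(
                f"segment {s.qname}:{s.qstart}-{s.qend} exceeds declared "
                f"length {query_lengths[s.qname]}"
            )
        by_query[s.qname].append((s.qstart, s.qend))
    out: list[tuple[str, int, int]] = []
    for qname in sorted(by_query):
        for s, e in complement_intervals(by_query[qname], query_lengths[qname]):
            out.append((qname, s, e))
    return out


def remove_vector(
    clone_seq: str,
    vector_hits: Iterable[tuple[int, int]],
    min_fragment_bp: int = DEFAULT_MIN_FRAGMENT_BP,
) -> list[str]:
    """Excise vector intervals from a clone sequence.

    Overlapping hits are merged before excision.  The ordered non-vector
    fragments are returned, dropping any shorter than *min_fragment_bp*
    (tiny residual fragments are uninformative for scaffolding).
    """
    hits = merge_intervals(list(vector_hits))
    for s, e in hits:
        if s < 0 or e > len(clone_seq):
            raise ValueError(f"vector hit ({s}, {e}) outside sequence bounds")
    keep = complement_intervals(hits, len(clone_seq))
    return [clone_seq[s:e] for s, e in keep if e - s >= min_fragment_bp]


# ---------------------------------------------------------------------------
# end-overlap scaffolding


def _onehot(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, len(seq)), dtype=np.float32)
    for k, b in enumerate(b"ACGT"):
        out[k] = arr == b
    return out


def suffix_prefix_overlap(
    a: str,
    b: str,
    min_overlap_bp: int,
    min_identity: float,
) -> Optional[tuple[int, float]]:
    """Longest suffix-of-*a* / prefix-of-*b* overlap meeting the thresholds.

    Match counts for every candidate overlap length are obtained at once by
    cross-correlating one-hot encodings (FFT), so the search is
    O(n log n) instead of quadratic.  Returns (length, identity_percent) or
    None.  Identity here is per-position agreement (no indels), adequate for
    clone ends that derive from the same underlying molecule.
    """
    na, nb = len(a), len(b)
    max_l = min(na, nb)
    if max_l < min_overlap_bp:
        return None
    A, B = _onehot(a), _onehot(b)
    # conv[m] = sum_i A[i] * B[i - (m - nb + 1)]; alignment where b[0] sits at
    # a index s has m = s + nb - 1 and overlap length L = na - s
    conv = sum(fftconvolve(A[k], B[k][::-1]) for k in range(4))
    lengths = np.arange(min_overlap_bp, max_l + 1)
    matches = np.rint(conv[(na - lengths) + nb - 1]).astype(np.int64)
    ident = 100.0 * matches / lengths
    ok = ident >= min_identity
    if not ok.any():
        return None
    best = int(np.nonzero(ok)[0][-1])  # longest qualifying overlap
    return int(lengths[best]), float(ident[best])


def join_scaffolds(
    clones: Mapping[str, str],
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
    min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
) -> ScaffoldSet:
    """Join clone sequences into scaffolds by end-overlap.

    Every pair of clone ends is tested in both orientations for a
    suffix/prefix overlap meeting the length and identity thresholds.  Joins
    are applied greedily, longest overlap first (ties broken by clone name),
    each clone end used at most once and cycles refused, so the result is a
    set of simple chains.  Clones without qualifying overlaps become
    single-clone scaffolds.
    """
    if not clones:
        raise ValueError("need at least one clone")
    names = sorted(clones)
    seqs = {n: clones[n].upper() for n in names}

    # candidate joins: (L, nameA, endA, nameB, endB) meaning endA of A meets
    # endB of B with overlap length L.  Ends are "L"/"R" on the original
    # orientation of each clone.
    candidates: list[tuple[int, float, str, str, str, str]] = []
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            sx, sy = seqs[x], seqs[y]
            combos = (
                (sx, sy, x, "R", y, "L"),  # X.R meets Y.L (both forward)
                (sy, sx, y, "R", x, "L"),  # Y.R meets X.L
                (sx, reverse_complement(sy), x, "R", y, "R"),  # X.R meets Y.R
                (reverse_complement(sx), sy, x, "L", y, "L"),  # X.L meets Y.L
            )
            for a, b, na_, ea, nb_, eb in combos:
                hit = suffix_prefix_overlap(a, b, min_overlap_bp, min_overlap_identity)
                if hit is not None:
                    L, ident = hit
                    candidates.append((L, ident, na_, ea, nb_, eb))

    candidates.sort(key=lambda c: (-c[0], c[2], c[4], c[3], c[5]))

    parent = {n: n for n in names}

    def find(n: str) -> str:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    end_used: set[tuple[str, str]] = set()
    joins: dict[tuple[str, str], tuple[str, str, int]] = {}
    for L, _ident, a, ea, b, eb in candidates:
        if (a, ea) in end_used or (b, eb) in end_used:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue  # would close a cycle
        parent[ra] = rb
        end_used.add((a, ea))
        end_used.add((b, eb))
        joins[(a, ea)] = (b, eb, L)
        joins[(b, eb)] = (a, ea, L)

    # walk each chain from a free end
    comp_members: dict[str, list[str]] = {}
    for n in names:
        comp_members.setdefault(find(n), []).append(n)

    scaffolds: list[dict] = []
    for members in comp_members.values():
        # find a clone with a free end to start from (chains are acyclic)
        start = None
        for n in sorted(members):
            for e in ("L", "R"):
                if (n, e) not in joins:
                    start = (n, e)
                    break
            if start:
                break
        assert start is not None
        chain: list[str] = []
        total = 0
        node, free_end = start
        while True:
            chain.append(node)
            total += len(seqs[node])
            other = "R" if free_end == "L" else "L"
            if (node, other) not in joins:
                break
            nxt, nxt_end, L = joins[(node, other)]
            total -= L
            node, free_end = nxt, nxt_end
        scaffolds.append({"clones": chain, "length": total, "sequence": None})

    scaffolds.sort(key=lambda s: (-len(s["clones"]), s["clones"][0]))
    return ScaffoldSet(scaffolds=scaffolds, unplaced=[])
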