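"""Segment filtering, multiplicity, unique regions, vector removal, scaffolds."""

import numpy as np
import pytest

from gv1scan import synthetic
from gv1scan.assembly import (
    AlignmentSegment,
    duplicated_regions,
    filter_segments,
    join_scaffolds,
    query_unique_regions,
    reference_multiplicity,
    remove_vector,
    suffix_prefix_overlap,
)
from gv1scan.splice import reverse_complement


def _seg(qs, qe, ts, te, ident=99.0, q="q", t="t"):
    return AlignmentSegment(q, qs, qe, t, ts, te, ident)


def _random_segments(rng, n=500):
    segs = []
    for _ in range(n):
        qs = int(rng.integers(0, 900_000))
        qlen = int(rng.integers(200, 5000))
        ts = int(rng.integers(0, 900_000))
        ident = float(rng.uniform(90, 100))
        segs.append(_seg(qs, qs + qlen, ts, ts + qlen, ident))
    return segs


class TestFilterSegments:
    def test_boundary_cases(self):
        dropped = _seg(0, 999, 0, 999, 99.0)
        kept = _seg(0, 1000, 0, 1000, 98.0)
        assert filter_segments([dropped, kept]) == [kept]

    def test_matches_brute_force_oracle(self, rng):
        segs = _random_segments(rng)
        kept = filter_segments(segs, 1000, 98.0)
        oracle = [s for s in segs if (s.qend - s.qstart) >= 1000 and s.identity >= 98.0]
        assert kept == oracle

    def test_idempotent_and_order_preserving(self, rng):
        segs = _random_segments(rng)
        once = filter_segments(segs)
        assert filter_segments(once) == once


class TestReferenceMultiplicity:
    def test_no_segments_all_zero(self):
        assert reference_multiplicity([], 100) == {}

    def test_engineered_duplicate_block(self):
        segs = [_seg(0, 1000, 2000, 3000), _seg(5000, 6000, 2000, 3000)]
        mult = reference_multiplicity(segs, 100, region=(0, 4000))
        starts, counts = mult["t"]
        in_block = (starts >= 2000) & (starts < 3000)
        assert np.all(counts[in_block] == 2)
        assert np.all(counts[~in_block] == 0)
        dups = duplicated_regions(mult, 100)
        assert dups == [("t", 2000, 3000)]

    def test_matches_interval_stabbing_oracle(self, rng):
        segs = _random_segments(rng, n=200)
        window = 1000
        mult = reference_multiplicity(segs, window)
        starts, counts = mult["t"]
        for w in rng.integers(0, len(starts), size=50):
            lo, hi = starts[w], starts[w] + window
            oracle = sum(1 for s in segs if s.tstart < hi and s.tend > lo)
            assert counts[w] == oracle

    def test_coverage_conservation_on_aligned_grid(self):
        # segments aligned to the window grid: sum(counts)*window == total span
        segs = [_seg(0, 3000, 1000, 4000), _seg(0, 2000, 3000, 5000)]
        window = 1000
        _, counts = reference_multiplicity(segs, window)["t"]
        assert counts.sum() * window == sum(s.target_span for s in segs)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            reference_multiplicity([_seg(0, 10, 0, 10)], 0)


class TestQueryUniqueRegions:
    def test_fully_covered_query_empty(self):
        segs = [_seg(0, 500, 0, 500), _seg(400, 1000, 600, 1200)]
        assert query_unique_regions(segs, {"q": 1000}) == []

    def test_uncovered_query_is_one_range(self):
        assert query_unique_regions([], {"q": 700}) == [("q", 0, 700)]

    def test_matches_complement_oracle(self, rng):
        segs = _random_segments(rng, n=100)
        qlen = 1_000_000
        regions = query_unique_regions(segs, {"q": qlen})
        covered = np.zeros(qlen // 100, dtype=bool)  # 100 bp resolution grid
        for s in segs:
            covered[s.qstart // 100 : s.qend // 100] = True
        for _, lo, hi in regions:
            # every reported unique range must be fully uncovered
            assert not covered[(lo + 99) // 100 : hi // 100].any()

    def test_exceeding_declared_length_raises(self):
        with pytest.raises(ValueError):
            query_unique_regions([_seg(0, 2000, 0, 2000)], {"q": 1000})


class TestRemoveVector:
    def test_no_hits_identity(self):
        seq = "ACGT" * 1000
        assert remove_vector(seq, []) == [seq]

    def test_vector_at_both_ends(self):
        seq = "A" * 2000 + "C" * 3000 + "G" * 2000
        frags = remove_vector(seq, [(0, 2000), (5000, 7000)])
        assert frags == ["C" * 3000]

    def test_internal_vector_splits_with_conserved_length(self):
        seq = "A" * 3000 + "T" * 1500 + "C" * 4000
        frags = remove_vector(seq, [(3000, 4500)])
        assert len(frags) == 2
        assert sum(map(len, frags)) == len(seq) - 1500

    def test_overlapping_hits_merged_and_short_fragments_dropped(self):
        seq = "A" * 1200 + "T" * 500 + "C" * 1200
        frags = remove_vector(seq, [(1200, 1500), (1400, 1700)], min_fragment_bp=1000)
        assert frags == ["A" * 1200, "C" * 1200]


class TestSuffixPrefixOverlap:
    def test_exact_overlap_found(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=2000))
        a = "".join(rng.choice(list("ACGT"), size=3000)) + core
        b = core + "".join(rng.choice(list("ACGT"), size=3000))
        hit = suffix_prefix_overlap(a, b, 500, 98.0)
        assert hit is not None
        L, ident = hit
        assert L == 2000 and ident == 100.0

    def test_no_overlap_below_threshold(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=2000))
        b = "".join(rng.choice(list("ACGT"), size=2000))
        assert suffix_prefix_overlap(a, b, 500, 98.0) is None

    def test_mismatches_lower_identity(self, rng):
        core = list("".join(rng.choice(list("ACGT"), size=1000)))
        b_core = core.copy()
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in range(0, 1000, 100):  # 1% mismatches
            b_core[i] = flip[b_core[i]]
        a = "".join(rng.choice(list("ACGT"), size=1000)) + "".join(core)
        b = "".join(b_core) + "".join(rng.choice(list("ACGT"), size=1000))
        hit = suffix_prefix_overlap(a, b, 500, 98.0)
        assert hit is not None
        assert hit[1] == pytest.approx(99.0, abs=0.05)


class TestJoinScaffolds:
    def test_disjoint_clones_one_scaffold_each(self, rng):
        clones = {
            f"c{i}": "".join(rng.choice(list("ACGT"), size=5000)) for i in range(4)
        }
        result = join_scaffolds(clones, min_overlap_bp=1000)
        assert result.n_scaffolds == 4
        assert all(len(s["clones"]) == 1 for s in result.scaffolds)

    def test_chain_of_three_with_engineered_overlaps(self):
        clones, comps = synthetic.gen_clone_sequences([3], clone_bp=20_000,
                                                      overlap_bp=5_000, seed=41)
        result = join_scaffolds(clones, min_overlap_bp=1000)
        assert result.n_scaffolds == 1
        sc = result.scaffolds[0]
        assert sorted(sc["clones"]) == sorted(comps[0])
        # merged length = 3 clones - 2 overlaps
        assert sc["length"] == 3 * 20_000 - 2 * 5_000

    def test_reverse_complemented_clone_still_joins(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=4000))
        a = "".join(rng.choice(list("ACGT"), size=8000)) + core
        b = core + "".join(rng.choice(list("ACGT"), size=8000))
        result = join_scaffolds({"a": a, "b": reverse_complement(b)}, 1000)
        assert result.n_scaffolds == 1

    def test_fifteen_clones_in_eight_components_give_eight_scaffolds(self):
        clones, comps = synthetic.gen_clone_sequences(
            [3, 2, 2, 2, 2, 1, 1, 2], clone_bp=20_000, overlap_bp=5_000, seed=47
        )
        assert len(clones) == 15 and len(comps) == 8
        result = join_scaffolds(clones, min_overlap_bp=1000)
        assert result.n_scaffolds == 8
        # scaffold membership equals the ground-truth overlap components
        got = {frozenset(s["clones"]) for s in result.scaffolds}
        assert got == {frozenset(c) for c in comps}

    def test_matches_union_find_component_oracle(self):
        # oracle: component count from union-find over ground-truth overlaps
        sizes = [4, 3, 1, 2]
        clones, comps = synthetic.gen_clone_sequences(sizes, seed=53)
        result = join_scaffolds(clones)
        assert result.n_scaffolds == len(comps)


class TestGenAlignmentSegments:
    def test_duplicated_block_has_multiplicity_two(self):
        dup = [(300_000, 360_000)]
        segs = synthetic.gen_alignment_segments(dup, [], seed=61)
        mult = reference_multiplicity(segs, 10_000)
        starts, counts = mult["13"]
        block = (starts >= 300_000) & (starts < 360_000)
        assert np.all(counts[block] >= 2)

    def test_unique_block_uncovered_on_query_axis(self):
        uniq = [(700_000, 760_000)]
        segs = synthetic.gen_alignment_segments([], uniq, seed=62)
        qlen = max(s.qend for s in segs)
        unique = query_unique_regions(segs, {"assembly": qlen})
        assert ("assembly", 700_000, 760_000) in unique

    def test_filtered_counts_match_brute_force(self):
        segs = synthetic.gen_alignment_segments(
            [(100_000, 150_000)], [(500_000, 550_000)], base_identity=98.0, seed=63
        )
        kept = filter_segments(segs, 1000, 98.0)
        oracle = sum(
            1 for s in segs if (s.qend - s.qstart) >= 1000 and s.identity >= 98.0
        )
        assert len(kept) == oracle

    def test_overlapping_spec_intervals_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_alignment_segments([(0, 100), (50, 150)], [], seed=1)

    def test_seed_determinism(self):
        a = synthetic.gen_alignment_segments([(10_000, 20_000)], [], seed=64)
        b = synthetic.gen_alignment_segments([(10_000, 20_000)], [], seed=64)
        assert a == b
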