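"""Marker selection: filtering, window scoring, beam search, placement.

The window-score oracle here enumerates genotype-state vectors from
first principles (string tuples of unordered allele pairs), a different
representation from the implementation's dosage encoding.
"""

import itertools

import numpy as np
import pytest

from mugakit.markersel import (
    CandidateSNP,
    beam_select_chromosome,
    exhaustive_select_chromosome,
    filter_candidates,
    hotspot_select,
    n_genotype_states,
    partition_intervals,
    place_wild_snps,
    select_uniform_spacing,
    split_by_intervals,
    window_score,
    window_scores_batch,
)


def oracle_window_score(window: np.ndarray) -> int:
    """Count distinct state vectors by direct enumeration (no missing)."""
    f, w = window.shape
    vectors = set()
    states = [(i, i) for i in range(f)] + list(itertools.combinations(range(f), 2))
    for a, b in states:
        vec = tuple(
            "".join(sorted(f"{window[a, m]}{window[b, m]}")) for m in range(w)
        )
        vectors.add(vec)
    return len(vectors)


def snp(i, pos, alleles, chrom="1", cm=None, **kw):
    return CandidateSNP(
        f"m{i}", chrom, pos, kw.pop("pair", ("A", "G")),
        founder_alleles=np.asarray(alleles, dtype=np.int8),
        position_cM=cm if cm is not None else pos / 1e6, **kw,
    )


class TestFilterCandidates:
    def test_close_pair_removed(self):
        a = snp(1, 1000, [0] * 8, min_dist_to_neighbor_bp=49)
        b = snp(2, 1049, [0] * 8, min_dist_to_neighbor_bp=49)
        assert filter_candidates([a, b]) == []

    def test_two_bead_snp_removed(self):
        at = snp(1, 1000, [0] * 8, pair=("A", "T"))
        assert not at.is_single_bead
        assert filter_candidates([at]) == []

    def test_isolated_transition_retained(self):
        c = snp(1, 1000, [0] * 8, min_dist_to_neighbor_bp=500)
        assert c.is_transition
        assert filter_candidates([c]) == [c]

    def test_unsorted_input_rejected(self):
        a = snp(1, 2000, [0] * 8)
        b = snp(2, 1000, [0] * 8)
        with pytest.raises(ValueError):
            filter_candidates([a, b])

    def test_output_is_ordered_subset(self, rng):
        cands = [
            snp(i, 1000 * i, rng.integers(0, 2, 8),
                min_dist_to_neighbor_bp=int(rng.integers(10, 100)))
            for i in range(1, 30)
        ]
        kept = filter_candidates(cands)
        assert all(k in cands for k in kept)
        idx = [cands.index(k) for k in kept]
        assert idx == sorted(idx)


class TestPartitionIntervals:
    def test_uniform_candidates(self):
        cands = [snp(i, i * 1_000_000, [0] * 8, cm=float(i)) for i in range(10)]
        bounds = partition_intervals(cands, 5, window_size=5)
        assert len(bounds) == 5
        groups = split_by_intervals(cands, bounds)
        assert [len(g) for g in groups] == [2] * 5

    def test_clustered_candidates_decrement(self):
        # candidates only in the first half: brute-force feasibility over n'
        cms = [0.0, 1.0, 2.0, 3.0, 4.0, 10.0]
        cands = [snp(i, int(c * 1e6) + 1, [0] * 8, cm=c) for i, c in enumerate(cms)]
        bounds = partition_intervals(cands, 4, window_size=2)

        def feasible(n_try):
            edges = np.linspace(0.0, 10.0, n_try + 1)
            counts = [0] * n_try
            for c in cms:
                i = min(int(np.searchsorted(edges, c, side="right")) - 1, n_try - 1)
                counts[i] += 1
            return all(counts)

        expected = next(n for n in (4, 3, 2) if feasible(n))
        assert len(bounds) == expected < 4
        assert all(len(g) >= 1 for g in split_by_intervals(cands, bounds))

    def test_infeasible_raises(self):
        cands = [snp(0, 1, [0] * 8, cm=0.0), snp(1, 2, [0] * 8, cm=1.0)]
        with pytest.raises(ValueError):
            partition_intervals(cands, 1, window_size=5)


class TestWindowScore:
    def test_state_space_size(self):
        assert n_genotype_states(8) == (28, 36)

    def test_monomorphic_window_scores_one(self):
        assert window_score(np.zeros((8, 5), dtype=int)) == 1

    def test_single_private_allele_scores_three(self):
        # founder-1 hom, founder-1 hets, everything else
        w = np.zeros((8, 5), dtype=int)
        w[0, 0] = 1
        assert window_score(w) == 3

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            w = rng.integers(0, 2, size=(8, 5))
            assert window_score(w) == oracle_window_score(w)

    def test_batch_agrees_with_scalar(self, rng):
        cfgs = rng.integers(0, 2, size=(50, 8, 5))
        batch = window_scores_batch(cfgs)
        assert batch.tolist() == [window_score(c) for c in cfgs]

    def test_upper_bound_and_invariance(self, rng):
        for _ in range(50):
            w = rng.integers(0, 2, size=(8, 5))
            k = window_score(w)
            assert 1 <= k <= 36
            # permutation of founders
            assert window_score(w[rng.permutation(8)]) == k
            # reflection of allele coding at one SNP
            w2 = w.copy()
            w2[:, 2] = 1 - w2[:, 2]
            assert window_score(w2) == k

    def test_missing_allele_is_conservative(self):
        w = np.zeros((8, 5), dtype=int)
        w[0, 0] = 1
        k_full = window_score(w)
        w_miss = w.copy()
        w_miss[0, 0] = -1  # wildcard collides with everything consistent
        assert window_score(w_miss) <= k_full


class TestBeamSelect:
    def _instance(self, rng, n_intervals=8, max_cands=3):
        return [
            [snp(100 * i + j, 10_000 * (i + 1) + j, rng.integers(0, 2, 8),
                 cm=float(i))
             for j in range(int(rng.integers(1, max_cands + 1)))]
            for i in range(n_intervals)
        ]

    def test_forced_path(self, rng):
        intervals = [[snp(i, 1000 * (i + 1), rng.integers(0, 2, 8), cm=float(i))]
                     for i in range(5)]
        res = beam_select_chromosome(intervals, window_size=5)
        alleles = np.stack([c.founder_alleles for c in res.chosen], axis=1)
        assert res.score == window_score(alleles)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(25):
            intervals = self._instance(rng)
            beam = beam_select_chromosome(intervals, 5, beam_width=100_000)
            exact = exhaustive_select_chromosome(intervals, 5)
            assert beam.score == exact.score

    def test_score_monotone_in_beam_width(self, rng):
        intervals = self._instance(rng)
        widths = [1, 10, 100, 100_000]
        scores = [beam_select_chromosome(intervals, 5, w).score for w in widths]
        assert scores == sorted(scores)
        assert scores[-1] == exhaustive_select_chromosome(intervals, 5).score

    def test_short_chromosome_flagged(self, rng):
        intervals = self._instance(rng, n_intervals=3)
        res = beam_select_chromosome(intervals, window_size=5)
        assert res.flagged_short and res.score == 0

    def test_empty_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            beam_select_chromosome([[], [snp(1, 10, [0] * 8)]], 5)


class TestHotspotSelect:
    def test_forced_window(self, rng):
        cands = [snp(i, 1000 + 30 * i, rng.integers(0, 2, 8)) for i in range(4)]
        res = hotspot_select(cands, 1040, 1140, w=4)
        assert [c.marker_id for c in res.chosen] == [c.marker_id for c in cands]
        assert not res.off_center

    def test_higher_scoring_run_wins(self, rng):
        # two feasible 4-SNP runs over 6 candidates; oracle scores both
        while True:
            alleles = rng.integers(0, 2, size=(6, 8))
            s1 = oracle_window_score(alleles[0:4].T)
            s2 = oracle_window_score(alleles[2:6].T)
            if s1 != s2:
                break
        cands = [snp(i, 1000 + 40 * i, alleles[i]) for i in range(6)]
        res = hotspot_select(cands, 1000, 1250, w=4)
        want = cands[0:4] if s1 > s2 else cands[2:6]
        assert [c.marker_id for c in res.chosen] == [c.marker_id for c in want]
        assert res.score == max(s1, s2)

    def test_tie_broken_by_span(self):
        alleles = [[0] * 8] * 6
        pos = [1000, 1010, 1020, 1030, 1100, 1200]  # run 0-3 much tighter
        cands = [snp(i, p, alleles[i]) for i, p in enumerate(pos)]
        res = hotspot_select(cands, 990, 1250, w=4)
        assert [c.position_bp for c in res.chosen] == pos[0:4]

    def test_off_center_flag(self, rng):
        cands = [snp(i, 1000 + 10 * i, rng.integers(0, 2, 8)) for i in range(4)]
        res = hotspot_select(cands, 5000, 5100, w=4)
        assert res.off_center


class TestUniformSpacing:
    def test_uniform_input_keeps_gaps_balanced(self):
        cands = [snp(i, 1000 * i, [0] * 8) for i in range(1, 101)]
        sel = select_uniform_spacing(cands, 10)
        pos = [c.position_bp for c in sel]
        gaps = np.diff(pos)
        assert gaps.max() <= 2 * gaps.min()

    def test_select_all_is_identity(self):
        cands = [snp(i, 1000 * i, [0] * 8) for i in range(1, 9)]
        sel = select_uniform_spacing(cands, len(cands))
        assert [c.marker_id for c in sel] == [c.marker_id for c in cands]

    def test_near_optimal_on_clustered_instance(self):
        # exhaustive oracle over all C(8, 3) subsets of a clustered instance
        pos = [0, 10, 20, 30, 500, 510, 900, 1000]
        cands = [snp(i, p + 1, [0] * 8) for i, p in enumerate(pos)]
        domain = (1, 1001)
        sel = select_uniform_spacing(cands, 3, domain=domain)

        def largest_gap(chosen):
            pts = [domain[0]] + sorted(chosen) + [domain[1]]
            return max(b - a for a, b in zip(pts, pts[1:]))

        best = min(
            largest_gap([cands[i].position_bp for i in combo])
            for combo in itertools.combinations(range(8), 3)
        )
        got = largest_gap([c.position_bp for c in sel])
        # greedy gap-halving is near-optimal; allow a factor-2 bound
        assert got <= 2 * best

    def test_bad_k(self):
        cands = [snp(1, 10, [0] * 8)]
        with pytest.raises(ValueError):
            select_uniform_spacing(cands, 0)


class TestPlaceWildSnps:
    def _snp(self, i, pos, transition, maf):
        pair = ("A", "G") if transition else ("A", "C")
        return CandidateSNP(f"w{i}", "1", pos, pair, maf=maf,
                            founder_alleles=np.zeros(8, np.int8),
                            position_cM=pos / 1e6)

    def test_exactly_satisfiable_window(self):
        novel = [
            self._snp(1, 100_000, True, 0.3),    # first half transition
            self._snp(2, 700_000, True, 0.3),    # second half transition
            self._snp(3, 500_000, False, 0.3),   # middle-third transversion
        ]
        picks = place_wild_snps(novel, 1_000_000)
        assert len(picks) == 3
        assert not any(p.spacing_violated for p in picks)
        assert {p.slot for p in picks} == {
            "transition_1", "transition_2", "transversion_mid"
        }

    def test_empty_slot_yields_fewer_picks(self):
        novel = [self._snp(1, 100_000, True, 0.3)]
        picks = place_wild_snps(novel, 1_000_000)
        assert len(picks) == 1 and picks[0].slot == "transition_1"

    def test_unavoidable_crowding_is_flagged(self):
        # every candidate within 100 kb of the others: brute force says any
        # full slot assignment must violate spacing for slots 2 and 3
        novel = [
            self._snp(1, 450_000, True, 0.4),
            self._snp(2, 500_000, True, 0.4),
            self._snp(3, 490_000, False, 0.4),
        ]
        assignments = list(itertools.permutations(novel))
        assert all(
            any(abs(a.position_bp - b.position_bp) < 100_000
                for a, b in itertools.combinations(trio, 2))
            for trio in assignments
        )
        picks = place_wild_snps(novel, 1_000_000)
        assert len(picks) == 3
        assert sum(p.spacing_violated for p in picks) == 2

    def test_higher_maf_favored(self):
        novel = [
            self._snp(1, 100_000, True, 0.1),
            self._snp(2, 300_000, True, 0.45),
        ]
        picks = place_wild_snps(novel, 1_000_000)
        slot1 = [p for p in picks if p.slot == "transition_1"]
        assert slot1[0].snp.marker_id == "w2"
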