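"""Informative-marker counts, concordance, diagnostic discovery, recoding."""

import numpy as np
import pytest

from mugakit.datamodel import Call
from mugakit.inform import (
    DiagnosticCatalog,
    allele_frequencies,
    augment_density,
    concordance,
    count_informative,
    f1_concordance,
    find_diagnostic,
    recode_for_phylogeny,
)

AA, AB, BB, N = Call.AA, Call.AB, Call.BB, Call.N


class TestCountInformative:
    def test_identical_vectors(self):
        v = [AA, BB, AB]
        assert count_informative(v, v, [1, 1, 1]) == 0

    def test_only_opposite_homozygotes_count(self):
        a = [AA, BB, AB]
        b = [BB, AA, AA]
        assert count_informative(a, b, [1, 1, 1]) == 2

    def test_tier_gating(self):
        a, b = [AA], [BB]
        assert count_informative(a, b, [3]) == 0
        assert count_informative(a, b, [2]) == 1

    def test_symmetry(self, rng):
        a = rng.integers(0, 4, 100).astype(np.int8)
        b = rng.integers(0, 4, 100).astype(np.int8)
        t = rng.integers(1, 5, 100)
        assert count_informative(a, b, t) == count_informative(b, a, t)


class TestConcordance:
    def test_identical(self):
        v = np.array([AA, AB, BB, N], dtype=np.int8)
        assert concordance(v, v) == 1.0

    def test_one_discordant_in_hundred(self):
        a = np.full(100, AA, dtype=np.int8)
        b = a.copy()
        b[0] = BB
        assert concordance(a, b) == pytest.approx(0.99)

    def test_all_missing_partner_rejected(self):
        a = np.array([AA, BB], dtype=np.int8)
        b = np.array([N, N], dtype=np.int8)
        with pytest.raises(ValueError):
            concordance(a, b)


class TestF1Concordance:
    def test_predictions(self):
        p1 = np.array([AA, AA, AB], dtype=np.int8)
        p2 = np.array([BB, AA, AA], dtype=np.int8)
        f1 = np.array([AB, AA, BB], dtype=np.int8)
        # marker 3 excluded (parent heterozygous); both others concordant
        assert f1_concordance(f1, p1, p2) == 1.0

    def test_discordant_counted(self):
        p1 = np.array([AA, AA], dtype=np.int8)
        p2 = np.array([BB, BB], dtype=np.int8)
        f1 = np.array([AB, AA], dtype=np.int8)
        assert f1_concordance(f1, p1, p2) == pytest.approx(0.5)

    def test_x_chromosome_excluded(self):
        p1 = np.array([AA, AA], dtype=np.int8)
        p2 = np.array([BB, BB], dtype=np.int8)
        f1 = np.array([AB, AA], dtype=np.int8)
        chroms = np.array(["1", "X"])
        assert f1_concordance(f1, p1, p2, chromosomes=chroms) == 1.0

    def test_no_eligible_markers(self):
        p1 = np.array([AB], dtype=np.int8)
        p2 = np.array([AA], dtype=np.int8)
        with pytest.raises(ValueError):
            f1_concordance(np.array([AA], dtype=np.int8), p1, p2)


def _calls(dom, mus, cas):
    """One-marker panel: per-subspecies call lists -> (1, n) matrix + labels."""
    rows = dom + mus + cas
    labels = ["dom"] * len(dom) + ["mus"] * len(mus) + ["cas"] * len(cas)
    return np.array(rows, dtype=np.int8)[None, :], labels


def test_allele_frequency_table_maf():
    # dom: BB, AB, AA -> 3 alt copies of 6 -> freq 0.5; mus: 1 of 4 -> 0.25
    calls, labels = _calls([BB, AB, AA], [AB, AA], [AA, N])
    table = allele_frequencies(["m"], calls, labels)
    assert table.maf("dom")[0] == pytest.approx(0.5)
    assert table.maf("mus")[0] == pytest.approx(0.25)
    assert table.call_counts["cas"][0] == 1  # no-call excluded
    assert table.maf("cas")[0] == pytest.approx(0.0)
    assert all(
        (table.alt_counts[s] <= 2 * table.call_counts[s]).all()
        for s in ("dom", "mus", "cas")
    )


class TestFindDiagnostic:
    def test_exclusive_allele(self):
        calls, labels = _calls([BB, BB], [AA, AA, AA], [AA, AA, AA])
        cat = find_diagnostic(["m"], calls, labels)
        assert cat.diagnostic_for["m"] == frozenset({"dom"})

    def test_two_mismatches_allowed(self):
        calls, labels = _calls([BB, BB], [AB, AB], [AA, AA])
        cat = find_diagnostic(["m"], calls, labels, max_mismatch=2)
        assert "dom" in cat.diagnostic_for.get("m", frozenset())
        assert cat.n_carriers_outside["m"]["dom"] == 2

    def test_three_outside_carriers_not_diagnostic(self):
        calls, labels = _calls([BB, BB], [AB, AB, AB], [AA, AA])
        cat = find_diagnostic(["m"], calls, labels, max_mismatch=2)
        assert "dom" not in cat.diagnostic_for.get("m", frozenset())

    def test_allele_shared_by_two_subspecies_never_diagnostic_at_zero(self):
        # alt allele carried in both dom and mus: exclusive to neither
        calls, labels = _calls([BB, BB], [BB, AA], [AA, AA])
        cat = find_diagnostic(["m"], calls, labels, max_mismatch=0)
        alleles = cat.diagnostic_allele.get("m", {})
        assert list(alleles.values()).count("alt") == 0


class TestAugmentDensity:
    def _catalog(self, markers):
        return DiagnosticCatalog(
            diagnostic_for={m: frozenset({"dom"}) for m in markers},
            diagnostic_allele={m: {"dom": "B"} for m in markers},
        )

    def test_region_already_dense_unchanged(self):
        cands = {"dom": [(f"m{i}", 100_000 + i * 200_000, 0.4) for i in range(5)]}
        cat = self._catalog([c[0] for c in cands["dom"]])
        res = augment_density(cat, cands, region=(1, 1_000_000))
        assert res.added["dom"] == []
        assert not res.deficits

    def test_fills_to_target_density(self):
        # stage-0 catalog empty; one high-MAF candidate every 150 kb
        cands = {"dom": [(f"m{i}", 1 + i * 150_000, 0.48) for i in range(20)]}
        cat = self._catalog([])
        res = augment_density(cat, cands, region=(1, 3_000_000))
        pos = sorted(
            p for mid, p, _ in cands["dom"] if mid in res.selected["dom"]
        )
        pts = [1] + pos + [3_000_000]
        assert max(b - a for a, b in zip(pts, pts[1:])) <= 300_000
        assert not res.deficits

    def test_zero_candidates_reported_as_deficit(self):
        cat = self._catalog([])
        res = augment_density(cat, {"dom": []}, region=(1, 1_000_000))
        assert any(d[0] == "dom" for d in res.deficits)
        assert res.selected.get("mus") is None  # no mus candidates supplied

    def test_never_removes_existing_markers(self):
        cands = {"dom": [("keep", 500_000, 0.1), ("new", 100_000, 0.4)]}
        cat = self._catalog(["keep"])
        res = augment_density(cat, cands, region=(1, 2_000_000))
        assert "keep" in res.selected["dom"]

    def test_recomb_interval_gets_random_pick(self):
        cands = {"dom": [(f"m{i}", 50_000 + i * 10_000, 0.3) for i in range(3)]}
        cat = self._catalog([])
        res = augment_density(
            cat, cands, region=(1, 200_000),
            recomb_intervals=[(40_000, 90_000)], seed=11,
        )
        assert any(
            40_000 <= p <= 90_000
            for mid, p, _ in cands["dom"] if mid in res.selected["dom"]
        )


class TestRecodeForPhylogeny:
    def test_codes_distinct_and_allelic_for_homs(self, rng):
        calls = np.array([[AA, BB, AB, N]], dtype=np.int8).T.reshape(1, 4)
        chars = recode_for_phylogeny(
            calls, ["s1", "s2", "s3", "s4"], [("T", "G")], seed=0
        )
        codes = {chars[s][0] for s in chars}
        assert len(codes) == 4  # all four states distinguishable
        assert chars["s1"][0] == "T" and chars["s2"][0] == "G"
        assert chars["s3"][0] in "AC" and chars["s4"][0] in "AC"

    def test_deterministic_under_seed(self, rng):
        calls = rng.integers(0, 4, size=(30, 6)).astype(np.int8)
        alleles = [("T", "G")] * 15 + [("A", "C")] * 15
        samples = [f"s{i}" for i in range(6)]
        a = recode_for_phylogeny(calls, samples, alleles, seed=99)
        b = recode_for_phylogeny(calls, samples, alleles, seed=99)
        assert a == b

    def test_codes_shared_across_samples(self, rng):
        calls = np.array([[AB, AB, N, N]], dtype=np.int8).reshape(1, 4)
        chars = recode_for_phylogeny(
            calls, ["a", "b", "c", "d"], [("T", "G")], seed=1
        )
        assert chars["a"] == chars["b"]
        assert chars["c"] == chars["d"]
        assert chars["a"] != chars["c"]

    def test_degenerate_alleles_rejected(self):
        with pytest.raises(ValueError):
            recode_for_phylogeny(
                np.array([[AA]], dtype=np.int8), ["s"], [("T", "T")], seed=0
            )
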