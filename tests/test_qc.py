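"""Quality-control statistics: d, K, call-rate flags, sex, tiers."""

import numpy as np
import pytest
from scipy import stats

from mugakit.datamodel import Call, GenotypeMatrix, SampleInfo
from mugakit.qc import (
    QCConfig,
    assign_tiers,
    callrate_flags,
    compute_d,
    ks_flag,
    sex_check,
)
from mugakit.synthetic import SimConfig, draw_d


class TestComputeD:
    def test_three_four_five(self):
        assert compute_d(0.6, 0.8) == pytest.approx(1.0)

    def test_axis_case_equals_channel_sum(self):
        assert compute_d(1.0, 0.0) == pytest.approx(1.0)

    def test_origin(self):
        assert compute_d(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_d(-0.1, 1.0)

    def test_d_bounded_by_R(self, rng):
        x, y = rng.random(100), rng.random(100)
        d = compute_d(x, y)
        assert (d <= x + y + 1e-12).all()
        assert compute_d(0.7, 0.0) == pytest.approx(0.7)  # equality on an axis


def ecdf_ks_oracle(values, mean, sd):
    """Two-sided KS by explicit ECDF evaluation at the sample points."""
    v = np.sort(values)
    n = len(v)
    cdf = stats.norm(mean, sd).cdf(v)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return max(upper.max(), lower.max())


class TestKSFlag:
    def test_distributional_identity_not_flagged(self):
        cfg = QCConfig()
        q = stats.norm(cfg.ref_mean, cfg.ref_sd).ppf(
            (np.arange(10_000) + 0.5) / 10_000
        )
        K, flagged = ks_flag(q)
        assert K <= 0.01 and not flagged

    def test_failed_array_flagged_and_matches_oracle(self, rng):
        cfg = SimConfig(seed=7)
        d = draw_d("failed", 5000, cfg, rng)
        K, flagged = ks_flag(d)
        assert flagged and K > 0.1
        assert K == pytest.approx(ecdf_ks_oracle(d, 0.97, 0.42), abs=1e-12)

    def test_reference_draws_below_threshold(self, rng):
        d = np.maximum(rng.normal(0.97, 0.42, 141_090), 0.0)
        K, flagged = ks_flag(d)
        assert K < 0.1 and not flagged

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            ks_flag(rng.normal(1, 0.4, 99))

    def test_order_invariant_and_bounded(self, rng):
        d = rng.normal(0.5, 0.3, 500).clip(0)
        K1, _ = ks_flag(d)
        K2, _ = ks_flag(d[::-1].copy())
        assert K1 == K2 and 0.0 <= K1 <= 1.0


def _geno_for(counts):
    """Build a 1-sample genotype matrix with given call counts."""
    calls = np.concatenate([
        np.full(n, code, dtype=np.int8)
        for code, n in counts.items()
    ])
    markers = [f"m{i}" for i in range(len(calls))]
    return GenotypeMatrix(markers, ["s1"], calls[:, None])


class TestCallrateFlags:
    def _run(self, group, counts, n_markers=None):
        geno = _geno_for(counts)
        cfg = QCConfig(full_array_markers=n_markers or len(geno.markers))
        info = [SampleInfo("s1", group)]
        return callrate_flags(geno, info, cfg)["s1"]

    def test_classical_inbred_het_boundary(self):
        flags = self._run("classical_inbred", {Call.AA: 1000, Call.AB: 2001})
        assert "het_fail" in flags
        flags = self._run("classical_inbred", {Call.AA: 1000, Call.AB: 2000})
        assert "het_fail" not in flags

    def test_other_mus_missing_strict_boundary(self):
        flags = self._run("other_mus", {Call.AA: 1000, Call.N: 45_000})
        assert "missing_fail" not in flags
        flags = self._run("other_mus", {Call.AA: 1000, Call.N: 45_001})
        assert "missing_fail" in flags

    def test_musculus_missing_threshold(self):
        flags = self._run("do", {Call.AA: 1000, Call.N: 15_001})
        assert "missing_fail" in flags

    def test_het_rule_restricted_to_classical_inbreds(self):
        flags = self._run("do", {Call.AA: 1000, Call.AB: 30_000})
        assert "het_fail" not in flags

    def test_thresholds_scale_with_subset(self):
        # 10x smaller array: the het bound shrinks proportionally
        geno = _geno_for({Call.AA: 1000, Call.AB: 300})
        cfg = QCConfig(full_array_markers=13_000)
        flags = callrate_flags(geno, [SampleInfo("s1", "classical_inbred")], cfg)
        assert "het_fail" in flags["s1"]


class TestSexCheck:
    def _panel(self):
        from mugakit.synthetic import simulate_panel, simulate_intensities

        panel = simulate_panel(SimConfig(seed=42))
        inten = simulate_intensities(panel)
        return panel, inten

    def test_recovers_known_sexes(self):
        panel, inten = self._panel()
        result = sex_check(panel.genotypes, inten, panel.manifest, panel.samples)
        for info in panel.samples:
            sex, mismatch = result[info.sample_id]
            assert sex == panel.truth.sample_sex[info.sample_id]
            assert not mismatch

    def test_flags_planted_swap(self):
        panel, inten = self._panel()
        swapped = []
        for info in panel.samples:
            s = SampleInfo(info.sample_id, info.group,
                           known_sex=info.known_sex,
                           strain_or_parents=info.strain_or_parents)
            swapped.append(s)
        victim = swapped[0]
        victim.known_sex = "M" if victim.known_sex == "F" else "F"
        result = sex_check(panel.genotypes, inten, panel.manifest, swapped)
        assert result[victim.sample_id][1] is True
        assert sum(m for _, m in result.values()) == 1

    def test_female_zero_good_y_calls(self):
        panel, inten = self._panel()
        marker_idx = {m: i for i, m in enumerate(panel.genotypes.markers)}
        y_rows = [marker_idx[m.marker_id] for m in panel.manifest
                  if m.chromosome == "Y"]
        females = [s for s, x in panel.truth.sample_sex.items() if x == "F"]
        for s in females:
            calls = panel.genotypes.sample_calls(s)[y_rows]
            assert (calls == Call.N).all()

    def test_no_y_markers_rejected(self):
        panel, inten = self._panel()
        autosomal = [m for m in panel.manifest if m.chromosome != "Y"]
        with pytest.raises(ValueError):
            sex_check(panel.genotypes, inten, autosomal, panel.samples)


class TestAssignTiers:
    def _tiers(self, calls):
        calls = np.asarray(calls, dtype=np.int8)[None, :]
        geno = GenotypeMatrix(["m"], [f"s{i}" for i in range(calls.shape[1])], calls)
        return assign_tiers(geno)["m"]

    def test_all_three_states_tier1(self):
        calls = [Call.AA] * 5 + [Call.AB] + [Call.BB] * 2
        assert self._tiers(calls) == 1

    def test_no_het_tier2(self):
        calls = [Call.AA] * 5 + [Call.BB] * 2
        assert self._tiers(calls) == 2

    def test_single_state_tier3(self):
        calls = [Call.AA] * 10
        assert self._tiers(calls) == 3

    def test_exact_ten_percent_nocall_is_tier4(self):
        calls = [Call.AA] * 17 + [Call.AB] * 5 + [Call.BB] * 5 + [Call.N] * 3
        assert len(calls) == 30
        assert self._tiers(calls) == 4

    def test_partition_is_exhaustive_and_idempotent(self, rng):
        calls = rng.integers(0, 4, size=(200, 30)).astype(np.int8)
        geno = GenotypeMatrix(
            [f"m{i}" for i in range(200)], [f"s{j}" for j in range(30)], calls
        )
        t1 = assign_tiers(geno)
        t2 = assign_tiers(geno)
        assert t1 == t2
        assert set(t1) == set(geno.markers)
        assert set(t1.values()) <= {1, 2, 3, 4}
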