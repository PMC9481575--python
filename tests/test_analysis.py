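"""Nucleosome counting, fiber-model fitting, cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import chromopull as cp
from chromopull.wlc import InsufficientDataError


class TestCountTotal:
    def test_bare_dna_counts_zero(self, wlc_lambda):
        tr = cp.generate_trace(cp.FiberSpec(n_octamers=0, seed=1))
        assert cp.count_total_nucleosomes(tr, wlc_lambda) == 0

    def test_round_trip_30_nucleosomes(self):
        spec = cp.FiberSpec(n_octamers=30, L_DNA_bp=12_000, seed=4)
        tr = cp.generate_trace(spec)
        wlc = cp.WLCParams(contour_bp=12_000)
        assert abs(cp.count_total_nucleosomes(tr, wlc) - 30) <= 1

    def test_saturated_lambda_cohort(self):
        # fully saturated lambda fiber: 198 nucleosomes, mean count +-2%
        spec = cp.FiberSpec(n_octamers=198, n_folded=68, seed=0)
        traces, _ = cp.generate_cohort(8, spec, seed=21)
        wlc = cp.WLCParams(contour_bp=cp.LAMBDA_DNA_BP)
        counts = [cp.count_total_nucleosomes(t, wlc) for t in traces]
        assert np.mean(counts) == pytest.approx(198, rel=0.02)

    def test_invariant_to_low_force_ruptures(self):
        # loops rupturing below 8 pN must not move the 8-15 pN count
        base = cp.FiberSpec(n_octamers=30, L_DNA_bp=14_000, seed=9)
        with_loops = base.replace(loops=((600.0, 2.5), (1200.0, 6.0)))
        wlc = cp.WLCParams(contour_bp=14_000)
        n_plain = cp.count_total_nucleosomes(cp.generate_trace(base), wlc)
        n_loops = cp.count_total_nucleosomes(cp.generate_trace(with_loops), wlc)
        assert n_plain == n_loops == 30

    def test_window_not_covered(self, wlc_lambda):
        spec = cp.FiberSpec(n_octamers=10, L_DNA_bp=5_000, seed=2)
        ramp = cp.ForceRamp(f_min_pN=0.3, f_max_pN=5.0)
        tr = cp.generate_trace(spec, protocol=ramp)
        with pytest.raises(InsufficientDataError):
            cp.count_total_nucleosomes(tr, cp.WLCParams(contour_bp=5_000))


class TestCountFolded:
    def test_beads_on_string_counts_zero(self):
        spec = cp.FiberSpec(n_octamers=40, L_DNA_bp=12_000, n_folded=0, seed=3)
        tr = cp.generate_trace(spec)
        wlc = cp.WLCParams(contour_bp=12_000)
        assert cp.count_folded_nucleosomes(tr, wlc, 197.0, 40) == 0

    def test_round_trip_random_fibers(self):
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(12):
            n = int(rng.integers(20, 60))
            nf = int(rng.integers(0, n + 1))
            L = int(n * 200 + rng.integers(4000, 12000))
            spec = cp.FiberSpec(
                n_octamers=n, n_folded=nf, L_DNA_bp=L,
                seed=int(rng.integers(2**31)),
            )
            tr = cp.generate_trace(spec)
            wlc = cp.WLCParams(contour_bp=L)
            n_tot = cp.count_total_nucleosomes(tr, wlc)
            got = cp.count_folded_nucleosomes(tr, wlc, 197.0, n_tot)
            errors.append(got - nf)
        assert max(abs(e) for e in errors) <= 2


class TestFoldedFraction:
    @pytest.mark.parametrize(
        "nf, nt, expected", [(49, 125, 39), (68, 198, 34), (0, 50, 0)]
    )
    def test_printed_values(self, nf, nt, expected):
        assert cp.folded_fraction(nf, nt) == expected

    def test_undefined_for_empty(self):
        with pytest.raises(ValueError):
            cp.folded_fraction(0, 0)

    @given(nf=st.integers(0, 200), scale=st.integers(2, 5))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_scale_equivariance(self, nf, scale):
        nt = 200
        assert cp.folded_fraction(nf, nt) == cp.folded_fraction(nf * scale, nt * scale)


class TestFitFiberParams:
    def test_recovery_small_cohort(self):
        # truth (k 0.25 pN/nm, dG1 20 kT, dG2 4.5 kT) with 10 nm noise
        spec = cp.FiberSpec(n_octamers=40, L_DNA_bp=12_000, seed=0)
        traces, _ = cp.generate_cohort(8, spec, seed=33)
        wlc = cp.WLCParams(contour_bp=12_000)
        ks, g1s, g2s = [], [], []
        for tr in traces:
            nt = cp.count_total_nucleosomes(tr, wlc)
            nf = cp.count_folded_nucleosomes(tr, wlc, 197.0, nt)
            res = cp.fit_fiber_params(tr, nt, nf, wlc, 197.0)
            assert res.success
            ks.append(res.k_fiber)
            g1s.append(res.dG1_kT)
            g2s.append(res.dG2_kT)
        assert np.median(ks) == pytest.approx(0.25, rel=0.10)
        assert np.median(g1s) == pytest.approx(20.0, rel=0.10)
        assert np.median(g2s) == pytest.approx(4.5, rel=0.10)

    def test_dG2_in_printed_range(self):
        # '601'-like cohort: fitted dG2 stays inside the reported 3.9-5.2 kT
        spec = cp.FiberSpec(
            n_octamers=30, L_DNA_bp=8_000, NRL_bp=197.0,
            folded_fraction=0.55, seed=0,
        )
        traces, _ = cp.generate_cohort(6, spec, seed=8)
        wlc = cp.WLCParams(contour_bp=8_000)
        g2s = []
        for tr in traces:
            nt = cp.count_total_nucleosomes(tr, wlc)
            nf = cp.count_folded_nucleosomes(tr, wlc, 197.0, nt)
            g2s.append(cp.fit_fiber_params(tr, nt, nf, wlc, 197.0).dG2_kT)
        assert 3.9 <= np.median(g2s) <= 5.2

    def test_bare_dna_degenerate(self, wlc_lambda):
        tr = cp.generate_trace(cp.FiberSpec(n_octamers=0, seed=6))
        res = cp.fit_fiber_params(tr, 0, 0, wlc_lambda)
        assert "degenerate" in res.flags
        assert not res.success
        assert np.isnan(res.k_fiber)


class TestSummarizeCohort:
    @staticmethod
    def _result(**kw):
        base = dict(
            N_total=100, N_folded=40, k_fiber=0.25, dG1_kT=20.0, dG2_kT=4.5,
            contour_bp_fitted=48_502.0, residual_rms_nm=12.0,
        )
        base.update(kw)
        return cp.TraceFitResult(**base)

    def test_constant_group_collapses(self):
        results = [self._result() for _ in range(5)]
        s = cp.summarize_cohort(results, ["a"] * 5, parameters=("k_fiber",))
        row = s.stats.iloc[0]
        assert row["sd"] == 0.0
        assert row["p5"] == row["p95"] == row["mean"] == 0.25

    def test_known_distribution(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.25, 0.05, 1000)
        results = [self._result(k_fiber=float(v)) for v in vals]
        s = cp.summarize_cohort(results, ["a"] * 1000, parameters=("k_fiber",))
        row = s.stats.iloc[0]
        se_mean = 0.05 / np.sqrt(1000)
        assert abs(row["mean"] - 0.25) < 3 * se_mean
        se_sd = 0.05 / np.sqrt(2 * 999)
        assert abs(row["sd"] - 0.05) < 3 * se_sd

    def test_identical_groups_rarely_significant(self):
        # null calibration of the Welch test across seeded replicates
        rng = np.random.default_rng(12)
        n_nonsig = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(20, 3, 30)
            b = rng.normal(20, 3, 30)
            results = [self._result(dG1_kT=float(v)) for v in np.concatenate([a, b])]
            groups = ["a"] * 30 + ["b"] * 30
            s = cp.summarize_cohort(results, groups, parameters=("dG1_kT",))
            if s.pairwise.iloc[0]["p_value"] > 0.05:
                n_nonsig += 1
        assert n_nonsig >= int(0.95 * reps) - 2

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.2, 0.05, 25), rng.normal(0.3, 0.05, 25)
        results = [self._result(k_fiber=float(v)) for v in np.concatenate([a, b])]
        s = cp.summarize_cohort(
            results, ["a"] * 25 + ["b"] * 25, parameters=("k_fiber",)
        )
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert s.pairwise.iloc[0]["p_value"] == pytest.approx(expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cp.summarize_cohort([], [])

    def test_percentile_ordering(self):
        rng = np.random.default_rng(9)
        results = [self._result(k_fiber=float(v)) for v in rng.uniform(0.1, 0.5, 50)]
        s = cp.summarize_cohort(results, ["g"] * 50, parameters=("k_fiber",))
        row = s.stats.iloc[0]
        assert row["p5"] <= row["mean"] <= row["p95"]
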