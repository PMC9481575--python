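"""Rupture detection, filtering, classification and rate normalization."""

import types

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromopull as cp
from chromopull.ruptures import (
    KLASS_HIGH,
    KLASS_LOW,
    KLASS_UNSTICKING,
    RuptureEvent,
    events_to_frame,
)


class TestMedianFilter:
    def test_constant_unchanged(self):
        x = np.full(50, 3.7)
        assert np.array_equal(cp.median_filter(x), x)

    def test_spike_removed(self):
        x = np.zeros(60)
        x[30] = 1e6
        assert np.all(cp.median_filter(x) == 0.0)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        got = cp.median_filter(x, 15)
        # independent oracle: explicit median over each centered, shrunken
        # window
        expect = np.array(
            [np.median(x[max(i - 7, 0):min(i + 8, x.size)]) for i in range(x.size)]
        )
        assert np.allclose(got, expect)

    @given(window=st.integers(3, 21).filter(lambda w: w % 2 == 1),
           n=st.integers(5, 80))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_length_preserved(self, window, n):
        x = np.arange(n, dtype=float)
        assert cp.median_filter(x, window).size == n

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            cp.median_filter(np.zeros(10), 14)


class TestDetectSteps:
    def test_smooth_trace_no_events(self, wlc_lambda):
        tr = cp.generate_trace(cp.FiberSpec(n_octamers=0, seed=2))
        assert cp.detect_steps(tr, wlc_lambda) == []

    def test_three_inserted_loops_recovered(self, wlc_lambda):
        spec = cp.FiberSpec(
            n_octamers=125, seed=105,
            loops=((400.0, 3.0), (1000.0, 5.0), (2500.0, 12.0)),
        )
        tr = cp.generate_trace(spec)
        events = cp.analyze_trace_ruptures(tr, wlc_lambda)
        kept = [e for e in events if e.klass in (KLASS_LOW, KLASS_HIGH)]
        assert len(kept) == 3
        for truth_bp, truth_f in ((400.0, 3.0), (1000.0, 5.0), (2500.0, 12.0)):
            match = [e for e in kept if abs(e.rupture_force - truth_f) < 0.4]
            assert len(match) == 1
            assert match[0].step_bp == pytest.approx(truth_bp, rel=0.10)

    def test_150bp_step_below_threshold(self, wlc_lambda):
        # 150 bp is below the 200 bp (68 nm) detection threshold
        spec = cp.FiberSpec(n_octamers=0, seed=3, loops=((150.0, 5.0),))
        tr = cp.generate_trace(spec, noise_nm=0.0)
        assert cp.detect_steps(tr, wlc_lambda) == []

    def test_kept_events_exceed_200bp(self, wlc_lambda):
        rng = np.random.default_rng(4)
        for _ in range(5):
            loops = tuple(
                (float(rng.uniform(300, 3000)), float(rng.uniform(1.2, 14)))
                for _ in range(3)
            )
            tr = cp.generate_trace(
                cp.FiberSpec(n_octamers=60, L_DNA_bp=30_000, seed=int(rng.integers(1e6)),
                             loops=loops)
            )
            for e in cp.detect_steps(tr, cp.WLCParams(contour_bp=30_000)):
                if e.kept:
                    assert e.step_bp > 200.0
                    assert e.step_nm > 0.0

    def test_merged_events_respect_join_gap(self, wlc_lambda):
        rng = np.random.default_rng(6)
        for _ in range(5):
            loops = tuple(
                (float(rng.uniform(400, 2000)), float(rng.uniform(1.2, 7.5)))
                for _ in range(4)
            )
            tr = cp.generate_trace(
                cp.FiberSpec(n_octamers=125, seed=int(rng.integers(1e6)), loops=loops)
            )
            events = cp.detect_steps(tr, wlc_lambda)
            idx = sorted(e.sample_index for e in events)
            gaps = np.diff(idx)
            # joining is exhaustive: surviving events are >= join_gap apart
            assert np.all(gaps >= 5)

    def test_unsorted_time_rejected(self, wlc_lambda):
        stub = types.SimpleNamespace(
            time_s=np.array([0.0, 2.0, 1.0]),
            force_pN=np.array([1.0, 2.0, 3.0]),
            extension_nm=np.zeros(3),
            metadata={},
            n_samples=3,
        )
        with pytest.raises(ValueError):
            cp.detect_steps(stub, wlc_lambda)


class TestFilterUnsticking:
    def test_zero_dR_kept(self, wlc_lambda):
        spec = cp.FiberSpec(n_octamers=125, seed=11, loops=((1500.0, 4.0),))
        tr = cp.generate_trace(spec, xy_noise_um=0.0)
        events = cp.filter_unsticking(cp.detect_steps(tr, wlc_lambda), tr)
        loop_ev = [e for e in events if abs(e.rupture_force - 4.0) < 0.4]
        assert len(loop_ev) == 1
        assert loop_ev[0].dR_um == pytest.approx(0.0, abs=1e-12)
        assert loop_ev[0].kept

    def test_lateral_jump_discarded(self, wlc_lambda):
        # a 0.2 um lateral jump coincident with the step marks unsticking
        spec = cp.FiberSpec(n_octamers=125, seed=12)
        tr0 = cp.generate_trace(spec)
        jump_idx = int(np.argmax(tr0.force_pN >= 4.0))
        tr = cp.generate_trace(
            spec, unsticking_jumps=((jump_idx, 400.0, 0.2, 0.0),)
        )
        events = cp.filter_unsticking(cp.detect_steps(tr, cp.WLCParams(48_502)), tr)
        near = [e for e in events if abs(e.sample_index - jump_idx) < 10]
        assert len(near) == 1
        assert near[0].klass == KLASS_UNSTICKING
        assert near[0].dR_um > 0.1

    def test_empty_events_pass_through(self, lambda_fiber_trace):
        assert cp.filter_unsticking([], lambda_fiber_trace) == []

    def test_no_xy_flagged(self, wlc_lambda):
        spec = cp.FiberSpec(n_octamers=125, seed=13, loops=((1500.0, 4.0),))
        tr = cp.generate_trace(spec)
        tr_noxy = cp.Trace(
            time_s=tr.time_s, force_pN=tr.force_pN,
            extension_nm=tr.extension_nm, metadata=tr.metadata,
        )
        events = cp.filter_unsticking(cp.detect_steps(tr_noxy, wlc_lambda), tr_noxy)
        assert events and all("no_xy" in e.flags for e in events)
        assert all(np.isnan(e.dR_um) for e in events)


class TestClassify:
    @pytest.mark.parametrize("force, expected", [(3.0, KLASS_LOW), (12.0, KLASS_HIGH),
                                                 (8.0, KLASS_HIGH), (7.999, KLASS_LOW)])
    def test_boundaries(self, force, expected):
        ev = RuptureEvent(
            sample_index=10, end_index=11, time_s=1.0, rupture_force=force,
            step_nm=100.0, step_bp=300.0,
        )
        assert cp.classify_ruptures([ev])[0].klass == expected


def _fake_trace(template_bp, trace_id="t"):
    t = np.arange(10.0)
    return cp.Trace(
        time_s=t, force_pN=np.linspace(1, 10, 10), extension_nm=np.zeros(10),
        metadata={"trace_id": trace_id, "template_bp": template_bp},
    )


def _fake_event(force, step_bp=500.0, klass=KLASS_LOW, trace_id="t"):
    return RuptureEvent(
        sample_index=1, end_index=2, time_s=0.1, rupture_force=force,
        step_nm=step_bp * 0.34, step_bp=step_bp, klass=klass, trace_id=trace_id,
    )


class TestRateNormalization:
    def test_no_events_zero_rate(self):
        rep = cp.rupture_rate_per_10kbp([], [_fake_trace(25_000)])
        assert rep.rate_per_10kbp == 0.0

    def test_arithmetic(self):
        # 5 low events over two 25 kbp traces -> 1.0 per 10 kbp
        traces = [_fake_trace(25_000, "a"), _fake_trace(25_000, "b")]
        events = [_fake_event(float(f)) for f in (2, 3, 4, 5, 6)]
        rep = cp.rupture_rate_per_10kbp(events, traces)
        assert rep.rate_per_10kbp == pytest.approx(1.0)
        assert rep.n_low == 5

    def test_high_class_excluded_from_rate(self):
        traces = [_fake_trace(50_000)]
        events = [_fake_event(3.0), _fake_event(12.0, klass=KLASS_HIGH)]
        rep = cp.rupture_rate_per_10kbp(events, traces)
        assert rep.n_low == 1 and rep.n_high == 1
        assert rep.rate_per_10kbp == pytest.approx(0.2)

    def test_additive_over_cohorts(self):
        ta = [_fake_trace(20_000, "a")]
        tb = [_fake_trace(30_000, "b")]
        ea = [_fake_event(2.0, trace_id="a") for _ in range(3)]
        eb = [_fake_event(4.0, trace_id="b") for _ in range(6)]
        ra = cp.rupture_rate_per_10kbp(ea, ta).rate_per_10kbp
        rb = cp.rupture_rate_per_10kbp(eb, tb).rate_per_10kbp
        rab = cp.rupture_rate_per_10kbp(ea + eb, ta + tb).rate_per_10kbp
        assert rab == pytest.approx((ra * 20 + rb * 30) / 50)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            cp.rupture_rate_per_10kbp([], [])


class TestProjectCount:
    def test_identity_at_reference(self):
        assert cp.project_count(37, 48_548) == pytest.approx(37.0)

    def test_halved_template_doubles(self):
        assert cp.project_count(10, 24_274) == pytest.approx(20.0)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            cp.project_count(10, 0)


def test_events_to_frame_columns():
    df = events_to_frame([_fake_event(3.0)])
    assert list(df.columns) == [
        "trace_id", "sample_index", "time_s", "rupture_force_pN",
        "step_nm", "step_bp", "dR_um", "class",
    ]
    assert df.iloc[0]["class"] == KLASS_LOW
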