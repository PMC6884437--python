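"""Windowing, per-step CL computation, and the gated update rule."""

import numpy as np
import pytest

from infoload import (
    BaselineWindow,
    Branch,
    SyntheticSpec,
    WindowSpec,
    compute_cl_step,
    compute_cl_trace,
    constrained_update,
    generate_session,
    preprocess_session,
    segment_windows,
    trace_median,
)

FS = 10.0


def enumerate_window_count(task_n: int, win: int, hop: int, borrow: bool) -> int:
    """Independent oracle: enumerate admissible window end offsets."""
    if borrow:
        # windows end at hop, 2*hop, ... within the task; early ones reach
        # back into the rest period
        return sum(1 for end in range(hop, task_n + 1, hop))
    count = 0
    start = 0
    while start + win <= task_n:
        count += 1
        start += hop
    return count


class TestSegmentWindows:
    def test_seventy_second_task_gives_seven_windows(self, rng):
        windows = segment_windows(rng.standard_normal(700), rng.standard_normal(600), FS)
        assert len(windows) == 7
        assert all(w.size == 200 for w in windows)

    def test_twenty_second_task_gives_two_windows(self, rng):
        windows = segment_windows(rng.standard_normal(200), rng.standard_normal(600), FS)
        assert len(windows) == 2

    def test_no_borrow_seventy_seconds_gives_six(self, rng):
        spec = WindowSpec(first_window_borrows_rest=False)
        windows = segment_windows(rng.standard_normal(700), rng.standard_normal(600), FS, spec)
        assert len(windows) == 6

    def test_first_window_content(self, rng):
        rest, task = rng.standard_normal(600), rng.standard_normal(700)
        w = segment_windows(task, rest, FS)
        assert np.array_equal(w[0], np.concatenate([rest[-100:], task[:100]]))
        assert np.array_equal(w[1], task[0:200])
        assert np.array_equal(w[2], task[100:300])

    @pytest.mark.parametrize("task_s", range(20, 181, 20))
    @pytest.mark.parametrize("win_s,step_s", [(20, 10), (20, 5), (10, 10), (10, 5)])
    def test_count_matches_enumeration_oracle(self, rng, task_s, win_s, step_s):
        spec = WindowSpec(window_s=win_s, step_s=step_s)
        task = rng.standard_normal(int(task_s * FS))
        rest = rng.standard_normal(600)
        got = len(segment_windows(task, rest, FS, spec))
        expected = enumerate_window_count(task.size, int(win_s * FS), int(step_s * FS), True)
        assert got == expected
        # with borrowing the count collapses to floor(task_s / step_s)
        assert got == int(task_s // step_s)

    def test_insufficient_rest_names_shortfall(self, rng):
        with pytest.raises(ValueError, match="short by 40"):
            segment_windows(rng.standard_normal(700), rng.standard_normal(60), FS)


class TestComputeClStep:
    def test_identical_window_and_baseline_gives_zero(self, rng):
        x = rng.standard_normal(200)
        d = compute_cl_step(x, BaselineWindow(x.copy()), bins=16)
        assert d.cl_raw == pytest.approx(0.0, abs=1e-12)

    def test_independent_window_keeps_entropy(self):
        g = np.random.default_rng(8)
        x = g.standard_normal(5000)
        b = BaselineWindow(g.standard_normal(5000))
        d = compute_cl_step(x, b, bins=8)
        assert d.cl_raw == pytest.approx(d.h_x, abs=0.1)

    def test_raw_cl_identity_and_bounds_fuzz(self):
        """cl_raw = h_x - mi to machine precision; 0 <= cl_raw <= h_x."""
        for seed in range(1000):
            g = np.random.default_rng(seed)
            x = g.normal(0, g.uniform(0.5, 2.0), 200)
            b = BaselineWindow(g.normal(0, g.uniform(0.5, 2.0), 200))
            d = compute_cl_step(x, b)
            assert d.cl_raw == pytest.approx(d.h_x - d.mi_xb, abs=1e-10)
            assert 0.0 <= d.cl_raw <= d.h_x + 1e-12

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="length"):
            compute_cl_step(rng.standard_normal(100), BaselineWindow(rng.standard_normal(200)))


def _completed(diag):
    return diag if diag.complete else None


class TestConstrainedUpdate:
    def _step(self, rng, mi, dkl, cl_raw=1.0, final=None):
        from infoload.cogload import StepDiagnostics
        return StepDiagnostics(
            tau=1, h_x=2.0, mi_xb=mi, dkl_xb=dkl, cl_raw=cl_raw,
            cl_final=cl_raw if final is None else final, branch=Branch.FIRST_STEP,
        )

    def test_mi_down_dkl_up_is_direct(self, rng):
        prev = self._step(rng, mi=0.5, dkl=0.2)
        from infoload.cogload import StepDiagnostics
        cur = StepDiagnostics(tau=2, h_x=2.0, mi_xb=0.4, dkl_xb=0.3, cl_raw=1.6)
        out = constrained_update(prev, cur, rng.standard_normal(200), rng.standard_normal(200))
        assert out.branch is Branch.DIRECT
        assert out.cl_final == out.cl_raw == 1.6

    def test_mi_up_dkl_down_is_direct(self, rng):
        prev = self._step(rng, mi=0.5, dkl=0.2)
        from infoload.cogload import StepDiagnostics
        cur = StepDiagnostics(tau=2, h_x=2.0, mi_xb=0.6, dkl_xb=0.2, cl_raw=1.4)
        out = constrained_update(prev, cur, rng.standard_normal(200), rng.standard_normal(200))
        assert out.branch is Branch.DIRECT

    def test_both_up_is_averaged_and_convex(self, rng):
        prev = self._step(rng, mi=0.5, dkl=0.2, cl_raw=1.0)
        from infoload.cogload import StepDiagnostics
        cur = StepDiagnostics(tau=2, h_x=2.0, mi_xb=0.6, dkl_xb=0.3, cl_raw=1.8)
        out = constrained_update(prev, cur, rng.standard_normal(200), rng.standard_normal(200))
        assert out.branch is Branch.AVERAGED
        assert out.alpha + out.beta == pytest.approx(1.0, abs=1e-12)
        assert min(1.0, 1.8) <= out.cl_final <= max(1.0, 1.8)

    def test_identical_windows_fall_back_to_half_weights(self, rng):
        x = rng.standard_normal(200)
        prev = self._step(rng, mi=0.5, dkl=0.2, cl_raw=1.0)
        from infoload.cogload import StepDiagnostics
        cur = StepDiagnostics(tau=2, h_x=2.0, mi_xb=0.6, dkl_xb=0.3, cl_raw=2.0)
        out = constrained_update(prev, cur, x, x.copy())
        assert out.branch is Branch.AVERAGED
        assert out.alpha == out.beta == 0.5
        assert out.cl_final == pytest.approx(1.5)

    def test_recursive_variant_uses_smoothed_previous(self, rng):
        prev = self._step(rng, mi=0.5, dkl=0.2, cl_raw=1.0, final=0.4)
        from infoload.cogload import StepDiagnostics
        cur = StepDiagnostics(tau=2, h_x=2.0, mi_xb=0.6, dkl_xb=0.3, cl_raw=1.8)
        xp, xc = rng.standard_normal(200), rng.standard_normal(200)
        plain = constrained_update(prev, cur, xp, xc)
        recur = constrained_update(prev, cur, xp, xc, recursive=True)
        assert recur.cl_final == pytest.approx(
            plain.cl_final - plain.alpha * (1.0 - 0.4)
        )


class TestTrace:
    def test_synthetic_session_trace_invariants(self, synthetic_session):
        trace = compute_cl_trace(preprocess_session(synthetic_session), "L3")
        assert len(trace.steps) == 7
        assert [s.tau for s in trace.steps] == list(range(1, 8))
        assert trace.steps[0].branch is Branch.FIRST_STEP
        assert trace.steps[0].cl_final == trace.steps[0].cl_raw
        for s in trace.steps:
            assert s.cl_final >= 0.0
            assert s.cl_raw <= s.h_x + 1e-12
            if s.branch is Branch.AVERAGED:
                assert s.alpha + s.beta == pytest.approx(1.0, abs=1e-9)

    def test_task_duplicating_baseline_gives_zero_median(self, rng):
        """A task that replays the baseline in every window has zero CL."""
        from infoload import ChannelMeta, NirsSession
        period = rng.standard_normal(100)
        # a 100-sample-periodic signal makes every 20-s window (at 10-s steps)
        # identical, sample for sample, to the 20-s baseline
        rest = np.tile(period, 6)
        task = np.tile(period, 7)
        samples = np.concatenate([rest, task])[:, None]
        session = NirsSession(samples=samples, channels=(ChannelMeta("L3", 3.0),),
                              rest_end_index=600)
        trace = compute_cl_trace(session, "L3")
        assert max(s.cl_raw for s in trace.steps) == pytest.approx(0.0, abs=1e-12)
        assert trace_median(trace) == pytest.approx(0.0, abs=1e-12)

    def test_trace_deterministic(self, synthetic_session):
        pp = preprocess_session(synthetic_session)
        a = compute_cl_trace(pp, "L3")
        b = compute_cl_trace(pp, "L3")
        assert [s.cl_final for s in a.steps] == [s.cl_final for s in b.steps]

    def test_short_rest_for_baseline_rejected(self, rng):
        from infoload import ChannelMeta, NirsSession
        session = NirsSession(
            samples=rng.standard_normal((900, 1)),
            channels=(ChannelMeta("L3", 3.0),), rest_end_index=210,
        )
        with pytest.raises(ValueError, match="baseline"):
            compute_cl_trace(session, "L3", WindowSpec(window_s=30.0, step_s=10.0))


class TestTraceMedian:
    @pytest.mark.parametrize(
        "values, expected",
        [([1.0, 2.0, 3.0], 2.0), ([1.0, 2.0, 3.0, 10.0], 2.5), ([4.2], 4.2)],
    )
    def test_median_rules(self, values, expected, rng):
        from infoload.cogload import CLTrace, StepDiagnostics
        steps = tuple(
            StepDiagnostics(tau=i + 1, h_x=5.0, mi_xb=0.0, dkl_xb=0.0,
                            cl_raw=v, cl_final=v, branch=Branch.DIRECT)
            for i, v in enumerate(values)
        )
        trace = CLTrace(steps=steps, spec=WindowSpec(), bins=16, channel="L3")
        assert trace_median(trace) == pytest.approx(expected)
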