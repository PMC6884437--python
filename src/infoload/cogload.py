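"""Windowed cognitive-load estimation with a gated, VI-weighted update rule.

The cognitive load of a task-period window X_t given the resting baseline B
is the conditional entropy

    CL(X_t) = H(X_t | B) = H(X_t) - MI(X_t; B),

i.e. the window's information content after discounting whatever it still
shares with the pre-task resting activity. Entropy alone would overestimate
load because residual resting activity carries over into the task period,
and that residue cannot be removed by mean subtraction (entropy is
translation-invariant).

Raw step-to-step CL differences can also reflect spontaneous hemodynamic
fluctuation rather than a change in load. A genuine load change must move
mutual information and distribution divergence in *opposite* directions
(more load -> less resemblance to rest -> lower MI and higher D_KL). Each
step is therefore gated: if MI and D_KL with respect to the baseline moved
consistently with a real change, the raw conditional entropy is accepted;
otherwise the current and previous conditional entropies are averaged with
weights derived from the variation of information between the two windows,

    alpha = H(X_{t-1} | X_t) / VI,   beta = H(X_t | X_{t-1}) / VI,

which sum to one exactly (VI = H(X_{t-1}|X_t) + H(X_t|X_{t-1})).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from . import infotheory as it
from .nirs_io import NirsSession, select_channel

logger = logging.getLogger(__name__)


class Branch(str, Enum):
    """Which arm of the gated update produced a step's final CL."""

    FIRST_STEP = "first_step"
    DIRECT = "direct"
    AVERAGED = "averaged"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout over the task period.

    window_s                 : window length in seconds (default 20).
    step_s                   : hop between consecutive windows (default 10).
    first_window_borrows_rest: when True, the first window spans the last
                               (window_s - step_s) seconds of rest plus the
                               first step_s seconds of task, so estimation
                               starts one step after task onset.
    """

    window_s: float = 20.0
    step_s: float = 10.0
    first_window_borrows_rest: bool = True

    def __post_init__(self):
        if not (0 < self.step_s <= self.window_s):
            raise ValueError(
                f"need 0 < step_s ({self.step_s}) <= window_s ({self.window_s})"
            )

    def window_n(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def step_n(self, fs: float) -> int:
        return int(round(self.step_s * fs))


@dataclass(frozen=True)
class BaselineWindow:
    """The conditioning window B: the final window_s seconds of rest."""

    samples: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float).ravel()
        if arr.size == 0 or not np.all(np.isfinite(arr)):
            raise ValueError("baseline window must be non-empty and finite")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StepDiagnostics:
    """Every quantity entering one CL estimation step.

    cl_raw is H(X_t|B) from the shared joint histogram of (X_t, B); cl_final
    is cl_raw on the direct/first-step branches, or the alpha/beta-weighted
    average of the two raw conditional entropies on the averaged branch.
    """

    tau: int
    h_x: float
    mi_xb: float
    dkl_xb: float
    cl_raw: float
    cl_final: float = float("nan")
    branch: Branch | None = None
    alpha: float = float("nan")
    beta: float = float("nan")
    vi_prev: float = float("nan")

    @property
    def complete(self) -> bool:
        return self.branch is not None


@dataclass(frozen=True)
class CLTrace:
    """Ordered per-window CL estimates with full step diagnostics."""

    steps: tuple[StepDiagnostics, ...]
    spec: WindowSpec
    bins: int
    channel: str

    def __post_init__(self):
        steps = tuple(self.steps)
        if not steps:
            raise ValueError("trace must contain at least one step")
        if [s.tau for s in steps] != list(range(1, len(steps) + 1)):
            raise ValueError("step indices must be consecutive from 1")
        object.__setattr__(self, "steps", steps)

    @property
    def cl_values(self) -> np.ndarray:
        return np.array([s.cl_final for s in self.steps])


def segment_windows(task, rest, fs: float, spec: WindowSpec | None = None) -> list[np.ndarray]:
    """Overlapping task-period windows, optionally borrowing the rest tail.

    With borrowing, window tau ends tau * step_s seconds after task onset
    and spans window_s seconds backwards, so early windows overlap the end
    of the rest period (window 1 is the last (window_s - step_s) seconds of
    rest plus the first step_s seconds of task) and the window count is
    floor(task_s / step_s). Without borrowing, windows slide through the
    task period only. Every window has exactly window_s * fs samples; a
    final partial window is never emitted.
    """
    spec = spec or WindowSpec()
    task = np.asarray(task, dtype=float).ravel()
    rest = np.asarray(rest, dtype=float).ravel()
    win = spec.window_n(fs)
    hop = spec.step_n(fs)
    windows: list[np.ndarray] = []
    if spec.first_window_borrows_rest:
        # window tau ends at tau*step_s into the task and reaches window_s
        # back, borrowing from the rest tail while the task is shorter than
        # a full window; the count is floor(task_s / step_s)
        borrow_max = win - hop
        if rest.size < borrow_max:
            raise ValueError(
                f"rest period has {rest.size} samples but the first window "
                f"borrows {borrow_max}; short by {borrow_max - rest.size}"
            )
        if task.size < hop:
            raise ValueError(
                f"task period has {task.size} samples; the first window needs "
                f"{hop}, short by {hop - task.size}"
            )
        joined = np.concatenate([rest, task]) if borrow_max else task
        offset = rest.size if borrow_max else 0
        end = hop
        while end <= task.size:
            windows.append(joined[offset + end - win: offset + end])
            end += hop
        return windows
    if task.size < win:
        raise ValueError(
            f"task period has {task.size} samples but a window needs {win}; "
            f"short by {win - task.size}"
        )
    start = 0
    while start + win <= task.size:
        windows.append(task[start: start + win])
        start += hop
    return windows


def compute_cl_step(x, b: BaselineWindow, bins: int = it.DEFAULT_BINS) -> StepDiagnostics:
    """One raw CL evaluation: H(X), MI(X;B), D_KL(X;B) and H(X|B).

    All entropy/MI terms come from one shared joint histogram of (X, B), so
    cl_raw = h_x - mi_xb holds to machine precision and 0 <= cl_raw <= h_x.
    The returned diagnostics are partial (no branch/final value yet).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(b):
        raise ValueError(f"window length {x.size} != baseline length {len(b)}")
    joint = it.build_joint_histogram(x, b.samples, bins)
    h_x = it.entropy(joint.marginal_x())
    mi = it.mutual_information_from_joint(joint)
    dkl = it.kl_divergence(x, b.samples, bins)
    return StepDiagnostics(
        tau=0, h_x=h_x, mi_xb=mi, dkl_xb=dkl, cl_raw=max(h_x - mi, 0.0),
    )


def constrained_update(
    prev: StepDiagnostics,
    cur: StepDiagnostics,
    x_prev,
    x_cur,
    bins: int = it.DEFAULT_BINS,
    recursive: bool = False,
) -> StepDiagnostics:
    """Complete the current step by gating it against the previous one.

    The direct branch fires when MI and D_KL with respect to the baseline
    moved in opposite directions across the step (a change consistent with a
    genuine load change); the inequality directions are exactly

        (MI_t <= MI_{t-1} and D_t > D_{t-1}) or (MI_t > MI_{t-1} and D_t <= D_{t-1}).

    Otherwise the step is smoothed: cl_final = alpha*CL_{t-1} + beta*CL_t
    with VI-derived weights. By default the averaged branch combines the two
    *raw* conditional entropies H(X_{t-1}|B) and H(X_t|B); with
    ``recursive=True`` it reuses the previous step's already-smoothed value.
    Identical consecutive windows give VI = 0; both weights are then 0.5 by
    continuity (both numerators vanish).
    """
    if not prev.complete:
        raise ValueError("previous step diagnostics are incomplete")
    direct = (
        (cur.mi_xb <= prev.mi_xb and cur.dkl_xb > prev.dkl_xb)
        or (cur.mi_xb > prev.mi_xb and cur.dkl_xb <= prev.dkl_xb)
    )
    if direct:
        return replace(cur, cl_final=cur.cl_raw, branch=Branch.DIRECT)
    joint = it.build_joint_histogram(
        np.asarray(x_prev, dtype=float).ravel(),
        np.asarray(x_cur, dtype=float).ravel(),
        bins,
    )
    hxy = it.joint_entropy(joint)
    h_prev_given_cur = hxy - it.entropy(joint.marginal_y())
    h_cur_given_prev = hxy - it.entropy(joint.marginal_x())
    vi = h_prev_given_cur + h_cur_given_prev
    if vi <= 0.0:
        alpha = beta = 0.5
        vi = max(vi, 0.0)
    else:
        alpha = h_prev_given_cur / vi
        beta = h_cur_given_prev / vi
    prev_cl = prev.cl_final if recursive else prev.cl_raw
    return replace(
        cur,
        cl_final=alpha * prev_cl + beta * cur.cl_raw,
        branch=Branch.AVERAGED,
        alpha=alpha,
        beta=beta,
        vi_prev=vi,
    )


def compute_cl_trace(
    session: NirsSession,
    channel: str,
    spec: WindowSpec | None = None,
    bins: int = it.DEFAULT_BINS,
    recursive: bool = False,
) -> CLTrace:
    """Full CL trace for one channel of a (preprocessed) session.

    The baseline is the final window_s seconds of the rest period. Step 1
    has no predecessor, so its final value is its raw conditional entropy;
    later steps pass through :func:`constrained_update`.
    """
    spec = spec or WindowSpec()
    rest, task = select_channel(session, channel)
    win = spec.window_n(session.fs)
    if rest.size < win:
        raise ValueError(
            f"rest period has {rest.size} samples; the {spec.window_s:g}-s "
            f"baseline needs {win}"
        )
    baseline = BaselineWindow(rest[rest.size - win:])
    windows = segment_windows(task, rest, session.fs, spec)
    steps: list[StepDiagnostics] = []
    for i, w in enumerate(windows):
        partial = compute_cl_step(w, baseline, bins)
        partial = replace(partial, tau=i + 1)
        if i == 0:
            steps.append(
                replace(partial, cl_final=partial.cl_raw, branch=Branch.FIRST_STEP)
            )
        else:
            steps.append(
                constrained_update(
                    steps[-1], partial, windows[i - 1], w, bins, recursive=recursive
                )
            )
    return CLTrace(steps=tuple(steps), spec=spec, bins=bins, channel=channel)


def trace_median(trace: CLTrace) -> float:
    """Median of the final per-step CL values (the session's load summary)."""
    return float(np.median(trace.cl_values))
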