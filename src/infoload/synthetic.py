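"""Synthetic NIRS session generator with controllable cognitive-load structure.

Each simulated session emulates a forehead total-blood-flow recording:
a resting period followed by a task period, sampled at 10 Hz, containing

* a per-channel band-limited (0.01-0.6 Hz) stochastic hemodynamic component
  whose task-period amplitude scales with the load level — the minimal
  mechanism an entropy-based load estimator should detect;
* sinusoidal systemic artifacts (cardiac ~1.1 Hz, respiration ~0.25 Hz,
  Mayer waves ~0.10 Hz) with random per-channel phases;
* a two-component skin-blood-flow (SBF) signal: a dominant series added to
  every channel with near-identical gains (global scalp perfusion) plus a
  weaker series with a left-right gradient pattern (asymmetric superficial
  flow). Together they occupy the two leading principal components of the
  rest period, which is exactly what the two-component PCA removal in the
  preprocessing chain assumes; a rank-one SBF would leave the second
  removed component pointing at an arbitrary direction of cortical signal,
  deleting a random fraction of the load signal per session;
* linear drift and white sensor noise.

Because the SBF components are, by design, fit on the rest period and
removed only from the task period, the rest-period baseline retains them.
The baseline's spread therefore exceeds the cleaned task windows' spread,
and the shared-alphabet histogram binning resolves the task amplitude —
this is what makes median CL increase with load level.

Load levels: the scalar ``load_level`` multiplies the task-period
hemodynamic amplitude (rest amplitude is load-independent); ``"low"`` and
``"high"`` map to 1.0 and 2.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .nirs_io import ChannelMeta, NirsSession

logger = logging.getLogger(__name__)

LOAD_LEVELS = {"low": 1.0, "high": 2.0}

#: default source-detector distances (cm) for the canonical 4-channel montage
_DEFAULT_MONTAGE = (("L1", 1.0), ("L3", 3.0), ("R1", 1.0), ("R3", 3.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters defining one simulated session.

    Amplitudes are in the same arbitrary units as the output samples.
    ``hemo_sigma`` is the rest-period (and unit-load task-period) standard
    deviation of the hemodynamic component; the task-period amplitude is
    ``hemo_sigma * load``.
    """

    fs: float = 10.0
    rest_s: float = 60.0
    task_s: float = 70.0
    n_channels: int = 4
    load_level: str | float = "low"
    hemo_sigma: float = 1.0
    hemo_band: tuple[float, float] = (0.01, 0.6)
    cardiac_hz: float = 1.1
    resp_hz: float = 0.25
    mayer_hz: float = 0.10
    artifact_amps: tuple[float, float, float] = (0.5, 0.3, 0.4)
    sbf_amp: float = 3.0
    sbf_lateral_ratio: float = 0.6
    sbf_band: tuple[float, float] = (0.1, 0.35)
    drift_slope: float = 0.01
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2.0 * self.cardiac_hz:
            raise ValueError(
                f"fs ({self.fs}) must exceed twice the cardiac frequency "
                f"({self.cardiac_hz})"
            )
        amps = (self.hemo_sigma, self.sbf_amp, self.noise_sigma, *self.artifact_amps)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if self.load < 0:
            raise ValueError(f"load_level must be >= 0, got {self.load_level!r}")
        if self.rest_s <= 0 or self.task_s <= 0 or self.n_channels < 1:
            raise ValueError("rest_s, task_s and n_channels must be positive")

    @property
    def load(self) -> float:
        if isinstance(self.load_level, str):
            try:
                return LOAD_LEVELS[self.load_level]
            except KeyError:
                raise ValueError(
                    f"load_level must be a number or one of {sorted(LOAD_LEVELS)}"
                ) from None
        return float(self.load_level)

    @property
    def n_rest(self) -> int:
        return int(round(self.rest_s * self.fs))

    @property
    def n_task(self) -> int:
        return int(round(self.task_s * self.fs))


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise confined to ``band`` (filtered with edge padding)."""
    pad = n  # generate double length and keep the tail to kill filter transients
    white = rng.standard_normal(n + pad)
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white)[pad:]
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_session(spec: SyntheticSpec, subject_id: str = "sim", condition: str = "") -> NirsSession:
    """Simulate one session; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    n_rest, n_task = spec.n_rest, spec.n_task
    n = n_rest + n_task
    t = np.arange(n) / spec.fs
    task_mask = np.arange(n) >= n_rest

    # two shared skin-blood-flow series for the whole session: a dominant
    # global component (near-identical gains, owns the first rest PC) and a
    # weaker left-right gradient component (owns the second)
    sbf_global = spec.sbf_amp * _bandlimited_noise(rng, n, spec.fs, spec.sbf_band)
    sbf_lateral = (
        spec.sbf_lateral_ratio * spec.sbf_amp
        * _bandlimited_noise(rng, n, spec.fs, spec.sbf_band)
    )
    g_global = 1.0 + 0.05 * rng.standard_normal(spec.n_channels)
    g_lateral = (
        np.linspace(1.0, -1.0, spec.n_channels)
        + 0.05 * rng.standard_normal(spec.n_channels)
    )

    samples = np.empty((n, spec.n_channels))
    art_freqs = (spec.cardiac_hz, spec.resp_hz, spec.mayer_hz)
    for ch in range(spec.n_channels):
        hemo = _bandlimited_noise(rng, n, spec.fs, spec.hemo_band)
        amp = np.where(task_mask, spec.hemo_sigma * spec.load, spec.hemo_sigma)
        sig = hemo * amp
        for freq, a in zip(art_freqs, spec.artifact_amps):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sig = sig + a * np.sin(2.0 * np.pi * freq * t + phase)
        sig = sig + g_global[ch] * sbf_global + g_lateral[ch] * sbf_lateral
        sig = sig + spec.drift_slope * t
        sig = sig + spec.noise_sigma * rng.standard_normal(n)
        samples[:, ch] = sig

    montage = _DEFAULT_MONTAGE if spec.n_channels == 4 else tuple(
        (f"C{i + 1}", 3.0) for i in range(spec.n_channels)
    )
    channels = tuple(ChannelMeta(lbl, dist) for lbl, dist in montage[: spec.n_channels])
    if isinstance(spec.load_level, str) and not condition:
        condition = spec.load_level
    return NirsSession(
        samples=samples,
        fs=spec.fs,
        channels=channels,
        rest_end_index=n_rest,
        subject_id=subject_id,
        condition=condition,
    )


@dataclass(frozen=True)
class CohortMember:
    """One simulated subject: a low-load and a high-load session."""

    subject_id: str
    low_session: NirsSession = field(repr=False)
    high_session: NirsSession = field(repr=False)


def generate_cohort(
    n_subjects: int,
    specs: tuple[SyntheticSpec, SyntheticSpec] | None = None,
    seed: int = 0,
    gain_sigma: float = 0.2,
    drift_jitter: float = 0.002,
) -> list[CohortMember]:
    """Simulate a cohort of paired low/high-load sessions.

    Per-subject variability: a multiplicative log-normal coupling gain
    (``exp(N(0, gain_sigma^2))``) and an additive normal drift perturbation
    (``N(0, drift_jitter)`` units/s on ``drift_slope``). The gain models
    optode-skin coupling efficiency and therefore scales *every* measured
    amplitude (hemodynamic, SBF, artifacts, noise) identically; it is shared
    between a subject's two sessions, as coupling and anatomy are
    per-subject, not per-condition.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if specs is None:
        specs = (
            SyntheticSpec(load_level="low"),
            SyntheticSpec(load_level="high"),
        )
    low_spec, high_spec = specs
    root = np.random.SeedSequence(seed)
    cohort = []
    for i, subj_seq in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(subj_seq)
        gain = float(np.exp(gain_sigma * rng.standard_normal()))
        drift_delta = float(drift_jitter * rng.standard_normal())
        session_seeds = rng.integers(0, 2**31 - 1, size=2)
        subject_id = f"sim{i + 1:03d}"

        def _perturb(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
            return replace(
                spec,
                hemo_sigma=spec.hemo_sigma * gain,
                sbf_amp=spec.sbf_amp * gain,
                noise_sigma=spec.noise_sigma * gain,
                artifact_amps=tuple(a * gain for a in spec.artifact_amps),
                drift_slope=spec.drift_slope + drift_delta,
                seed=seed,
            )

        low = generate_session(
            _perturb(low_spec, int(session_seeds[0])), subject_id=subject_id
        )
        high = generate_session(
            _perturb(high_spec, int(session_seeds[1])), subject_id=subject_id
        )
        cohort.append(CohortMember(subject_id, low, high))
    return cohort
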