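"""Signal conditioning for NIRS sessions: bandpass, detrend, SBF removal.

The chain mirrors standard fNIRS practice for single-wavelength total
blood-flow recordings:

1. first-order Butterworth bandpass (0.01-0.6 Hz) to attenuate cardiac
   pulsation, respiration aliases and very slow drift;
2. linear detrending;
3. skin-blood-flow (SBF) attenuation: the leading principal components of
   the rest-period multi-channel recording are taken to represent the
   superficial, scalp-borne signal shared across channels, and their span
   is projected out of the task-period recording.

The PCA step treats channels as variables and time points as observations.
Centering always uses rest-period channel means, so SBF removal is an affine
correction fit on rest data only and applied to the task period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning-chain parameters.

    low_cut/high_cut : bandpass corner frequencies in Hz.
    filter_order     : Butterworth order (1 = first-order design).
    zero_phase       : forward-backward filtering (no phase lag) when True;
                       a causal single-pass variant for strict-online use
                       when False.
    n_sbf_components : number of leading rest-period principal components
                       removed from the task period (0 disables removal).
    """

    low_cut: float = 0.01
    high_cut: float = 0.6
    filter_order: int = 1
    zero_phase: bool = True
    n_sbf_components: int = 2

    def validate(self, fs: float, n_channels: int | None = None) -> None:
        if not (0.0 < self.low_cut < self.high_cut < fs / 2.0):
            raise ValueError(
                f"cutoffs must satisfy 0 < low ({self.low_cut}) < high "
                f"({self.high_cut}) < fs/2 ({fs / 2.0})"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.n_sbf_components < 0:
            raise ValueError("n_sbf_components must be >= 0")
        if n_channels is not None and self.n_sbf_components >= n_channels:
            raise ValueError(
                f"n_sbf_components ({self.n_sbf_components}) must be smaller "
                f"than the channel count ({n_channels})"
            )


def min_filter_length(fs: float, cfg: PreprocessConfig) -> int:
    """Minimum input length for stable filtering.

    Three times the longest filter time constant, 1/(2*pi*low_cut); shorter
    inputs raise rather than being silently padded.
    """
    tau_s = 1.0 / (2.0 * np.pi * cfg.low_cut)
    return int(np.ceil(3.0 * tau_s * fs))


def bandpass(x, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Butterworth bandpass of a 1-D signal (or column-wise for 2-D)."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    arr = np.asarray(x, dtype=float)
    n = arr.shape[0]
    n_min = min_filter_length(fs, cfg)
    if n < n_min:
        raise ValueError(
            f"signal too short for stable filtering: {n} samples < "
            f"minimum {n_min} (3x the {1/(2*np.pi*cfg.low_cut):.1f}-s "
            "filter time constant)"
        )
    sos = sps.butter(
        cfg.filter_order, [cfg.low_cut, cfg.high_cut], btype="bandpass",
        fs=fs, output="sos",
    )
    if cfg.zero_phase:
        return sps.sosfiltfilt(sos, arr, axis=0)
    return sps.sosfilt(sos, arr, axis=0)


def detrend_linear(x) -> np.ndarray:
    """Remove the least-squares line (column-wise for 2-D input)."""
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("detrending needs at least 2 samples")
    return sps.detrend(arr, axis=0, type="linear")


def _rest_pca_loadings(rest: np.ndarray, n_components: int) -> np.ndarray:
    """Orthonormal loadings (channels x k) of the rest-period covariance."""
    centered = rest - rest.mean(axis=0, keepdims=True)
    # SVD of time x channel matrix: right singular vectors are the loadings
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if rank < n_components:
        logger.warning(
            "rest matrix rank %d < requested %d SBF components; using %d",
            rank, n_components, rank,
        )
        n_components = rank
    return vt[:n_components].T


def sbf_attenuate(rest, task, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Project rest-period principal components out of the task period.

    Loadings are fit on the channel-wise-centered rest matrix; the task
    matrix is centered with the *rest* channel means, its projection onto
    the leading loadings subtracted. The result is the centered, SBF-cleaned
    task matrix (same shape as ``task``).
    """
    cfg = cfg or PreprocessConfig()
    rest = np.asarray(rest, dtype=float)
    task = np.asarray(task, dtype=float)
    if rest.ndim != 2 or task.ndim != 2 or rest.shape[1] != task.shape[1]:
        raise ValueError("rest and task must be [time x channel] with equal channel sets")
    n_ch = rest.shape[1]
    if cfg.n_sbf_components >= n_ch:
        raise ValueError(
            f"n_sbf_components ({cfg.n_sbf_components}) must be smaller than "
            f"the channel count ({n_ch})"
        )
    if rest.shape[0] < n_ch + 1:
        raise ValueError("rest period must have more time samples than channels")
    rest_means = rest.mean(axis=0, keepdims=True)
    task_c = task - rest_means
    if cfg.n_sbf_components == 0:
        return task_c
    w = _rest_pca_loadings(rest, cfg.n_sbf_components)  # channels x k
    return task_c - (task_c @ w) @ w.T


def preprocess_session(session, cfg: PreprocessConfig | None = None):
    """Apply the full chain (filter -> detrend -> SBF removal) to a session.

    The whole recording is filtered and detrended jointly, then split at the
    rest/task boundary; SBF components are fit on the rest part only and
    removed from the task part only. The rest part is likewise centered with
    rest-period channel means so both halves live in one affine frame.
    Returns a new session with identical metadata.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(session.fs, n_channels=session.n_channels)
    filtered = bandpass(session.samples, session.fs, cfg)
    detrended = detrend_linear(filtered)
    rest = detrended[: session.rest_end_index]
    task = detrended[session.rest_end_index:]
    cleaned_task = sbf_attenuate(rest, task, cfg)
    rest_centered = rest - rest.mean(axis=0, keepdims=True)
    samples = np.vstack([rest_centered, cleaned_task])
    return replace(session, samples=samples)
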