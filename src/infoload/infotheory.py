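"""Histogram plug-in estimators of information quantities over signal windows.

All quantities (entropy, joint/conditional entropy, mutual information,
Kullback-Leibler divergence, variation of information) are computed from
equal-width histograms in a common discrete alphabet, in bits by default.

The plug-in estimator is used deliberately: every algebraic identity the
cognitive-load update rule relies on —

    H(X|B) = H(X) - MI(X;B)
    VI(X,Y) = H(X) + H(Y) - 2 MI(X;Y) = H(X|Y) + H(Y|X)

holds to machine precision when all terms are derived from one shared joint
histogram, which is not true of k-NN or kernel estimators.

Binning conventions
-------------------
* Pairwise quantities (MI, conditional entropy, VI) bin both series with one
  shared set of equal-width edges spanning the pooled min-max of the two
  inputs, so both live in a common alphabet.
* Half-open bins ``[e_i, e_{i+1})`` with the final bin closed on the right.
* Values outside the edge range are clipped into the terminal bins, with a
  warning.
* KL divergence applies Jeffreys smoothing (+0.5 pseudo-count per bin to
  both histograms, then renormalisation) so it is finite and zero iff the
  two smoothed histograms coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BINS = 16
"""Default bin count, sized for the 200-sample (20 s at 10 Hz) windows."""

_PROB_ATOL = 1e-9


def _as_finite_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


@dataclass(frozen=True)
class HistogramModel:
    """A 1-D probability histogram over explicit bin edges."""

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least 2 bin edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if probs.shape != (edges.size - 1,):
            raise ValueError("probs length must equal number of bins")
        if np.any(probs < -_PROB_ATOL):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probs", probs)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1


@dataclass(frozen=True)
class JointHistogram:
    """A 2-D probability histogram; marginals are exact row/column sums."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        ex = np.asarray(self.edges_x, dtype=float)
        ey = np.asarray(self.edges_y, dtype=float)
        pr = np.asarray(self.probs, dtype=float)
        if not (np.all(np.diff(ex) > 0) and np.all(np.diff(ey) > 0)):
            raise ValueError("bin edges must be strictly increasing")
        if pr.shape != (ex.size - 1, ey.size - 1):
            raise ValueError("probs shape must match edge counts")
        if abs(pr.sum() - 1.0) > 1e-6 or np.any(pr < -_PROB_ATOL):
            raise ValueError("probs must be a probability matrix")
        object.__setattr__(self, "edges_x", ex)
        object.__setattr__(self, "edges_y", ey)
        object.__setattr__(self, "probs", pr)

    def marginal_x(self) -> HistogramModel:
        return HistogramModel(self.edges_x, self.probs.sum(axis=1))

    def marginal_y(self) -> HistogramModel:
        return HistogramModel(self.edges_y, self.probs.sum(axis=0))


def _digitize(x: np.ndarray, edges: np.ndarray, name: str = "input") -> np.ndarray:
    """Bin indices with half-open bins, last bin closed, out-of-range clipped."""
    n_out = np.count_nonzero((x < edges[0]) | (x > edges[-1]))
    if n_out:
        logger.warning(
            "%d %s value(s) outside histogram range [%g, %g]; clipped into terminal bins",
            n_out, name, edges[0], edges[-1],
        )
        warnings.warn(f"{n_out} {name} value(s) clipped into terminal bins", stacklevel=3)
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def equal_width_edges(lo: float, hi: float, bins: int) -> np.ndarray:
    """Equal-width edges on [lo, hi]; degenerate ranges get a unit-width pad."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if hi <= lo:
        # all-identical samples: centre a unit-width support on the value
        lo, hi = lo - 0.5, lo + 0.5
    return np.linspace(lo, hi, bins + 1)


def build_histogram(x, edges) -> HistogramModel:
    """Histogram of ``x`` over explicit ``edges`` (probabilities, not counts)."""
    arr = _as_finite_1d(x, "x")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least 2 bin edges")
    idx = _digitize(arr, edges, "histogram")
    counts = np.bincount(idx, minlength=edges.size - 1).astype(float)
    return HistogramModel(edges, counts / arr.size)


def build_joint_histogram(x, y, bins: int = DEFAULT_BINS) -> JointHistogram:
    """Joint histogram of index-paired samples on shared pooled-range edges."""
    ax = _as_finite_1d(x, "x")
    ay = _as_finite_1d(y, "y")
    if ax.size != ay.size:
        raise ValueError(f"length mismatch: {ax.size} vs {ay.size}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    pooled = np.concatenate([ax, ay])
    edges = equal_width_edges(pooled.min(), pooled.max(), bins)
    ix = _digitize(ax, edges)
    iy = _digitize(ay, edges)
    counts = np.zeros((bins, bins))
    np.add.at(counts, (ix, iy), 1.0)
    return JointHistogram(edges, edges, counts / ax.size)


def entropy(h: HistogramModel) -> float:
    """Shannon entropy in bits: -sum p log2 p over p > 0."""
    return float(-_xlog2x(h.probs).sum())


def entropy_of(x, bins: int = DEFAULT_BINS) -> float:
    """Entropy of one window, binned over its own min-max range."""
    arr = _as_finite_1d(x, "x")
    edges = equal_width_edges(arr.min(), arr.max(), bins)
    return entropy(build_histogram(arr, edges))


def joint_entropy(j: JointHistogram) -> float:
    """Joint Shannon entropy in bits over the probability matrix."""
    return float(-_xlog2x(j.probs).sum())


def mutual_information_from_joint(j: JointHistogram) -> float:
    """MI = H(X) + H(Y) - H(X,Y), all terms from the one joint histogram."""
    mi = entropy(j.marginal_x()) + entropy(j.marginal_y()) - joint_entropy(j)
    # plug-in MI from a shared joint is non-negative up to rounding
    assert mi > -1e-9, f"negative MI {mi} from shared joint"
    return max(mi, 0.0)


def mutual_information(x, y, bins: int = DEFAULT_BINS) -> float:
    """Mutual information in bits between index-paired series."""
    j = build_joint_histogram(x, y, bins)
    mi = mutual_information_from_joint(j)
    hx = entropy(j.marginal_x())
    hy = entropy(j.marginal_y())
    assert mi <= min(hx, hy) + 1e-9, "MI exceeded a marginal entropy"
    return mi


def conditional_entropy(x, y, bins: int = DEFAULT_BINS) -> float:
    """H(X|Y) = H(X,Y) - H(Y) in bits, from one shared joint histogram."""
    j = build_joint_histogram(x, y, bins)
    return max(joint_entropy(j) - entropy(j.marginal_y()), 0.0)


def kl_divergence(p_samples, q_samples, bins: int = DEFAULT_BINS) -> float:
    """D_KL(P || Q) in bits between two sample distributions.

    Histograms share equal-width edges over the pooled range; lengths may
    differ. Jeffreys smoothing (+0.5 per bin, then renormalise) keeps the
    divergence finite and zero iff the smoothed histograms are equal.
    """
    ap = _as_finite_1d(p_samples, "p_samples")
    aq = _as_finite_1d(q_samples, "q_samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    pooled = np.concatenate([ap, aq])
    edges = equal_width_edges(pooled.min(), pooled.max(), bins)
    cp = np.bincount(_digitize(ap, edges), minlength=bins).astype(float)
    cq = np.bincount(_digitize(aq, edges), minlength=bins).astype(float)
    p = (cp + 0.5) / (cp.sum() + 0.5 * bins)
    q = (cq + 0.5) / (cq.sum() + 0.5 * bins)
    dkl = float(np.sum(p * np.log2(p / q)))
    assert dkl > -1e-9, "KL divergence must be non-negative (Gibbs inequality)"
    return max(dkl, 0.0)


def variation_of_information(x, y, bins: int = DEFAULT_BINS) -> float:
    """VI(X,Y) = H(X|Y) + H(Y|X) in bits, from one shared joint histogram.

    Computed both as H(X)+H(Y)-2MI and as the sum of the two conditional
    entropies; the two forms agree exactly because every term comes from the
    same joint, and that agreement is asserted.
    """
    j = build_joint_histogram(x, y, bins)
    hx = entropy(j.marginal_x())
    hy = entropy(j.marginal_y())
    hxy = joint_entropy(j)
    mi = hx + hy - hxy
    vi_sum_form = hx + hy - 2.0 * mi          # 2*H(X,Y) - H(X) - H(Y)
    vi_cond_form = (hxy - hy) + (hxy - hx)
    assert abs(vi_sum_form - vi_cond_form) < 1e-9
    return max(vi_sum_form, 0.0)
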