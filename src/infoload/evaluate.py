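"""Evaluation machinery: confusion metrics, rank statistics, bootstraps.

Covers the analyses used to validate the CL pipeline:

* binary labels from an 8-point self-assessment questionnaire (1-4 easy,
  5-8 difficult) and the confusion counts / accuracy / precision / recall /
  F1 they induce;
* the paired "higher-load median exceeds lower-load median" accuracy
  criterion;
* Wilcoxon rank-sum and Spearman rank statistics with the z-based effect
  size r = z / sqrt(N);
* three percentile-bootstrap procedures (one-sample mean, paired Spearman
  correlation, and KL divergence between two CL samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .infotheory import DEFAULT_BINS, kl_divergence

logger = logging.getLogger(__name__)

EASY = "easy"
DIFFICULT = "difficult"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency counts with "difficult" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_matrix(self) -> np.ndarray:
        """[[tp, fn], [fp, tn]] — rows: reference difficult/easy."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/precision/recall/F1; undefined ratios are None, never 0."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap point estimate, CI and optional two-tailed p."""

    point: float
    ci_low: float
    ci_high: float
    level: float
    n_resamples: int
    boot_mean: float
    boot_sd: float
    p_two_tailed: float | None = None

    @property
    def excludes_zero(self) -> bool:
        """True when the CI lies strictly on one side of zero (H0 rejected)."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def label_from_questionnaire(score: int) -> str:
    """Map an 8-point self-assessed difficulty score to a binary label."""
    score = int(score)
    if not 1 <= score <= 8:
        raise ValueError(f"questionnaire score must be in 1..8, got {score}")
    return EASY if score <= 4 else DIFFICULT


def confusion(predictions, references) -> ConfusionCounts:
    """Confusion counts over paired label sequences ("difficult" positive)."""
    preds = list(predictions)
    refs = list(references)
    if not preds or len(preds) != len(refs):
        raise ValueError(
            f"predictions ({len(preds)}) and references ({len(refs)}) must be "
            "non-empty and equal-length"
        )
    valid = {EASY, DIFFICULT}
    if not (set(preds) <= valid and set(refs) <= valid):
        raise ValueError(f"labels must be one of {sorted(valid)}")
    tp = sum(p == DIFFICULT and r == DIFFICULT for p, r in zip(preds, refs))
    tn = sum(p == EASY and r == EASY for p, r in zip(preds, refs))
    fp = sum(p == DIFFICULT and r == EASY for p, r in zip(preds, refs))
    fn = sum(p == EASY and r == DIFFICULT for p, r in zip(preds, refs))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts."""
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise ValueError("precision + recall must be positive")
    return 2.0 * precision * recall / (precision + recall)


def median_accuracy_criterion(medians_low, medians_high) -> float:
    """Fraction of subjects whose high-load median strictly exceeds the low.

    Ties count as failures (strict inequality).
    """
    lo = np.asarray(medians_low, dtype=float)
    hi = np.asarray(medians_high, dtype=float)
    if lo.size == 0 or lo.shape != hi.shape:
        raise ValueError("paired median sequences must be non-empty and equal-length")
    return float(np.mean(hi > lo))


def rank_tests(a, b) -> dict:
    """Two-sample Wilcoxon rank-sum and Spearman correlation.

    Returns both the raw rank-sum statistic and its normal approximation z,
    with the effect size r = z / sqrt(N) (N = combined sample size), plus
    the Spearman rho/p when the inputs are paired (equal length) and
    non-constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("rank tests need at least 2 observations per sample")
    rs = stats.ranksums(a, b)
    n_total = a.size + b.size
    # scipy's ranksums statistic *is* the z-approximation; recover the raw
    # rank sum of the first sample for completeness
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_raw = float(ranks[: a.size].sum())
    out = {
        "ranksum_z": float(rs.statistic),
        "ranksum_w": w_raw,
        "ranksum_p": float(rs.pvalue),
        "effect_size_r": float(rs.statistic / np.sqrt(n_total)),
        "n": int(n_total),
        "spearman_rho": None,
        "spearman_p": None,
    }
    if a.size == b.size:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("constant input; Spearman correlation undefined")
        else:
            rho = stats.spearmanr(a, b)
            out["spearman_rho"] = float(rho.statistic)
            out["spearman_p"] = float(rho.pvalue)
    return out


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")


def bootstrap_one_sample(
    diffs, level: float = 0.99, n: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Percentile bootstrap of a sample mean (e.g. paired CL differences).

    H0 (zero mean) is rejected when zero falls outside the CI; the result's
    ``excludes_zero`` property reports that decision.
    """
    _check_level(level)
    arr = np.asarray(diffs, dtype=float)
    if arr.size == 0:
        raise ValueError("diffs must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = _percentile_ci(means, level)
    return BootstrapResult(
        point=float(arr.mean()), ci_low=lo, ci_high=hi, level=level,
        n_resamples=n, boot_mean=float(means.mean()), boot_sd=float(means.std(ddof=1)),
    )


def bootstrap_correlation(
    x, y, level: float = 0.95, n: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Paired bootstrap of the Spearman correlation.

    Pairs are resampled jointly; the two-tailed p is the fraction of the
    bootstrap distribution whose absolute correlation exceeds the absolute
    observed correlation.
    """
    _check_level(level)
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size != ay.size or ax.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    rng = np.random.default_rng(seed)
    observed = float(stats.spearmanr(ax, ay).statistic)
    boots = np.empty(n)
    for i in range(n):
        idx = rng.integers(0, ax.size, size=ax.size)
        xs, ys = ax[idx], ay[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            boots[i] = 0.0
        else:
            boots[i] = stats.spearmanr(xs, ys).statistic
    lo, hi = _percentile_ci(boots, level)
    p = float(np.mean(np.abs(boots) > abs(observed)))
    return BootstrapResult(
        point=observed, ci_low=lo, ci_high=hi, level=level, n_resamples=n,
        boot_mean=float(boots.mean()), boot_sd=float(boots.std(ddof=1)),
        p_two_tailed=p,
    )


def bootstrap_kl(
    sample_a, sample_b, level: float = 0.99, n: int = 10_000,
    bins: int = DEFAULT_BINS, seed: int = 0,
) -> BootstrapResult:
    """Bootstrap of D_KL(A || B) between two CL samples.

    Each set is resampled independently per replicate. H0 is non-divergence
    (zero inside the CI); note the smoothed plug-in D_KL of finite samples
    is biased upward, so the CI lower bound sits near—not exactly at—zero
    under H0.
    """
    _check_level(level)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(seed)
    boots = np.empty(n)
    for i in range(n):
        ra = a[rng.integers(0, a.size, size=a.size)]
        rb = b[rng.integers(0, b.size, size=b.size)]
        boots[i] = kl_divergence(ra, rb, bins)
    lo, hi = _percentile_ci(boots, level)
    return BootstrapResult(
        point=kl_divergence(a, b, bins), ci_low=lo, ci_high=hi, level=level,
        n_resamples=n, boot_mean=float(boots.mean()), boot_sd=float(boots.std(ddof=1)),
    )
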