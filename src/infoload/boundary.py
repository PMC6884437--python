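"""Decision boundary between two cognitive-load populations.

Given the CL medians of a low-load condition (S1) and a high-load condition
(S2), the boundary 𝔻 is the midpoint between the extreme CL values that lie
*uniquely* in one set's range — the elements outside the two sets' overlap:

1. sort S1 descending and S2 ascending;
2. find the smallest element of S1 inside S2's range and the largest
   element of S2 inside S1's range (the overlap markers);
3. take the immediate S1 neighbour below the S1 marker and the immediate S2
   neighbour above the S2 marker;
4. average those two neighbours.

Elements falling in the closed overlap region are discarded from both sets
("refined" sets); the fitted boundary strictly separates the refined sets,
which is asserted on every fit. Session medians above the boundary classify
as "difficult", at or below as "easy".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

EASY = "easy"
DIFFICULT = "difficult"


class BoundaryFitError(ValueError):
    """The two CL sets cannot be separated (nested/identical ranges)."""


@dataclass(frozen=True, eq=False)
class DecisionBoundaryModel:
    """Fitted boundary 𝔻 plus the inputs, refined sets and discard counts."""

    d: float
    s1: np.ndarray
    s2: np.ndarray
    s1_refined: np.ndarray
    s2_refined: np.ndarray
    n_discarded_s1: int
    n_discarded_s2: int
    swapped: bool

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "s1": self.s1.tolist(),
            "s2": self.s2.tolist(),
            "s1_refined": self.s1_refined.tolist(),
            "s2_refined": self.s2_refined.tolist(),
            "n_discarded_s1": self.n_discarded_s1,
            "n_discarded_s2": self.n_discarded_s2,
            "swapped": self.swapped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecisionBoundaryModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            d=float(obj["d"]),
            s1=np.asarray(obj["s1"], dtype=float),
            s2=np.asarray(obj["s2"], dtype=float),
            s1_refined=np.asarray(obj["s1_refined"], dtype=float),
            s2_refined=np.asarray(obj["s2_refined"], dtype=float),
            n_discarded_s1=int(obj["n_discarded_s1"]),
            n_discarded_s2=int(obj["n_discarded_s2"]),
            swapped=bool(obj["swapped"]),
        )


def fit_decision_boundary(s1, s2) -> DecisionBoundaryModel:
    """Fit 𝔻 between a lower (s1) and a higher (s2) CL population.

    Fitting is label-agnostic: if median(s1) > median(s2) the inputs are
    swapped so s1 is always the lower set, and the swap is flagged. Disjoint
    ranges give the midpoint of the adjacent extremes with nothing
    discarded. A missing strict neighbour falls back to the set's own
    extreme (min(s1) or max(s2)) with a warning.
    """
    a1 = np.asarray(s1, dtype=float).ravel()
    a2 = np.asarray(s2, dtype=float).ravel()
    if a1.size < 2 or a2.size < 2:
        raise ValueError("each CL set needs at least 2 elements")
    if not (np.all(np.isfinite(a1)) and np.all(np.isfinite(a2))):
        raise ValueError("CL sets must be finite")
    if a1.size == a2.size and np.array_equal(np.sort(a1), np.sort(a2)):
        raise BoundaryFitError("the two CL sets are identical; no boundary exists")
    swapped = bool(np.median(a1) > np.median(a2))
    if swapped:
        a1, a2 = a2, a1
    s1_sorted = np.sort(a1)[::-1]  # descending
    s2_sorted = np.sort(a2)       # ascending

    lo2, hi2 = s2_sorted[0], s2_sorted[-1]
    lo1, hi1 = s1_sorted[-1], s1_sorted[0]
    in_s2 = a1[(a1 >= lo2) & (a1 <= hi2)]  # closed-interval membership
    in_s1 = a2[(a2 >= lo1) & (a2 <= hi1)]

    if in_s2.size == 0 and in_s1.size == 0:
        # disjoint ranges: midpoint of the adjacent extremes
        d = 0.5 * (hi1 + lo2)
        model = DecisionBoundaryModel(
            d=float(d), s1=a1, s2=a2, s1_refined=np.sort(a1), s2_refined=np.sort(a2),
            n_discarded_s1=0, n_discarded_s2=0, swapped=swapped,
        )
        _assert_separation(model)
        return model

    # overlap markers: smallest s1 element inside s2's range, largest s2
    # element inside s1's range; one-sided overlap keeps the other marker at
    # the opposing range edge so the discard region stays well-defined
    m1 = in_s2.min() if in_s2.size else lo2
    m2 = in_s1.max() if in_s1.size else hi1

    below = a1[a1 < m1]
    if below.size:
        neighbor1 = below.max()
    else:
        neighbor1 = lo1
        logger.warning(
            "no S1 element strictly below the overlap marker %g; using min(S1)=%g",
            m1, lo1,
        )
    above = a2[a2 > m2]
    if above.size:
        neighbor2 = above.min()
    else:
        neighbor2 = hi2
        logger.warning(
            "no S2 element strictly above the overlap marker %g; using max(S2)=%g",
            m2, hi2,
        )
    d = 0.5 * (neighbor1 + neighbor2)

    # refine: drop everything in the closed overlap of the two ranges,
    # [min(S2), max(S1)] — the region the markers delimit
    region_lo, region_hi = lo2, hi1
    keep1 = (a1 < region_lo) | (a1 > region_hi)
    keep2 = (a2 < region_lo) | (a2 > region_hi)
    s1_refined = np.sort(a1[keep1])
    s2_refined = np.sort(a2[keep2])
    if s1_refined.size == 0 or s2_refined.size == 0:
        raise BoundaryFitError(
            "no element survives overlap removal on one side "
            f"(|S1'|={s1_refined.size}, |S2'|={s2_refined.size}); the sets' "
            "ranges are nested or identical"
        )
    model = DecisionBoundaryModel(
        d=float(d), s1=a1, s2=a2, s1_refined=s1_refined, s2_refined=s2_refined,
        n_discarded_s1=int(a1.size - s1_refined.size),
        n_discarded_s2=int(a2.size - s2_refined.size),
        swapped=swapped,
    )
    _assert_separation(model)
    return model


def _assert_separation(model: DecisionBoundaryModel) -> None:
    if not (
        np.all(model.s1_refined < model.d) and np.all(model.s2_refined > model.d)
    ):
        raise BoundaryFitError(
            f"fitted boundary {model.d:g} does not separate the refined sets "
            f"(S1' max {model.s1_refined.max():g}, S2' min {model.s2_refined.min():g})"
        )


def classify_median(median_cl: float, model: DecisionBoundaryModel) -> str:
    """Label a session median: above 𝔻 -> difficult, at or below -> easy."""
    if not np.isfinite(median_cl):
        raise ValueError(f"median CL must be finite, got {median_cl}")
    if median_cl == model.d:
        logger.info("median CL exactly on the boundary %g; classifying as easy", model.d)
        return EASY
    return DIFFICULT if median_cl > model.d else EASY
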