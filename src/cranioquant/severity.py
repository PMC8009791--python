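"""Severity scoring: cohort rank-sum score, severity index and cranial indices.

Three layers quantify scaphocephaly severity from the curve variables:

* the cohort rank-sum score — skull width (R + L, narrower = higher rank)
  and peak sum (F + O, larger = higher rank) are each ranked 1..N across a
  cohort and the two ranks added, giving a score between 2 and 2N whose
  cohort mean is always N + 1;
* the severity index (O - 1.1) + (F - 1.15) + (1.70 - (R + L)), measuring
  the deviation from control reference values (occiput 1.1, forehead 1.15,
  both sides 2 x 0.85), classified mild (< 0.20), moderate (>= 0.20) or
  severe (>= 0.35);
* the cranial index, both traditional (biparietal / occipitofrontal
  diameter x 100) and curve-derived (100 x (R + L) / (F + O)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .features import CurveFeatures
from .geometry import Outline2D

#: severity-index class boundaries (moderate from, severe from), inclusive
DEFAULT_CUTOFFS = (0.20, 0.35)
#: control reference values: occiput, forehead, width-of-skull (R + L)
CONTROL_OCCIPUT = 1.1
CONTROL_FOREHEAD = 1.15
CONTROL_WIDTH_SUM = 1.70


class SeverityError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRanking:
    subject_ids: list
    widths: np.ndarray  # R + L per subject
    peak_sums: np.ndarray  # F + O per subject
    ranks_width: np.ndarray
    ranks_peaks: np.ndarray
    scores: np.ndarray  # rank_width + rank_peaks

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))


@dataclass(frozen=True)
class SeverityResult:
    severity_index: float
    severity_class: str
    components: dict
    ci_curve: float
    ucsq_rank_score: float | None = None
    rank_width: float | None = None
    rank_peaks: float | None = None
    ci_traditional: float | None = None


def ucsq_score(cohort: list[CurveFeatures], subject_ids: list | None = None) -> CohortRanking:
    """Rank-sum severity score across a cohort.

    The narrower the skull (smaller R + L) the higher its width rank, and
    the larger F + O the higher its peak rank; ties share the average rank,
    so each rank vector sums to N(N+1)/2 and the mean score is N + 1.
    """
    n = len(cohort)
    if n < 2:
        raise SeverityError(f"cohort ranks need at least 2 subjects, got {n}")
    if subject_ids is None:
        subject_ids = list(range(n))
    widths = np.array([f.width_sum for f in cohort], dtype=float)
    peaks = np.array([f.peak_sum for f in cohort], dtype=float)
    ranks_width = rankdata(-widths, method="average")
    ranks_peaks = rankdata(peaks, method="average")
    return CohortRanking(
        subject_ids=list(subject_ids),
        widths=widths,
        peak_sums=peaks,
        ranks_width=ranks_width,
        ranks_peaks=ranks_peaks,
        scores=ranks_width + ranks_peaks,
    )


def severity_index(
    features: CurveFeatures,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> tuple[float, str]:
    """Severity index and class for one subject.

    value = (O - 1.1) + (F - 1.15) + (1.70 - (R + L)); components may be
    negative (no flooring — the formula is applied literally).  Classes:
    mild below ``cutoffs[0]``, severe at or above ``cutoffs[1]``, moderate
    between; both boundaries are inclusive on the more-severe side.
    """
    comps = severity_components(features)
    value = comps["occiput"] + comps["forehead"] + comps["width"]
    return value, classify_severity(value, cutoffs)


def severity_components(features: CurveFeatures) -> dict:
    return {
        "occiput": features.O - CONTROL_OCCIPUT,
        "forehead": features.F - CONTROL_FOREHEAD,
        "width": CONTROL_WIDTH_SUM - features.width_sum,
    }


def classify_severity(value: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> str:
    moderate_from, severe_from = cutoffs
    if not moderate_from < severe_from:
        raise SeverityError("cutoffs must be increasing")
    if value >= severe_from:
        return "severe"
    if value >= moderate_from:
        return "moderate"
    return "mild"


def ci_traditional(width_mm: float, length_mm: float) -> float:
    """Traditional cranial index: biparietal / occipitofrontal x 100 (%)."""
    if width_mm <= 0 or length_mm <= 0:
        raise SeverityError("cranial index needs positive width and length")
    return 100.0 * width_mm / length_mm


def ci_curve(features: CurveFeatures) -> float:
    """Curve-derived cranial index: 100 x (R + L) / (F + O) (%).

    Width is twice the mean of both sides (= R + L); length is the sum of
    the forehead and occiput maxima.  Because the curve is cut 4 cm above
    the landmark plane rather than at the largest anteroposterior extent,
    this can sit below the traditional index.
    """
    return 100.0 * features.width_sum / features.peak_sum


def ci_from_extrema(F: float, O: float, R: float, L: float) -> float:
    return 100.0 * (R + L) / (F + O)


def outline_diameters(outline: Outline2D) -> tuple[float, float]:
    """(biparietal width, occipitofrontal length) extents of an outline, mm.

    Length is the extent along the outline frame's anterior axis, width the
    extent perpendicular to it.
    """
    a = outline.anterior_angle
    d = np.array([np.cos(a), np.sin(a)])
    p = np.array([-np.sin(a), np.cos(a)])
    proj_l = outline.vertices @ d
    proj_w = outline.vertices @ p
    return float(np.ptp(proj_w)), float(np.ptp(proj_l))


def ci_traditional_from_outline(outline: Outline2D) -> float:
    width, length = outline_diameters(outline)
    return ci_traditional(width, length)


def evaluate(
    features: CurveFeatures,
    outline: Outline2D | None = None,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> SeverityResult:
    """Per-subject severity layers (rank score requires a cohort; see
    :func:`ucsq_score`)."""
    value, cls = severity_index(features, cutoffs)
    return SeverityResult(
        severity_index=value,
        severity_class=cls,
        components=severity_components(features),
        ci_curve=ci_curve(features),
        ci_traditional=None if outline is None else ci_traditional_from_outline(outline),
    )
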