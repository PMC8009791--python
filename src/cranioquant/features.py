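"""Curve variables: quadrant extrema, derived widths and abruptness slopes.

From an aligned normalized curve the four anatomical extrema are read in
the four quadrants — occipital maximum O around theta = 0, forehead
maximum F around pi, and the two lateral trough minima R and L.  Derived
quantities follow: the skull width R/2 + L/2, the occiput and forehead
prominences over the sides, and the forehead-occiput difference.  The
abruptness of each of the four monotone segments is the slope Delta y /
Delta theta between the curve's crossings of the 1.1 and 0.9 levels within
that segment (descents negative, ascents positive); a segment that never
reaches a level has no defined abruptness and is reported as missing with
a reason code rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curve import RadialCurve, _sector_mask

#: the level pair between which segment slopes are measured
UPPER_LEVEL = 1.1
LOWER_LEVEL = 0.9


class FeatureError(ValueError):
    pass


@dataclass
class CurveFeatures:
    """All variables read from one aligned radial curve (dimensionless).

    ``F``/``O`` are the forehead/occiput maxima, ``R``/``L`` the right/left
    trough minima, ``XF``/``XR``/``XL``/``XO`` their angular positions in
    radians on the aligned grid.  ``diff_forehead_occiput`` is |F - O|
    (the signed value is kept alongside).  The four abruptness slopes are
    None when undefined, with the reason in ``abruptness_missing``;
    ``abruptness_spans`` records the angular distance between the level
    crossings so the slope can be re-expressed in any angular unit.
    """

    F: float
    O: float
    R: float
    L: float
    XF: float
    XO: float
    XR: float
    XL: float
    width: float
    diff_occiput_sides: float
    diff_forehead_sides: float
    diff_forehead_occiput: float
    diff_forehead_occiput_signed: float
    Do: float | None = None
    Af: float | None = None
    Df: float | None = None
    Ao: float | None = None
    abruptness_missing: dict = field(default_factory=dict)
    abruptness_spans: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def width_sum(self) -> float:
        """Skull width as the sum of both sides, R + L (used by the
        severity index, where the control reference is 1.70 = 2 x 0.85)."""
        return self.R + self.L

    @property
    def peak_sum(self) -> float:
        """F + O, the curve-based cranial length."""
        return self.F + self.O


def derive_features(F: float, O: float, R: float, L: float) -> dict:
    """The arithmetic identities tying the derived variables to the extrema."""
    width = R / 2.0 + L / 2.0
    return {
        "width": width,
        "diff_occiput_sides": O - width,
        "diff_forehead_sides": F - width,
        "diff_forehead_occiput": abs(F - O),
        "diff_forehead_occiput_signed": F - O,
    }


def _quadrant_extremum(curve: RadialCurve, center: float, kind: str):
    mask = _sector_mask(curve.theta, center, np.pi / 2)
    idx = np.flatnonzero(mask)
    vals = curve.y[idx]
    j = int(np.argmax(vals) if kind == "max" else np.argmin(vals))
    return float(vals[j]), int(idx[j])


def extract_features(curve: RadialCurve) -> CurveFeatures:
    """Read all curve variables off an aligned, normalized curve.

    Sectors are the four quadrants of the aligned grid, centered at 0
    (occiput), pi (forehead) and +/- pi/2 (the lateral troughs); which
    lateral quadrant is the subject's left follows the curve's recorded
    left axis.  An extremum landing on a sector boundary is flagged as a
    possible misalignment.
    """
    if not (curve.aligned and curve.normalized):
        raise FeatureError("extract_features expects an aligned, normalized curve")
    O, iO = _quadrant_extremum(curve, 0.0, "max")
    F, iF = _quadrant_extremum(curve, np.pi, "max")
    # assign left to the lateral quadrant whose center is nearest the left axis
    left_at_half_pi = np.cos(curve.left_angle - np.pi / 2) >= 0
    left_center = np.pi / 2 if left_at_half_pi else 3 * np.pi / 2
    right_center = 3 * np.pi / 2 if left_at_half_pi else np.pi / 2
    L, iL = _quadrant_extremum(curve, left_center, "min")
    R, iR = _quadrant_extremum(curve, right_center, "min")

    warns = []
    for name, i, center in (("O", iO, 0.0), ("F", iF, np.pi),
                            ("L", iL, left_center), ("R", iR, right_center)):
        d = abs(np.angle(np.exp(1j * (curve.theta[i] - center))))
        if d >= np.pi / 4 - curve.step / 2:
            warns.append(f"extremum {name} lies on its sector boundary; check alignment")

    feats = CurveFeatures(
        F=F,
        O=O,
        R=R,
        L=L,
        XF=float(curve.theta[iF]),
        XO=float(curve.theta[iO]),
        XR=float(curve.theta[iR]),
        XL=float(curve.theta[iL]),
        **derive_features(F, O, R, L),
        warnings=warns,
    )
    Do, Af, Df, Ao, missing, spans = _abruptness_all(curve, iO, iF, iL, iR)
    feats.Do, feats.Af, feats.Df, feats.Ao = Do, Af, Df, Ao
    feats.abruptness_missing = missing
    feats.abruptness_spans = spans
    return feats


def abruptness(curve: RadialCurve):
    """(Do, Af, Df, Ao): slopes of the four monotone segments.

    Segments run between consecutive extrema along the aligned grid:
    occiput -> first trough (first descent, Do), trough -> forehead (first
    ascent, Af), forehead -> second trough (second descent, Df) and trough
    -> occiput (second ascent, Ao).  Each slope is +/- 0.2 divided by the
    angular distance between the segment's linearly interpolated crossings
    of 1.1 and 0.9.
    """
    if not (curve.aligned and curve.normalized):
        raise FeatureError("abruptness expects an aligned, normalized curve")
    _, iO = _quadrant_extremum(curve, 0.0, "max")
    _, iF = _quadrant_extremum(curve, np.pi, "max")
    _, i1 = _quadrant_extremum(curve, np.pi / 2, "min")
    _, i2 = _quadrant_extremum(curve, 3 * np.pi / 2, "min")
    Do, Af, Df, Ao, missing, _ = _abruptness_all(curve, iO, iF, i1, i2)
    return Do, Af, Df, Ao, missing


def _abruptness_all(curve: RadialCurve, iO: int, iF: int, iA: int, iB: int):
    """Slopes for the four segments delimited by the extremum indices.

    ``iA``/``iB`` are the trough indices in the (pi/2) and (3pi/2)
    quadrants; traversal starts at the occiput index and proceeds in
    increasing theta.
    """
    n = curve.n_samples
    first_trough = iA if (iA - iO) % n <= (iB - iO) % n else iB
    second_trough = iB if first_trough == iA else iA
    stops = [iO, first_trough, iF, second_trough, iO + n]
    # unroll indices so each segment is a contiguous slice
    unrolled = [iO]
    for s in stops[1:]:
        prev = unrolled[-1]
        s_adj = s
        while s_adj < prev:
            s_adj += n
        unrolled.append(s_adj)

    names = ("Do", "Af", "Df", "Ao")
    descending = (True, False, True, False)
    out, missing, spans = {}, {}, {}
    for name, desc, a, b in zip(names, descending, unrolled[:-1], unrolled[1:]):
        idx = np.arange(a, b + 1)
        y = curve.y[idx % n]
        th = idx * curve.step
        slope, span, reason = _segment_slope(th, y, desc)
        out[name] = slope
        if span is not None:
            spans[name] = span
        if reason is not None:
            missing[name] = reason
    return out["Do"], out["Af"], out["Df"], out["Ao"], missing, spans


def _segment_slope(th: np.ndarray, y: np.ndarray, descending: bool):
    """Slope of one segment between the 1.1 and 0.9 crossings.

    Returns (slope, angular span, missing-reason); slope/span are None when
    a level is never reached.  With ripple, several crossings of a level
    can occur: the 1.1 crossing nearest the segment's peak end and the 0.9
    crossing nearest its trough end are used, measuring the full shoulder
    of the peak.
    """
    if y.size < 2:
        return None, None, "segment too short"
    if np.max(y) < UPPER_LEVEL:
        return None, None, f"segment never reaches {UPPER_LEVEL}"
    if np.min(y) > LOWER_LEVEL:
        return None, None, f"segment never reaches {LOWER_LEVEL}"
    up = _level_crossings(th, y, UPPER_LEVEL)
    dn = _level_crossings(th, y, LOWER_LEVEL)
    if not up or not dn:
        return None, None, "level touched but not crossed"
    # peak end: start for descents, end for ascents
    peak_t = th[0] if descending else th[-1]
    trough_t = th[-1] if descending else th[0]
    t_up = min(up, key=lambda t: abs(t - peak_t))
    t_dn = min(dn, key=lambda t: abs(t - trough_t))
    span = abs(t_dn - t_up)
    if span <= 0:
        return None, None, "coincident level crossings"
    slope = (UPPER_LEVEL - LOWER_LEVEL) / span
    return (-slope if descending else slope), span, None


def _level_crossings(th: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """Angles where the piecewise-linear segment crosses ``level``.

    A sample exactly at the level counts as a crossing at that sample (the
    first touching sample when a run of ties occurs).
    """
    out = []
    d = y - level
    for i in range(len(y) - 1):
        if d[i] == 0.0:
            if i == 0 or d[i - 1] != 0.0:
                out.append(float(th[i]))
        elif d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            out.append(float(th[i] + t * (th[i + 1] - th[i])))
    if d[-1] == 0.0 and (len(d) < 2 or d[-2] != 0.0):
        out.append(float(th[-1]))
    return out
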