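"""The normalized radial ("sinusoid") curve of a cranial outline.

Distances from the outline's center of mass are sampled on a uniform
angular grid, divided by their circular mean so the curve is dimensionless
with mean 1, and circularly shifted so theta = 0 sits at the occipital
maximum.  After alignment a scaphocephalic curve traverses its four
monotone segments in the order descent-from-occiput, ascent-to-forehead,
descent-from-forehead, ascent-to-occiput.  In control-shaped heads the
occiput peaks near 1.1, the forehead near 1.15 and the lateral troughs
near 0.85 on this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Outline2D, centroid, point_in_outline

#: default angular resolution: 360 samples = 1 degree, which localizes the
#: 0.9/1.1 level crossings used for abruptness to better than 0.5 degrees
DEFAULT_N_SAMPLES = 360


class CurveError(ValueError):
    pass


@dataclass
class RadialCurve:
    """Radial profile y(theta) on a uniform angular grid over [0, 2pi).

    ``y`` is in mm until :func:`normalize` divides by the circular mean
    (stored as ``scale_mm``); :func:`align` rotates the grid so theta = 0
    is the occipital maximum and records the shift.  ``anterior_angle`` and
    ``left_angle`` track where the anatomical directions currently point.
    """

    theta: np.ndarray
    y: np.ndarray
    anterior_angle: float
    left_angle: float
    normalized: bool = False
    aligned: bool = False
    alignment_shift_rad: float = 0.0
    scale_mm: float | None = None
    smoothing_window: int | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.theta.shape != self.y.shape or self.theta.ndim != 1:
            raise CurveError("theta and y must be equal-length 1-D arrays")
        step = 2 * np.pi / self.n_samples
        if not np.allclose(self.theta, np.arange(self.n_samples) * step, atol=1e-9):
            raise CurveError("theta must be the uniform grid k*2pi/n on [0, 2pi)")
        if not np.all(np.isfinite(self.y)):
            raise CurveError("curve contains non-finite values")
        if np.any(self.y <= 0):
            raise CurveError("curve values must be strictly positive")

    @property
    def n_samples(self) -> int:
        return int(self.theta.size)

    @property
    def step(self) -> float:
        return 2 * np.pi / self.n_samples

    def value_at(self, angle: float) -> float:
        """Linear (periodic) interpolation of y at an arbitrary angle."""
        a = float(angle) % (2 * np.pi)
        i = int(a // self.step)
        t = (a - i * self.step) / self.step
        return float((1 - t) * self.y[i] + t * self.y[(i + 1) % self.n_samples])


def radial_profile(
    outline: Outline2D,
    center: tuple[float, float] | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> RadialCurve:
    """Distances (mm) from ``center`` to the outline at uniform angles.

    ``center`` defaults to the outline's area centroid and must lie strictly
    inside the polygon.  Rays that cross the boundary more than once (the
    outline is not star-shaped there) take the outermost crossing; the
    number of such rays is recorded as a warning.
    """
    if n_samples < 8:
        raise CurveError("n_samples too small to resolve the curve")
    if center is None:
        center = centroid(outline)
    if not point_in_outline(outline, center):
        raise CurveError(f"center {center} lies outside the outline polygon")
    c = np.asarray(center, dtype=float)
    theta = np.arange(n_samples) * (2 * np.pi / n_samples)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])

    p1 = outline.vertices
    p2 = np.roll(p1, -1, axis=0)
    e = p2 - p1  # edge vectors, (V, 2)
    w = p1 - c  # ray origin to edge start, (V, 2)
    # solve c + t d = p1 + s e per (ray, edge) via 2-D cross products
    denom = dirs[:, 0, None] * e[None, :, 1] - dirs[:, 1, None] * e[None, :, 0]
    cross_we = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]
    cross_wd = dirs[:, 0, None] * w[None, :, 1] - dirs[:, 1, None] * w[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_we / denom
        s = -cross_wd / denom
    # half-open edge interval with a small tolerance so a ray through a
    # shared vertex is counted on exactly one of the two incident edges
    valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (s >= -1e-9) & (s < 1.0 - 1e-9)
    t = np.where(valid, t, -np.inf)
    dist = t.max(axis=1)
    n_hits = valid.sum(axis=1)
    if np.any(n_hits == 0):
        raise CurveError("a ray from the center misses the outline boundary")
    warns = []
    n_multi = int(np.sum(n_hits > 1))
    if n_multi:
        warns.append(
            f"{n_multi}/{n_samples} rays crossed the outline more than once; "
            "outermost crossing used"
        )
    return RadialCurve(
        theta=theta,
        y=dist,
        anterior_angle=outline.anterior_angle,
        left_angle=outline.left_angle,
        warnings=warns,
    )


def normalize(curve: RadialCurve) -> RadialCurve:
    """Divide by the circular mean radius; the result has mean 1 exactly.

    On the uniform grid the circular mean is the arithmetic mean, so the
    output is scale-invariant: multiplying every input distance by k > 0
    leaves it unchanged.  The mean radius in mm is kept as ``scale_mm``.
    """
    mean = float(np.mean(curve.y))
    return replace(
        curve,
        y=curve.y / mean,
        normalized=True,
        scale_mm=mean if curve.scale_mm is None else curve.scale_mm,
        warnings=list(curve.warnings),
    )


def smooth(curve: RadialCurve, window: int = 5) -> RadialCurve:
    """Optional periodic moving average (off by default in the pipeline)."""
    if window < 1 or window % 2 == 0:
        raise CurveError("smoothing window must be odd and >= 1")
    kernel = np.ones(window) / window
    padded = np.concatenate([curve.y[-(window // 2):], curve.y, curve.y[: window // 2]])
    y = np.convolve(padded, kernel, mode="valid")
    return replace(curve, y=y, smoothing_window=window, warnings=list(curve.warnings))


def align(curve: RadialCurve, flat_tolerance: float = 1e-6) -> RadialCurve:
    """Circularly shift the curve so theta = 0 is the occipital maximum.

    The occipital maximum is searched in the posterior quadrant (the
    quarter-turn sector opposite the anterior direction).  A flat curve
    (peak-to-peak below ``flat_tolerance``) has no distinguishable maximum
    and is aligned by the anatomical frame alone, with a warning.
    """
    if not curve.normalized:
        raise CurveError("align expects a normalized curve")
    posterior = (curve.anterior_angle + np.pi) % (2 * np.pi)
    warns = list(curve.warnings)
    if float(np.ptp(curve.y)) < flat_tolerance:
        shift_idx = int(np.round(posterior / curve.step)) % curve.n_samples
        warns.append("flat curve: aligned by anatomical frame alone")
    else:
        sector = _sector_mask(curve.theta, posterior, np.pi / 2)
        idx = np.flatnonzero(sector)
        shift_idx = int(idx[np.argmax(curve.y[idx])])
    shift = curve.theta[shift_idx]
    return replace(
        curve,
        y=np.roll(curve.y, -shift_idx),
        aligned=True,
        alignment_shift_rad=float((curve.alignment_shift_rad + shift) % (2 * np.pi)),
        anterior_angle=float((curve.anterior_angle - shift) % (2 * np.pi)),
        left_angle=float((curve.left_angle - shift) % (2 * np.pi)),
        warnings=warns,
    )


def _sector_mask(theta: np.ndarray, center: float, width: float) -> np.ndarray:
    """Boolean mask of grid angles within +/- width/2 of ``center`` (wrapped)."""
    d = np.angle(np.exp(1j * (theta - center)))
    return np.abs(d) <= width / 2 + 1e-12


def outline_to_curve(
    outline: Outline2D,
    n_samples: int = DEFAULT_N_SAMPLES,
    smoothing_window: int | None = None,
) -> RadialCurve:
    """Full outline -> aligned normalized curve convenience chain."""
    c = radial_profile(outline, n_samples=n_samples)
    if smoothing_window:
        c = smooth(c, smoothing_window)
    return align(normalize(c))


def curve_from_extrema(
    F: float,
    O: float,
    R: float,
    L: float,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> RadialCurve:
    """Synthetic aligned curve with prescribed quadrant extrema.

    Builds y = c0 + c1 cos(theta) + c2 cos(2 theta) + c3 sin(theta) so that
    y(0) = O (occiput), y(pi) = F (forehead), y(pi/2) = L and y(3pi/2) = R.
    Because the harmonic terms average to zero, the circular mean is c0 and
    the curve is emitted normalized when c0 = 1.  Used to realize a mean
    cohort shape from summary extrema.
    """
    c1 = (O - F) / 2.0
    c0 = ((O + F) / 2.0 + (R + L) / 2.0) / 2.0
    c2 = ((O + F) / 2.0 - (R + L) / 2.0) / 2.0
    c3 = (L - R) / 2.0
    theta = np.arange(n_samples) * (2 * np.pi / n_samples)
    y = c0 + c1 * np.cos(theta) + c2 * np.cos(2 * theta) + c3 * np.sin(theta)
    if np.any(y <= 0):
        raise CurveError("requested extrema produce a non-positive curve")
    return RadialCurve(
        theta=theta,
        y=y,
        anterior_angle=np.pi,
        left_angle=np.pi / 2,
        normalized=bool(abs(c0 - 1.0) < 1e-9),
        aligned=True,
    )
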