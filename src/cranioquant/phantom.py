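"""Parametric cranial phantoms for exercising the full pipeline.

A phantom outline is an ellipse (anteroposterior axis along x, anterior at
angle pi) modulated by wrapped-Gaussian bumps at anatomically meaningful
angles: a frontal boss at theta = pi, an occipital bulge at theta = 0 and
negative temporal pinches at theta = +/- pi/2.  Bump amplitudes are
fractions of the mean ellipse radius, so the deformity dials act on the
same dimensionless scale the normalized radial curve is read on.  Head
volumes are ellipsoid-like stacks of scaled outlines with the exact
continuous volume attached, and rater/normative tables are drawn from
simple seeded models.  None of this emulates CT intensities or real skull
anatomy; it provides shapes whose every feature is analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geometry import Outline2D
from .icv import NormativeTable, VolumeMask

#: angular width (rad) of the deformity bumps; chosen so ascent/descent
#: flanks cross the 0.9/1.1 levels over a resolvable angular span
BUMP_SIGMA_RAD = 0.5

ITEM_NAMES = (
    "width",
    "length",
    "vertex height",
    "frontal bossing",
    "occipital bulging",
    "temporal narrowing",
)


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Dials describing one synthetic skull outline.

    ``base_length_mm``/``base_width_mm`` are the full anteroposterior and
    biparietal extents of the underlying ellipse.  The three deformity
    amplitudes are fractions of the mean ellipse radius (0 = none);
    ``temporal_narrowing`` is subtracted at the lateral poles.  ``noise_sd``
    is radial i.i.d. Gaussian noise per vertex, in mm.
    """

    base_length_mm: float = 160.0
    base_width_mm: float = 120.0
    frontal_bossing: float = 0.0
    occipital_bulge: float = 0.0
    temporal_narrowing: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    n_vertices: int = 360

    def __post_init__(self) -> None:
        if self.base_length_mm <= 0 or self.base_width_mm <= 0:
            raise PhantomError("base axes must be positive")
        if min(self.frontal_bossing, self.occipital_bulge, self.temporal_narrowing) < 0:
            raise PhantomError("deformity amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.n_vertices < 32:
            raise PhantomError("n_vertices must be >= 32")


def _wrapped_gaussian(theta: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    d = np.angle(np.exp(1j * (theta - mu)))  # wrapped difference in (-pi, pi]
    return np.exp(-0.5 * (d / sigma) ** 2)


def ellipse_radius(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Polar radius of the base ellipse at angles ``theta``."""
    a = spec.base_length_mm / 2.0
    b = spec.base_width_mm / 2.0
    theta = np.asarray(theta, dtype=float)
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def outline_radius(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Noise-free generator radius (mm): ellipse plus deformity bumps.

    The bump term is ``mean ellipse radius x sum of amplitude-weighted
    wrapped Gaussians``; the mean radius is taken over the spec's own
    uniform vertex grid so the formula is exactly reproducible.
    """
    theta = np.asarray(theta, dtype=float)
    grid = _theta_grid(spec.n_vertices)
    r_mean = float(np.mean(ellipse_radius(spec, grid)))
    bumps = (
        spec.frontal_bossing * _wrapped_gaussian(theta, np.pi, BUMP_SIGMA_RAD)
        + spec.occipital_bulge * _wrapped_gaussian(theta, 0.0, BUMP_SIGMA_RAD)
        - spec.temporal_narrowing
        * (
            _wrapped_gaussian(theta, np.pi / 2, BUMP_SIGMA_RAD)
            + _wrapped_gaussian(theta, -np.pi / 2, BUMP_SIGMA_RAD)
        )
    )
    return ellipse_radius(spec, theta) + r_mean * bumps


def _theta_grid(n: int) -> np.ndarray:
    return np.arange(n) * (2 * np.pi / n)


def make_outline(spec: PhantomSpec) -> Outline2D:
    """Generate the phantom outline polygon (mm, anterior at angle pi)."""
    theta = _theta_grid(spec.n_vertices)
    r = outline_radius(spec, theta)
    if np.any(r <= 0):
        k = int(np.argmin(r))
        raise PhantomError(
            f"deformity amplitudes drive the radius to {r[k]:.2f} mm at "
            f"theta={theta[k]:.3f} rad; reduce temporal_narrowing or widen the base"
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        r = r + rng.normal(0.0, spec.noise_sd, size=r.shape)
        if np.any(r <= 0):
            raise PhantomError("noise drove the radius non-positive; lower noise_sd")
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Outline2D(vertices=verts, anterior_angle=np.pi)


def make_volume(
    spec: PhantomSpec,
    n_slices: int,
    slice_spacing_mm: float,
    xy_spacing_mm: float | None = None,
) -> VolumeMask:
    """Ellipsoid-like binary head volume: a stack of scaled phantom outlines.

    Slice k sits at height z_k; its cross-section is the phantom outline
    scaled by sqrt(1 - (z_k / c)^2) with vertical semi-axis
    c = n_slices x spacing / 2, so an all-zero-dial spec yields an exact
    ellipsoid.  The continuous solid's volume (base polygon area x 4c/3) is
    attached as ``analytic_volume_mm3``; voxelization marks voxels whose
    centers fall inside the scaled polygon.
    """
    if n_slices < 3:
        raise PhantomError(f"need at least 3 slices, got {n_slices}")
    if slice_spacing_mm <= 0:
        raise PhantomError("slice spacing must be positive")
    dz = float(slice_spacing_mm)
    dxy = dz if xy_spacing_mm is None else float(xy_spacing_mm)
    if dxy <= 0:
        raise PhantomError("xy spacing must be positive")

    outline = make_outline(spec)
    base = outline.vertices
    c = n_slices * dz / 2.0
    r_max = float(np.max(np.linalg.norm(base, axis=1)))
    n_xy = int(np.ceil(2 * (r_max + 2 * dxy) / dxy))
    coords = (np.arange(n_xy) - (n_xy - 1) / 2.0) * dxy
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    xs, ys = X.ravel(), Y.ravel()

    vox = np.zeros((n_xy, n_xy, n_slices), dtype=bool)
    for k in range(n_slices):
        z = -c + (k + 0.5) * dz
        s = 1.0 - (z / c) ** 2
        if s <= 0:
            continue
        s = float(np.sqrt(s))
        poly = Polygon(base * s)
        shapely.prepare(poly)
        vox[:, :, k] = shapely.contains_xy(poly, xs, ys).reshape(n_xy, n_xy)

    base_area = Polygon(base).area
    analytic = base_area * (4.0 * c / 3.0)
    origin = (float(coords[0]), float(coords[0]), float(-c + 0.5 * dz))
    return VolumeMask(
        voxels=vox,
        spacing_mm=(dxy, dxy, dz),
        origin_mm=origin,
        analytic_volume_mm3=float(analytic),
    )


def make_rater_table(
    n_subjects: int, n_raters: int, agreement: float, seed: int = 0
) -> pd.DataFrame:
    """Seeded rater-score table: subjects x raters x 6 items, scores {0,1,2}.

    Each subject-item pair has a latent true score; every rater reports it
    with probability ``agreement`` and otherwise draws uniformly from
    {0, 1, 2}.  ``agreement=1`` makes raters identical; ``agreement=0``
    removes the subject effect entirely.  Returned in long form with
    columns (subject, rater, item, score).
    """
    if n_raters < 2:
        raise PhantomError(f"need at least 2 raters, got {n_raters}")
    if n_subjects < 2:
        raise PhantomError(f"need at least 2 subjects, got {n_subjects}")
    if not 0.0 <= agreement <= 1.0:
        raise PhantomError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    latent = rng.integers(0, 3, size=(n_subjects, 1, len(ITEM_NAMES)))
    latent = np.broadcast_to(latent, (n_subjects, n_raters, len(ITEM_NAMES)))
    random_scores = rng.integers(0, 3, size=latent.shape)
    copy = rng.random(latent.shape) < agreement
    scores = np.where(copy, latent, random_scores)
    rows = [
        (s, r, ITEM_NAMES[i], int(scores[s, r, i]))
        for s in range(n_subjects)
        for r in range(n_raters)
        for i in range(len(ITEM_NAMES))
    ]
    return pd.DataFrame(rows, columns=["subject", "rater", "item", "score"])


def make_normative_table(max_age_months: int = 36) -> NormativeTable:
    """Synthetic normative ICV table (NOT clinical reference data).

    A smooth saturating growth model per sex — infant intracranial volume
    rising steeply in the first year and flattening after — with SD set to
    8% of the mean.  Shaped like published normative growth curves but
    entirely synthetic; supply a real table for clinical use.
    """
    ages = np.arange(0, max_age_months + 1, 2, dtype=float)
    rows = []
    for sex, v0, gain in (("male", 450.0, 750.0), ("female", 410.0, 690.0)):
        mean = v0 + gain * (1.0 - np.exp(-ages / 8.0))
        for a, m in zip(ages, mean):
            rows.append((sex, a, round(m, 1), round(0.08 * m, 1)))
    return NormativeTable(pd.DataFrame(rows, columns=list(NormativeTable.COLUMNS)))


def make_cohort(
    n: int,
    seed: int = 0,
    severity_range: tuple[float, float] = (0.25, 1.0),
) -> list[PhantomSpec]:
    """A cohort of phantoms spanning mild to severe scaphocephalic shape.

    A severity dial s in [0, 1] elongates the base ellipse (150 -> 178 mm),
    narrows it (128 -> 106 mm) and raises the frontal/occipital bumps and
    temporal pinch together, which carries the extracted curve variables
    across the ranges seen in scaphocephaly cohorts (severity index about
    0 to 0.7, curve cranial index about 75 down to 55).  Small seeded
    jitter decorrelates skull width from peak height so cohort ranks are
    non-trivial.
    """
    rng = np.random.default_rng(seed)
    sev = np.linspace(*severity_range, n)
    specs = []
    for s in sev:
        specs.append(
            PhantomSpec(
                base_length_mm=150.0 + 28.0 * s + rng.normal(0, 1.5),
                base_width_mm=128.0 - 22.0 * s + rng.normal(0, 1.5),
                frontal_bossing=float(0.035 * s * (1 + rng.normal(0, 0.05))),
                occipital_bulge=float(0.05 * s * (1 + rng.normal(0, 0.05))),
                temporal_narrowing=float(0.04 * s * (1 + rng.normal(0, 0.05))),
                noise_sd=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
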