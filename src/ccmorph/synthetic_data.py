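"""Synthetic corpus-callosum-like curves and two-group cohorts.

The generator emulates the mid-sagittal corpus-callosum boundary as a
crescent: an outer circular arc and an inner arc offset inward by a
smoothly varying thickness profile (cosine-modulated so the band tapers
toward the two tips), joined tip-to-tip into a simple closed clockwise
polygon.  Cohorts add, per subject,

* covariate-driven global scale (total intracranial volume acts through a
  cube-root volume-to-length link),
* for disease subjects, a localized contiguous "atrophy" arc where the
  band is thinned by a fractional amount with cosine roll-off,
* smoothed point-wise radial noise, and
* a random rigid pose so rigid pre-alignment is genuinely exercised.

Everything is a pure function of (parameters, seed); the ground-truth
effect arc is recorded in the curve's intrinsic index parameterization so
recovered significance maps can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .curves import Curve, ensure_clockwise, is_simple, write_curve
from .errors import InvalidParamsError

__all__ = [
    "CrescentParams",
    "CohortSpec",
    "SyntheticCohort",
    "make_crescent",
    "generate_cohort",
    "cohort_to_masks",
    "simulate_marker_matrix",
    "save_cohort",
]

_TIV_MEAN = 1.5e6  # mm^3
_TIV_SD = 1.2e5


@dataclass(frozen=True)
class CrescentParams:
    """Geometry of the base crescent (pixel units)."""

    center: tuple[float, float] = (64.0, 64.0)
    outer_radius: float = 40.0
    thickness: float = 12.0
    arc_span: float = 3.4  # radians subtended by the outer arc
    bend: float = 0.3  # asymmetry of the thickness profile
    n_points: int = 200

    def __post_init__(self):
        if not (self.outer_radius > self.thickness > 0):
            raise InvalidParamsError(
                f"need outer_radius > thickness > 0, got {self.outer_radius}, {self.thickness}"
            )
        if self.n_points < 40:
            raise InvalidParamsError(f"n_points must be >= 40, got {self.n_points}")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort design with a localized atrophy effect.

    ``effect_center`` / ``effect_width`` are fractions of the closed
    curve's index parameterization; ``effect_size`` is the fractional
    thinning of the band at the effect center (cosine roll-off to zero at
    the arc's edges).  Ages ~ N(70, 8), sex ~ Bernoulli(0.5), total
    intracranial volume ~ N(1.5e6, 1.2e5) mm^3 scales each shape by
    (tiv / 1.5e6)^(1/3).
    """

    n_control: int = 60
    n_disease: int = 60
    effect_center: float = 0.5
    effect_width: float = 0.25
    effect_size: float = 0.30
    shape_noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise InvalidParamsError("CohortSpec requires an explicit seed")
        if self.n_control < 3 or self.n_disease < 3:
            raise InvalidParamsError("group sizes must be >= 3")
        if not (0 <= self.effect_center < 1):
            raise InvalidParamsError("effect_center must be in [0, 1)")
        if not (0 < self.effect_width <= 0.5):
            raise InvalidParamsError("effect_width must be in (0, 0.5]")
        if not (0 <= self.effect_size <= 0.6):
            raise InvalidParamsError("effect_size must be in [0, 0.6]")


@dataclass
class SyntheticCohort:
    curves: list
    covariates: pd.DataFrame
    truth_mask: np.ndarray  # per-point boolean atrophy arc (reference indices)
    effect_size: float
    params: CrescentParams
    spec: CohortSpec


# ---------------------------------------------------------------------------
# crescent geometry


def _crescent_polar(params: CrescentParams):
    """Per-point (angle, radius) profile of the closed crescent.

    Returns arrays (theta, radius, medial_radius, half_thickness) of length
    n_points: the first half walks the outer arc, the second half walks
    the inner arc back, so the polygon closes tip-to-tip.
    """
    n = params.n_points
    n_out = n // 2
    n_in = n - n_out
    span = params.arc_span

    # u in [-1, 1] across the arc; the band stays thick until near the two
    # blunt ends (the genu/splenium bulbs) and is skewed by `bend`
    def half_thickness(u):
        taper = np.maximum(1.0 - u**2, 0.0) ** 0.3
        skew = 1.0 + params.bend * np.sin(0.5 * np.pi * u)
        return 0.5 * params.thickness * taper * skew

    u_out = np.linspace(-1.0, 1.0, n_out)
    u_in = np.linspace(1.0, -1.0, n_in + 2)[1:-1]  # interior points, reversed

    theta_out = 0.5 * span * u_out
    theta_in = 0.5 * span * u_in
    mid_r = params.outer_radius - 0.5 * params.thickness
    r_out = mid_r + half_thickness(u_out)
    r_in = mid_r - half_thickness(u_in)

    theta = np.concatenate([theta_out, theta_in])
    radius = np.concatenate([r_out, r_in])
    medial = np.full(n, mid_r)
    half_t = np.concatenate([half_thickness(u_out), half_thickness(u_in)])
    return theta, radius, medial, half_t


def _polar_to_curve(theta, radius, params: CrescentParams, subject_id="") -> Curve:
    cx, cy = params.center
    # angle 0 points "up" on screen (-y); positive angles sweep clockwise
    x = cx + radius * np.sin(theta)
    y = cy - radius * np.cos(theta)
    return ensure_clockwise(Curve(points=np.column_stack([x, y]),
                                  subject_id=subject_id))


def make_crescent(params: CrescentParams, subject_id: str = "template") -> Curve:
    """Deterministically build the base crescent as a simple closed curve."""
    theta, radius, _, _ = _crescent_polar(params)
    curve = _polar_to_curve(theta, radius, params, subject_id)
    if not is_simple(curve):
        raise InvalidParamsError("crescent parameters yield a self-intersecting polygon")
    return curve


def _effect_weights(n: int, center: float, width: float) -> np.ndarray:
    """Cosine window of the effect over curve index fraction (periodic)."""
    f = np.arange(n) / n
    d = np.minimum(np.abs(f - center), 1.0 - np.abs(f - center))
    w = np.where(d <= width / 2, 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width)), 0.0)
    return w


def _smooth_periodic(x: np.ndarray, window: int = 5) -> np.ndarray:
    k = np.ones(window) / window
    ext = np.concatenate([x[-(window // 2):], x, x[: window // 2]])
    return np.convolve(ext, k, mode="valid")


def generate_cohort(base: CrescentParams, spec: CohortSpec) -> SyntheticCohort:
    """Generate a two-group cohort of crescent curves with known truth.

    Disease subjects get the band thinned by ``effect_size`` (cosine
    roll-off) over the arc ``effect_center ± effect_width/2`` of the index
    parameterization; all subjects get a tiv-driven global scale, smoothed
    Gaussian radial noise and a random rigid pose (rotation U(−15°, 15°),
    translation U(−10, 10) px).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = base.n_points
    theta, radius, medial, half_t = _crescent_polar(base)
    w = _effect_weights(n, spec.effect_center, spec.effect_width)
    truth = w > 0.0

    n_total = spec.n_control + spec.n_disease
    groups = np.array([0] * spec.n_control + [1] * spec.n_disease)
    age = rng.normal(70.0, 8.0, n_total)
    sex = rng.integers(0, 2, n_total)
    tiv = rng.normal(_TIV_MEAN, _TIV_SD, n_total)

    curves = []
    rows = []
    cx, cy = base.center
    for s in range(n_total):
        sid = f"sub{s:03d}"
        scale = (tiv[s] / _TIV_MEAN) ** (1.0 / 3.0)
        r = radius.copy()
        if groups[s] == 1 and spec.effect_size > 0:
            # thin the band: pull each point toward the medial line
            offset = r - medial
            r = medial + offset * (1.0 - spec.effect_size * w)
        curve = None
        for attempt in range(10):
            noise = np.zeros(n)
            if spec.shape_noise_sd > 0:
                noise = _smooth_periodic(rng.normal(0.0, spec.shape_noise_sd, n))
            r_noisy = r + noise
            pts_theta = theta
            cand = _polar_to_curve(pts_theta, r_noisy, base, sid)
            # tiv scale about the crescent center, then a random rigid pose
            pts = (cand.points - (cx, cy)) * scale + (cx, cy)
            ang = rng.uniform(-np.pi / 12, np.pi / 12)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            shift = rng.uniform(-10.0, 10.0, 2)
            ctr = pts.mean(axis=0)
            pts = (pts - ctr) @ R.T + ctr + shift
            cand = Curve(points=pts, subject_id=sid)
            if is_simple(cand):
                curve = ensure_clockwise(cand)
                break
        if curve is None:
            raise InvalidParamsError(
                f"subject {sid}: no simple polygon after 10 noise resamples"
            )
        curves.append(curve)
        rows.append({"subject_id": sid, "group": int(groups[s]),
                     "age": float(age[s]), "sex": int(sex[s]),
                     "tiv": float(tiv[s])})

    return SyntheticCohort(
        curves=curves,
        covariates=pd.DataFrame(rows),
        truth_mask=truth,
        effect_size=spec.effect_size,
        params=base,
        spec=spec,
    )


def cohort_to_masks(cohort: SyntheticCohort, grid_shape: tuple[int, int]):
    """Rasterize every cohort curve to a binary mask (even-odd region)."""
    from .evaluation import rasterize_curve

    return [rasterize_curve(c, grid_shape) for c in cohort.curves]


# ---------------------------------------------------------------------------
# marker-level simulation (for statistics calibration at scale)


def simulate_marker_matrix(n_control: int, n_disease: int, n_points: int,
                           seed: int, effect_mask: np.ndarray | None = None,
                           effect_delta: float = 0.0, noise_sd: float = 0.05,
                           tiv_slope: float = 0.10, age_slope: float = -0.002,
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a Jacobian marker matrix straight from the linear model.

    Markers are 1 + covariate effects + spatially smoothed Gaussian noise,
    minus ``effect_delta`` on ``effect_mask`` points for disease subjects.
    This provides null and alternative marker matrices at a scale where
    hundreds of replicate cohorts are practical, for calibrating the
    permutation machinery; it does not involve registration.
    """
    rng = np.random.default_rng(seed)
    n_total = n_control + n_disease
    groups = np.array([0] * n_control + [1] * n_disease)
    age = rng.normal(70.0, 8.0, n_total)
    sex = rng.integers(0, 2, n_total)
    tiv = rng.normal(_TIV_MEAN, _TIV_SD, n_total)

    J = np.ones((n_total, n_points))
    J += tiv_slope * ((tiv - _TIV_MEAN) / _TIV_SD)[:, None]
    J += age_slope * (age - 70.0)[:, None]
    noise = rng.normal(0.0, noise_sd, (n_total, n_points))
    noise = np.apply_along_axis(_smooth_periodic, 1, noise)
    J += noise
    if effect_mask is not None and effect_delta != 0.0:
        J[groups == 1] -= effect_delta * np.asarray(effect_mask, float)[None, :]
    cov = pd.DataFrame({
        "subject_id": [f"sub{i:03d}" for i in range(n_total)],
        "group": groups, "age": age, "sex": sex, "tiv": tiv,
    })
    return J, cov


def save_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Serialize a cohort as curves/*.csv + covariates.csv + truth/spec JSON."""
    outdir = Path(outdir)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)
    for c in cohort.curves:
        write_curve(c, outdir / "curves" / f"{c.subject_id}.csv")
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps({
        "truth_mask": cohort.truth_mask.astype(int).tolist(),
        "effect_size": cohort.effect_size,
    }))
    (outdir / "spec.json").write_text(json.dumps({
        "params": cohort.params.__dict__ | {"center": list(cohort.params.center)},
        "spec": cohort.spec.__dict__,
    }))
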