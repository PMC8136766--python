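"""Curve data model and geometry utilities.

A :class:`Curve` is an ordered closed planar polyline in pixel units,
typically the boundary of a mid-sagittal corpus-callosum segmentation.
The coordinate convention throughout the package is the image convention:
``x`` is the column index, ``y`` is the row index, the origin sits at the
top-left corner and ``y`` increases downward.  "Clockwise" means clockwise
as the image is displayed, which corresponds to a *positive* signed
shoelace area under this convention (and to counter-clockwise in
mathematical y-up axes).

Curves are stored *open*: the last point is distinct from the first and
closure is implicit, which avoids duplicate-point edge cases when building
segments.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
import shapely

from .errors import (
    BorderTouchError,
    DegenerateCurveError,
    EmptyCohortError,
    InvalidCurveError,
    MultipleComponentsError,
    NoForegroundError,
    ParseError,
    TooFewPointsError,
)

__all__ = [
    "Curve",
    "RigidTransform",
    "DownsampleScheme",
    "signed_area",
    "polygon_area",
    "ensure_clockwise",
    "is_simple",
    "extract_boundary",
    "select_template",
    "downsample_curve",
    "rigid_align",
    "read_curve",
    "write_curve",
    "read_mask",
]

_AREA_TOL = 1e-12


@dataclass(frozen=True)
class Curve:
    """Ordered closed planar polyline.

    Parameters
    ----------
    points : (n, 2) float array
        Vertex coordinates ``(x, y)`` in pixel units, implicitly closed
        (last vertex connects back to the first).
    subject_id : str
        Free-form label, usually the subject identifier.
    closed : bool
        Always ``True`` in this pipeline; kept explicit for clarity.
    """

    points: np.ndarray
    subject_id: str = ""
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidCurveError(f"points must be (n, 2), got {pts.shape}")
        if len(pts) < 3:
            raise InvalidCurveError(f"a curve needs >= 3 points, got {len(pts)}")
        same = np.all(pts == np.roll(pts, -1, axis=0), axis=1)
        if same.any():
            raise InvalidCurveError("consecutive points must be distinct")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (no reflection, no scaling).

    ``apply`` maps a point ``p`` to ``R @ p + t`` where ``R`` is the
    rotation by ``rotation_angle`` (radians, about the origin, in image
    coordinates) and ``t = translation``.
    """

    rotation_angle: float
    translation: tuple[float, float]
    converged: bool = True

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_angle), np.sin(self.rotation_angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + np.asarray(self.translation)


@dataclass(frozen=True)
class DownsampleScheme:
    """Down-sampling factor and which curves it applies to.

    ``mode`` is either ``"template_only"`` (down-sample the single template
    curve, leave targets at full resolution) or ``"template_and_target"``.
    Factor 1 is the identity regardless of mode.
    """

    factor: int = 1
    mode: str = "template_only"

    def __post_init__(self):
        if self.factor not in (1, 2, 3, 4, 5):
            raise InvalidCurveError(f"down-sampling factor must be in 1..5, got {self.factor}")
        if self.mode not in ("template_only", "template_and_target"):
            raise InvalidCurveError(f"unknown down-sampling mode {self.mode!r}")


# ---------------------------------------------------------------------------
# basic geometry


def signed_area(points: np.ndarray) -> float:
    """Signed shoelace area; positive iff clockwise in the image convention."""
    x, y = points[:, 0], points[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


def polygon_area(curve: Curve) -> float:
    """Absolute enclosed area (pixels^2) of the closed curve."""
    return abs(signed_area(curve.points))


def is_clockwise(curve: Curve) -> bool:
    a = signed_area(curve.points)
    if abs(a) <= _AREA_TOL:
        raise DegenerateCurveError("polygon has zero area")
    return a > 0


def ensure_clockwise(curve: Curve) -> Curve:
    """Return the curve with clockwise orientation, reversing if needed.

    Idempotent; raises :class:`DegenerateCurveError` on zero-area input.
    """
    if is_clockwise(curve):
        return curve
    return replace(curve, points=curve.points[::-1].copy())


def is_simple(curve: Curve) -> bool:
    """True if the closed polygon has no self-intersections (shapely check)."""
    ring = shapely.LinearRing(np.vstack([curve.points, curve.points[:1]]))
    return bool(ring.is_simple)


# ---------------------------------------------------------------------------
# boundary extraction

# Moore neighbourhood in clockwise *screen* order starting East, as
# (drow, dcol) offsets.  Clockwise on screen (y down) visits E, SE, S, SW,
# W, NW, N, NE.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def extract_boundary(mask: np.ndarray) -> Curve:
    """Trace the outer boundary of the single foreground component of a mask.

    Uses Moore boundary tracing (8-connected walk) restricted to the
    component's border pixels — foreground pixels with at least one
    background 4-neighbour — so the returned pixels are exactly the outer
    border of the 4-connected component, ordered clockwise and starting at
    the top-left-most border pixel.  Interior holes are ignored.

    Raises
    ------
    NoForegroundError, MultipleComponentsError, BorderTouchError
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise NoForegroundError("mask has no foreground pixels")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        raise MultipleComponentsError(n)
    fg = labels == 1
    rows, cols = np.nonzero(fg)
    if rows.min() == 0 or cols.min() == 0 or rows.max() == mask.shape[0] - 1 \
            or cols.max() == mask.shape[1] - 1:
        raise BorderTouchError("foreground component touches the image border")

    # border pixels: foreground with a background 4-neighbour
    padded = np.pad(fg, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = fg & ~interior

    # start at the top-left-most border pixel (row-major scan order)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    def in_border(rc):
        r, c = rc
        return 0 <= r < border.shape[0] and 0 <= c < border.shape[1] and border[r, c]

    contour = [start]
    # the pixel West of the start is background (start is left-most in its row)
    backtrack = (start[0], start[1] - 1)
    current = start
    max_steps = 4 * int(border.sum()) + 8
    for _ in range(max_steps):
        # scan the Moore neighbourhood clockwise starting just after backtrack
        dr, dc = backtrack[0] - current[0], backtrack[1] - current[1]
        k0 = _MOORE.index((dr, dc))
        nxt = None
        prev = backtrack
        for j in range(1, 9):
            cand_off = _MOORE[(k0 + j) % 8]
            cand = (current[0] + cand_off[0], current[1] + cand_off[1])
            if in_border(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated border pixel
            break
        if nxt == start and len(contour) >= 3:
            break
        contour.append(nxt)
        backtrack = prev
        current = nxt

    if len(contour) < 3:
        raise InvalidCurveError("traced boundary has fewer than 3 pixels")
    # (row, col) -> (x, y)
    pts = np.array([(c, r) for r, c in contour], dtype=float)
    curve = Curve(points=pts)
    return ensure_clockwise(curve)


# ---------------------------------------------------------------------------
# template selection & down-sampling


def select_template(curves: list[Curve]) -> tuple[int, Curve]:
    """Pick the curve whose enclosed area is closest to the cohort mean area.

    Ties break toward the lowest index.  Returns ``(index, curve)``.
    """
    if not curves:
        raise EmptyCohortError("cannot select a template from an empty cohort")
    areas = np.array([polygon_area(c) for c in curves])
    idx = int(np.argmin(np.abs(areas - areas.mean())))
    return idx, curves[idx]


def downsample_curve(curve: Curve, factor: int) -> Curve:
    """Keep every ``factor``-th point starting at index 0."""
    if factor < 1:
        raise InvalidCurveError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return curve
    pts = curve.points[::factor]
    if len(pts) < 3:
        raise TooFewPointsError(
            f"factor {factor} leaves {len(pts)} points (< 3) of {curve.n_points}"
        )
    return replace(curve, points=pts.copy())


# ---------------------------------------------------------------------------
# rigid alignment (ICP)


def _kabsch_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form rotation+translation minimizing ||R src + t - dst||^2.

    Rotation only (det +1), no scaling.
    """
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return R, t


def _closest_on_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Closest point on the closed polyline ``poly`` for each query point."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a  # (m, 2)
    L2 = np.maximum(np.sum(e**2, axis=1), 1e-300)
    # t[i, j]: projection parameter of point i on segment j
    t = ((points[:, None, :] - a[None]) * e[None]).sum(-1) / L2[None]
    t = np.clip(t, 0.0, 1.0)
    proj = a[None] + t[..., None] * e[None]  # (n, m, 2)
    d2 = np.sum((proj - points[:, None, :]) ** 2, axis=-1)
    j = np.argmin(d2, axis=1)
    return proj[np.arange(len(points)), j], d2[np.arange(len(points)), j]


def rigid_align(
    moving: Curve,
    fixed: Curve,
    tol: float = 1e-8,
    max_iters: int = 500,
) -> tuple[Curve, RigidTransform]:
    """Rigidly align ``moving`` to ``fixed`` by iterative closest point.

    Initializes with a centroid translation, then alternates closest-point
    correspondence (each moving vertex projects onto the closed fixed
    polyline, which avoids the tangential discretization bias of
    vertex-to-vertex matching) with the closed-form rotation-only Kabsch
    solution, until the mean-squared closest-point distance improves by
    less than ``tol`` or ``max_iters`` is reached.  Never raises on
    non-convergence; the returned transform carries ``converged=False``.
    """
    fixed_pts = fixed.points

    R_tot = np.eye(2)
    t_tot = fixed_pts.mean(axis=0) - moving.points.mean(axis=0)
    cur = moving.points + t_tot

    corr, d2 = _closest_on_polyline(cur, fixed_pts)
    prev_msd = float(np.mean(d2))
    best_msd = prev_msd
    best_R, best_t, best_pts = R_tot, t_tot, cur
    converged = False
    for _ in range(max_iters):
        R, t = _kabsch_rigid(cur, corr)
        cur = cur @ R.T + t
        R_tot = R @ R_tot
        t_tot = R @ t_tot + t
        corr, d2 = _closest_on_polyline(cur, fixed_pts)
        msd = float(np.mean(d2))
        if msd < best_msd:
            best_msd, best_R, best_t, best_pts = msd, R_tot, t_tot, cur
        if prev_msd - msd < tol:
            converged = True
            break
        prev_msd = msd

    angle = float(np.arctan2(best_R[1, 0], best_R[0, 0]))
    transform = RigidTransform(
        rotation_angle=angle,
        translation=(float(best_t[0]), float(best_t[1])),
        converged=converged,
    )
    aligned = replace(moving, points=best_pts.copy())
    return aligned, transform


# ---------------------------------------------------------------------------
# I/O


def read_curve(path: str | Path) -> Curve:
    """Read a curve from CSV (``x,y`` header) or JSON (``{"points": ...}``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        pts = data.get("points")
        if pts is None:
            raise ParseError("JSON curve file lacks a 'points' list")
        try:
            arr = np.array(pts, dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric point data: {exc}") from exc
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
            raise InvalidCurveError(f"need an (n>=3, 2) point list, got shape {arr.shape}")
        return Curve(points=arr, subject_id=str(data.get("subject_id", path.stem)))

    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["x", "y"]:
            raise ParseError("expected header 'x,y'", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError("expected two columns", line=lineno)
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                raise ParseError(f"non-numeric cell {row!r}", line=lineno) from None
    if len(rows) < 3:
        raise InvalidCurveError(f"curve file has {len(rows)} points (< 3)")
    return Curve(points=np.array(rows), subject_id=path.stem)


def write_curve(curve: Curve, path: str | Path) -> None:
    """Write a curve to CSV or JSON (chosen by suffix), lossless to 17 digits."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "subject_id": curve.subject_id,
            "points": [[float(x), float(y)] for x, y in curve.points],
        }
        path.write_text(json.dumps(payload))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in curve.points:
            writer.writerow([repr(float(x)), repr(float(y))])


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 2D binary mask from an 8-bit PNG (nonzero = foreground)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr != 0
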