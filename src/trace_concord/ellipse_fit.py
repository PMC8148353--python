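"""Direct least-squares ellipse fitting of traced boundary points.

Fits the conic ``A x^2 + B xy + C y^2 + D x + E y + F = 0`` subject to
the ellipse constraint ``B^2 - 4AC < 0`` by minimizing algebraic
distance with the constraint ``4AC - B^2 = 1``.  The quadratic and
linear halves of the design matrix are separated so the constrained
eigenproblem reduces to a 3x3 one:

    D1 rows (x^2, xy, y^2),  D2 rows (x, y, 1)
    S1 = D1'D1, S2 = D1'D2, S3 = D2'D2
    C1 = [[0, 0, 2], [0, -1, 0], [2, 0, 0]]
    M  = C1^-1 (S1 - S2 S3^-1 S2')

The eigenvector of ``M`` with a positive constraint value
``4 a1 a3 - a2^2`` gives the quadratic coefficients; the linear half
follows as ``a2 = -S3^-1 S2' a1``.  Exactly one eigenvector satisfies
the constraint in exact arithmetic; numerically the one with the
largest positive constraint value is chosen.

Input points are translated to their centroid and isotropically scaled
to RMS radius sqrt(2) before the fit and the conic mapped back — raw
pixel coordinates (thousands of pixels) would make the scatter blocks
severely ill-conditioned.  The conditioning is mathematically
equivalent, not an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError, InputError
from .trace_io import Polyline, TraceMask, mask_to_boundary

__all__ = [
    "ConicCoefficients",
    "EllipseParams",
    "C1_CONSTRAINT",
    "fit_ellipse_conic",
    "conic_to_geometric",
    "geometric_to_conic",
    "ellipse_to_mask",
    "refit_tracing",
]

#: Constraint matrix enforcing 4AC - B^2 = 1 on the quadratic half.
C1_CONSTRAINT = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])


@dataclass(frozen=True)
class ConicCoefficients:
    """Algebraic conic ``(A, B, C, D, E, F)``, unit-norm with ``A > 0``."""

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        norm = np.linalg.norm(vec)
        if not np.isfinite(norm) or norm == 0:
            raise InputError("conic coefficients must be finite and not all zero")
        vec = vec / norm
        if vec[0] < 0:
            vec = -vec
        if vec[1] ** 2 - 4 * vec[0] * vec[2] >= 0:
            raise InputError("coefficients do not satisfy the ellipse condition B^2 - 4AC < 0")
        for name, v in zip("ABCDEF", vec):
            object.__setattr__(self, name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E, self.F], dtype=float)


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center (px), semi-axes (px), rotation (rad in [0, pi))."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    rotation: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise InputError(
                f"require semi_major >= semi_minor > 0, got {self.semi_major}, {self.semi_minor}"
            )
        object.__setattr__(self, "rotation", float(self.rotation) % math.pi)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def radius_at(self, angle_rad: np.ndarray | float) -> np.ndarray | float:
        """Boundary distance from the center along a given direction."""
        t = np.asarray(angle_rad, dtype=float) - self.rotation
        a, b = self.semi_major, self.semi_minor
        return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def _extract_points(tracing: TraceMask | Polyline | np.ndarray) -> np.ndarray:
    if isinstance(tracing, TraceMask):
        return mask_to_boundary(tracing).points
    if isinstance(tracing, Polyline):
        return tracing.points
    pts = np.asarray(tracing, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"points must be (n, 2), got {pts.shape}")
    return pts


def fit_ellipse_conic(points: TraceMask | Polyline | np.ndarray) -> ConicCoefficients:
    """Fit a conic constrained to be an ellipse to boundary points.

    Parameters
    ----------
    points
        An ``(n, 2)`` array of ``(x, y)`` points, a :class:`Polyline`
        (all vertices are used, misaligned arcs included — absorbing
        them is the point of the fit), or a :class:`TraceMask` (its
        outer contour pixels are used).

    Raises
    ------
    InputError
        Fewer than 6 points.
    FitError
        Degenerate geometry (collinear points, singular scatter) or no
        eigenvector satisfying the ellipse constraint.
    """
    pts = _extract_points(points)
    if len(pts) < 6:
        raise InputError(f"ellipse fit needs at least 6 points, got {len(pts)}")

    # condition: center on the mean, scale to RMS radius sqrt(2)
    mean = pts.mean(axis=0)
    centered = pts - mean
    rms = math.sqrt((centered**2).sum() / len(pts))
    if rms < 1e-12:
        raise FitError("all points coincide")
    s = math.sqrt(2.0) / rms
    u = centered[:, 0] * s
    v = centered[:, 1] * s

    d1 = np.column_stack([u * u, u * v, v * v])
    d2 = np.column_stack([u, v, np.ones_like(u)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration (singular S3)") from exc
    reduced = s1 + s2 @ t_mat
    # premultiply by C1^-1 = [[0,0,.5],[0,-1,0],[.5,0,0]]
    m = np.vstack([reduced[2] / 2.0, -reduced[1], reduced[0] / 2.0])

    eigvals, eigvecs = np.linalg.eig(m)
    best = None
    best_cond = 0.0
    for i in range(3):
        if abs(eigvals[i].imag) > 1e-8 * (1 + abs(eigvals[i].real)):
            continue
        a1 = np.real(eigvecs[:, i])
        nrm = np.linalg.norm(a1)
        if nrm == 0:
            continue
        a1 = a1 / nrm
        cond = 4 * a1[0] * a1[2] - a1[1] ** 2
        if cond > best_cond:
            best_cond = cond
            best = a1
    if best is None:
        raise FitError("no eigenvector satisfies the ellipse constraint")
    a1 = best
    a2 = t_mat @ a1
    a, b, c, d, e, f = a1[0], a1[1], a1[2], a2[0], a2[1], a2[2]

    # undo the conditioning: x = u/s + mx, y = v/s + my
    mx, my = mean
    A = a
    B = b
    C = c
    D = d / s - 2 * a * mx - b * my
    E = e / s - b * mx - 2 * c * my
    F = (
        f / s**2
        + a * mx**2
        + b * mx * my
        + c * my**2
        - d * mx / s
        - e * my / s
    )
    try:
        return ConicCoefficients(A, B, C, D, E, F)
    except InputError as exc:  # should not happen once the constraint held
        raise FitError(f"fitted conic is not an ellipse: {exc}") from exc


def conic_to_geometric(conic: ConicCoefficients) -> EllipseParams:
    """Convert algebraic conic coefficients to geometric parameters.

    The center solves the gradient-zero system; the semi-axes and
    rotation come from the eigen-decomposition of the quadratic form.
    Rotation is canonicalized to ``[0, pi)`` with the semi-major axis
    along the reported angle; a circle reports rotation 0.
    """
    A, B, C, D, E, F = conic.as_array()
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise InputError("conic is not an ellipse (B^2 - 4AC >= 0)")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    f_center = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    if f_center >= 0:
        raise InputError("degenerate conic: empty or point ellipse")
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vecs = np.linalg.eigh(q)  # ascending; both positive since A > 0
    semi = np.sqrt(-f_center / lam)  # larger axis from smaller eigenvalue
    semi_major, semi_minor = float(semi[0]), float(semi[1])
    if math.isclose(semi_major, semi_minor, rel_tol=1e-12):
        rotation = 0.0
    else:
        major_vec = vecs[:, 0]
        rotation = math.atan2(major_vec[1], major_vec[0]) % math.pi
    return EllipseParams((cx, cy), semi_major, semi_minor, rotation)


def geometric_to_conic(params: EllipseParams) -> ConicCoefficients:
    """Exact inverse of :func:`conic_to_geometric` (up to normalization)."""
    cx, cy = params.center
    a, b = params.semi_major, params.semi_minor
    co, si = math.cos(params.rotation), math.sin(params.rotation)
    A = co * co / a**2 + si * si / b**2
    B = 2 * co * si * (1 / a**2 - 1 / b**2)
    C = si * si / a**2 + co * co / b**2
    D = -2 * A * cx - B * cy
    E = -B * cx - 2 * C * cy
    F = A * cx * cx + B * cx * cy + C * cy * cy - 1.0
    return ConicCoefficients(A, B, C, D, E, F)


def ellipse_to_mask(params: EllipseParams, shape: tuple[int, int]) -> TraceMask:
    """Rasterize an ellipse: pixel centers satisfying the interior
    inequality (<= 1) are foreground; the ellipse is clipped to bounds."""
    h, w = shape
    cx, cy = params.center
    r = params.semi_major
    y0 = max(0, int(math.floor(cy - r)) - 1)
    y1 = min(h, int(math.ceil(cy + r)) + 2)
    x0 = max(0, int(math.floor(cx - r)) - 1)
    x1 = min(w, int(math.ceil(cx + r)) + 2)
    grid = np.zeros((h, w), dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return TraceMask(grid)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy
    co, si = math.cos(params.rotation), math.sin(params.rotation)
    major = dx * co + dy * si
    minor = -dx * si + dy * co
    inside = (major / params.semi_major) ** 2 + (minor / params.semi_minor) ** 2 <= 1.0
    grid[y0:y1, x0:x1] = inside
    return TraceMask(grid)


def refit_tracing(
    tracing: TraceMask | Polyline, shape: tuple[int, int]
) -> TraceMask:
    """Replace a tracing by the raster of its best-fit ellipse.

    Polyline vertices are fitted as-is (misaligned segments included);
    masks contribute their outer-contour pixels.  Contour pixel centers
    lie on average half a pixel inside the underlying boundary, so for
    mask input both semi-axes are grown by 0.5 px after the fit (the
    standard half-pixel raster compensation).  Fit failures propagate
    as :class:`FitError` — the pipeline falls back to the raw tracing
    and flags the record.
    """
    conic = fit_ellipse_conic(tracing)
    params = conic_to_geometric(conic)
    if isinstance(tracing, TraceMask):
        params = EllipseParams(
            params.center, params.semi_major + 0.5, params.semi_minor + 0.5, params.rotation
        )
    return ellipse_to_mask(params, shape)
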