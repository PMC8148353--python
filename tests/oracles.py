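"""Independent reference computations used to check the package.

These deliberately avoid the code paths they verify: the ellipse oracle
solves the full 6x6 constrained generalized eigenproblem in one shot
(no block reduction), the kappa oracle counts an explicit 2x2
contingency table, and the boundary-distance oracles evaluate analytic
polar shapes in closed form.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla


def fitzgibbon_conic(points: np.ndarray) -> np.ndarray:
    """Ellipse-constrained algebraic fit via the full 6x6 generalized
    eigenproblem S a = lambda C a with constraint 4AC - B^2 = 1.

    Returns the unit-norm conic vector (A..F) with A > 0.  Points are
    conditioned (centered, isotropically scaled) and the conic mapped
    back, same as any careful implementation must.
    """
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    s = np.sqrt(2.0) / np.sqrt((centered**2).sum() / len(pts))
    x = centered[:, 0] * s
    y = centered[:, 1] * s
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    scatter = design.T @ design
    constraint = np.zeros((6, 6))
    constraint[0, 2] = constraint[2, 0] = 2.0
    constraint[1, 1] = -1.0
    eigvals, eigvecs = sla.eig(scatter, constraint)
    best, best_cond = None, 0.0
    for i in range(6):
        if not np.isfinite(eigvals[i]):
            continue
        v = np.real(eigvecs[:, i])
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        v = v / nrm
        cond = 4 * v[0] * v[2] - v[1] ** 2
        if cond > best_cond:
            best_cond, best = cond, v
    assert best is not None, "oracle found no ellipse solution"
    a, b, c, d, e, f = best
    mx, my = mean
    conic = np.array(
        [
            a,
            b,
            c,
            d / s - 2 * a * mx - b * my,
            e / s - b * mx - 2 * c * my,
            f / s**2 + a * mx**2 + b * mx * my + c * my**2 - d * mx / s - e * my / s,
        ]
    )
    conic /= np.linalg.norm(conic)
    if conic[0] < 0:
        conic = -conic
    return conic


def kappa_contingency(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Cohen's kappa from an explicit 2x2 contingency table over two
    boolean arrays of identical shape.  Returns (kappa, Po, Pe)."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    n = a.size
    n11 = int(np.sum(a & b))
    n00 = int(np.sum(~a & ~b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    po = (n11 + n00) / n
    pa1, pb1 = (n11 + n10) / n, (n11 + n01) / n
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe >= 1.0 - 1e-15:
        return 1.0, po, pe
    return (po - pe) / (1 - pe), po, pe


def mu_d_polar(
    r_ref, r_test, angles_deg: np.ndarray
) -> float:
    """mu_d for analytic polar boundaries: mean |r_ref - r_test| over the
    given directions.  ``r_ref``/``r_test`` are callables of degrees."""
    angles = np.asarray(angles_deg, dtype=float)
    dr = np.array([float(r_ref(a)) for a in angles])
    dt = np.array([float(r_test(a)) for a in angles])
    return float(np.mean(np.abs(dr - dt)))


def ellipse_points(
    cx: float,
    cy: float,
    a: float,
    b: float,
    rot_rad: float,
    n: int = 100,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Points on (or noisily around) a parametric ellipse."""
    if rng is None:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    else:
        t = rng.uniform(0.0, 2 * np.pi, n)
    co, si = np.cos(rot_rad), np.sin(rot_rad)
    x = cx + a * np.cos(t) * co - b * np.sin(t) * si
    y = cy + a * np.cos(t) * si + b * np.sin(t) * co
    if noise_sd > 0:
        assert rng is not None
        x = x + rng.normal(0.0, noise_sd, n)
        y = y + rng.normal(0.0, noise_sd, n)
    return np.column_stack([x, y])


def circle_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean raster of a filled circle (pixel-center rule), built
    directly from the implicit equation — independent of the package's
    rasterizers."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def polar_shape_mask(
    shape: tuple[int, int], center: tuple[float, float], radius_fn, step_deg: float = 0.1
) -> np.ndarray:
    """Boolean raster of a star-convex region given by an analytic polar
    radius function, via per-pixel angle/radius test (no polygon code)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    rr = np.hypot(dx, dy)
    bound = np.asarray(radius_fn(theta), dtype=float)
    return rr <= bound
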