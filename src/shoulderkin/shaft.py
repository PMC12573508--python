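"""Humeral shaft axis estimation by least-squares cylinder fitting.

The humeral frame needs a superior-inferior shaft axis.  Clinical CT
truncates the elbow epicondyles, so instead of the ISB elbow-based axis the
shaft axis is recovered from a pre-selected cloud of cortical-surface points
(a roughly 50 mm non-tapering segment distal to the calcar) by fitting an
infinite circular cylinder in the least-squares sense:

    minimize  sum_i ( dist(p_i, axis) - r )^2

over the axis line and radius.  The solver is a damped Gauss-Newton
(Levenberg-Marquardt) iteration on a 5-parameter chart: two in-plane offsets
of the axis point, two direction angles, and the radius.  It is initialized
from the dominant principal direction of the centered cloud, which is within
a few degrees of the true axis for elongated shaft segments, so the damped
iteration converges in a handful of steps.

Region selection is deliberately *not* automated: choosing where the shaft
stops tapering is a manual, view-dependent step, and the input here is the
already-selected cloud.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShaftPointCloud",
    "CylinderFit",
    "InsufficientPointsError",
    "DegenerateCloudError",
    "fit_cylinder",
]

_MIN_POINTS = 50


class InsufficientPointsError(ValueError):
    """Fewer than the minimum number of shaft surface points."""


class DegenerateCloudError(ValueError):
    """Cloud geometry (planar/collinear) cannot constrain a cylinder."""


@dataclass(frozen=True)
class ShaftPointCloud:
    """N x 3 cortical-surface points (mm) from the pre-selected shaft region."""

    points: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
            raise ValueError("points must be a finite N x 3 array")
        if pts.shape[0] < _MIN_POINTS:
            raise InsufficientPointsError(
                f"need >= {_MIN_POINTS} shaft points, got {pts.shape[0]}"
            )
        extent = _principal_extent(pts)
        if extent < 10.0:
            raise DegenerateCloudError(
                f"cloud extent {extent:.1f} mm along principal direction; "
                "too short to constrain a shaft axis"
            )
        if not 20.0 <= extent <= 120.0:
            warnings.warn(
                f"shaft cloud extent {extent:.1f} mm outside the typical "
                "20-120 mm range",
                stacklevel=2,
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class CylinderFit:
    """Fitted axis (point + superiorly oriented unit direction), radius, residual."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    rms_residual: float
    iterations: int
    converged: bool
    cost_trace: np.ndarray = field(repr=False, default=None)


def _principal_extent(pts: np.ndarray) -> float:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[0]
    return float(proj.max() - proj.min())


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    st, ct = math.sin(theta), math.cos(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), ct])


def _residuals_and_jac(params, pts, centroid, e1, e2):
    """Residuals r_i = dist(p_i, axis) - radius and analytic Jacobian."""
    a, b, theta, phi, radius = params
    q = centroid + a * e1 + b * e2
    d = _dir_from_angles(theta, phi)
    w = pts - q
    wd = w @ d
    perp = w - np.outer(wd, d)
    rho = np.linalg.norm(perp, axis=1)
    rho_safe = np.where(rho < 1e-12, 1e-12, rho)
    u = perp / rho_safe[:, None]  # unit radial vectors
    res = rho - radius
    # d rho / d q = -u ; d rho / d d = -wd * (u . dD/dangle)
    dd_dtheta = np.array(
        [
            math.cos(theta) * math.cos(phi),
            math.cos(theta) * math.sin(phi),
            -math.sin(theta),
        ]
    )
    dd_dphi = np.array(
        [-math.sin(theta) * math.sin(phi), math.sin(theta) * math.cos(phi), 0.0]
    )
    jac = np.empty((pts.shape[0], 5))
    jac[:, 0] = -(u @ e1)
    jac[:, 1] = -(u @ e2)
    jac[:, 2] = -wd * (u @ dd_dtheta)
    jac[:, 3] = -wd * (u @ dd_dphi)
    jac[:, 4] = -1.0
    return res, jac


def fit_cylinder(
    cloud: ShaftPointCloud,
    superior_hint=None,
    max_iter: int = 200,
    rel_tol: float = 1e-12,
) -> CylinderFit:
    """Least-squares cylinder fit to a shaft point cloud.

    Parameters
    ----------
    cloud
        Pre-selected cortical-surface points.
    superior_hint
        Vector whose positive dot product with the fitted direction defines
        "superior"; defaults to +Y of the input coordinate system.
    max_iter, rel_tol
        Iteration cap and relative cost-change convergence criterion for the
        damped Gauss-Newton loop.

    Returns
    -------
    CylinderFit
        ``axis_point`` is the projection of the cloud centroid onto the
        fitted axis; ``cost_trace`` holds the (non-increasing) accepted cost
        after each iteration.  On non-convergence the best iterate is
        returned with ``converged=False`` and a warning.
    """
    pts = cloud.points
    centroid = pts.mean(axis=0)
    c = pts - centroid
    _, svals, vt = np.linalg.svd(c, full_matrices=False)
    if svals[1] < 1e-9 * svals[0]:
        raise DegenerateCloudError("points are collinear")
    d0 = vt[0]
    # complement basis fixed at the initial direction; the axis point moves
    # in this plane, which removes the gauge freedom along the axis
    e1 = vt[1]
    e2 = np.cross(d0, e1)
    theta0 = math.acos(max(-1.0, min(1.0, d0[2])))
    phi0 = math.atan2(d0[1], d0[0])
    perp0 = c - np.outer(c @ d0, d0)
    r0 = float(np.linalg.norm(perp0, axis=1).mean())
    if r0 < 1e-9:
        raise DegenerateCloudError("points lie on a line through the centroid")
    params = np.array([0.0, 0.0, theta0, phi0, r0])

    res, jac = _residuals_and_jac(params, pts, centroid, e1, e2)
    cost = float(res @ res)
    trace = [cost]
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        jtj = jac.T @ jac
        jtr = jac.T @ res
        accepted = False
        for _ in range(50):
            try:
                step = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj)), -jtr)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jtj + lam * np.eye(5), -jtr, rcond=None)[0]
            trial = params + step
            res_t, jac_t = _residuals_and_jac(trial, pts, centroid, e1, e2)
            cost_t = float(res_t @ res_t)
            if cost_t <= cost:
                params, res, jac = trial, res_t, jac_t
                prev = cost
                cost = cost_t
                lam = max(lam * 0.3, 1e-12)
                accepted = True
                break
            lam *= 10.0
        trace.append(cost)
        if not accepted:
            converged = True  # damping exhausted: at a (local) minimum
            break
        if prev - cost <= rel_tol * max(prev, 1e-300):
            converged = True
            break
    if not converged:
        warnings.warn("cylinder fit did not converge; returning best iterate")

    a, b, theta, phi, radius = params
    axis_dir = _dir_from_angles(theta, phi)
    q = centroid + a * e1 + b * e2
    hint = np.array([0.0, 1.0, 0.0]) if superior_hint is None else (
        np.asarray(superior_hint, dtype=float)
    )
    if float(axis_dir @ hint) < 0.0:
        axis_dir = -axis_dir
    axis_point = q + ((centroid - q) @ axis_dir) * axis_dir
    w = pts - axis_point
    rho = np.linalg.norm(w - np.outer(w @ axis_dir, axis_dir), axis=1)
    rms = float(np.sqrt(np.mean((rho - radius) ** 2)))
    return CylinderFit(
        axis_point=axis_point,
        axis_dir=axis_dir,
        radius=float(abs(radius)),
        rms_residual=rms,
        iterations=it,
        converged=converged,
        cost_trace=np.asarray(trace),
    )
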