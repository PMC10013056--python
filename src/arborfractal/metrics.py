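"""Connectivity and cost metrics of an arbor, and their balance across a
distortion ensemble.

Five quantities characterize how an arbor trades connectivity against cost:

* ``P`` — profile area (µm²): the area of the arbor's orthogonal projection,
  uniformly expanded by 2 µm to account for spine growth around each
  dendrite, averaged over viewing angles. A proxy for the potential to
  connect to passing axons.
* ``A_s`` — dendrite surface area (µm²): the membrane area, a proxy for
  metabolic operating cost.
* ``V_m`` — dendrite volume (µm³): the material in the branches, a proxy
  for building cost.
* ``A_b``, ``V_b`` — surface area and volume of the arbor's convex hull,
  used to normalize the above to the bounding region.

The balance ratios are derivatives with respect to the arbor dimension D_A
along a distortion ensemble:

    R_PA = d(P/A_b)/dD_A / d(A_s/A_b)/dD_A
    R_PV = d(P/A_b)/dD_A / d(V_m/V_b)/dD_A
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from .errors import DegenerateHullError, EmptyArborError, ParameterError
from .morphology import Arbor

DEFAULT_EXPANSION = 2.0  # µm, spine-growth allowance around each dendrite
DEFAULT_N_VIEWS = 64
_BUFFER_QUAD_SEGS = 32


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit directions on the sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _view_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(direction)))] = 1.0
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


def _silhouette_area(starts2d, ends2d, widths) -> float:
    geoms = []
    for a, b, w in zip(starts2d, ends2d, widths):
        if np.linalg.norm(b - a) < 1e-12:
            geoms.append(Point(a).buffer(w, quad_segs=_BUFFER_QUAD_SEGS))
        else:
            geoms.append(
                LineString([a, b]).buffer(w, quad_segs=_BUFFER_QUAD_SEGS)
            )
    return float(unary_union(geoms).area)


def profile_area(
    arbor: Arbor,
    expansion: float = DEFAULT_EXPANSION,
    n_views: int = DEFAULT_N_VIEWS,
) -> float:
    """Mean expanded profile area P (µm²).

    Each cylindrical segment projects to a stadium (capsule silhouette) of
    half-width radius + expansion; the areas of the unions are averaged
    over deterministic Fibonacci-sphere view directions.
    """
    if n_views < 1:
        raise ParameterError("n_views must be >= 1")
    if expansion < 0:
        raise ParameterError("expansion must be >= 0")
    starts, ends, radii, _ = arbor.segments()
    if len(starts) == 0:
        raise EmptyArborError("arbor has no segments")
    widths = radii + expansion
    areas = []
    for d in fibonacci_sphere(n_views):
        u, v = _view_basis(d)
        basis = np.column_stack([u, v])
        areas.append(_silhouette_area(starts @ basis, ends @ basis, widths))
    return float(np.mean(areas))


def dendrite_volume(arbor: Arbor) -> float:
    """Branch volume V_m (µm³): sum of cylinder volumes π r² L.

    Junction overlaps are ignored, consistent with the segment-wise model.
    """
    starts, ends, radii, _ = arbor.segments()
    if len(starts) == 0:
        raise EmptyArborError("arbor has no segments")
    lengths = np.linalg.norm(ends - starts, axis=1)
    return float(np.sum(np.pi * radii**2 * lengths))


def _cylinder_mesh(a, b, r, n_theta, n_axial):
    """Lateral-surface triangles of one cylinder: (n_tri, 3, 3) vertices."""
    axis = b - a
    L = np.linalg.norm(axis)
    t = axis / L
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t)))] = 1.0
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    ang = 2 * np.pi * np.arange(n_theta) / n_theta
    circle = r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    rings = [
        a + (k / n_axial) * axis + circle for k in range(n_axial + 1)
    ]  # each (n_theta, 3)
    tris = []
    for k in range(n_axial):
        lo, hi = rings[k], rings[k + 1]
        for i in range(n_theta):
            j = (i + 1) % n_theta
            tris.append([lo[i], lo[j], hi[i]])
            tris.append([hi[i], lo[j], hi[j]])
    return np.array(tris)


def _points_in_any_other_cylinder(points, own_seg, starts, ends, radii,
                                  chunk=20000):
    """Bool per point: strictly inside some cylinder other than own_seg."""
    axes = ends - starts
    L2 = np.einsum("ij,ij->i", axes, axes)
    inside = np.zeros(len(points), dtype=bool)
    others = np.arange(len(starts)) != own_seg
    s, e, ax, l2, rr = (
        starts[others], ends[others], axes[others], L2[others], radii[others]
    )
    for c0 in range(0, len(points), chunk):
        p = points[c0:c0 + chunk]
        rel = p[:, None, :] - s[None, :, :]          # (np, m, 3)
        t = np.einsum("pmk,mk->pm", rel, ax) / l2     # axial parameter
        radial2 = np.einsum("pmk,pmk->pm", rel, rel) - t**2 * l2
        hit = (t > 1e-9) & (t < 1 - 1e-9) & (radial2 < (rr - 1e-9) ** 2)
        inside[c0:c0 + chunk] = hit.any(axis=1)
    return inside


def dendrite_surface_area(arbor: Arbor, n_theta: int = 16,
                          n_axial: int = 2) -> float:
    """Dendrite surface area A_s (µm²).

    Each cylindrical segment's lateral surface is tessellated into
    triangles (``n_theta`` circumferential facets, ``n_axial`` axial
    subdivisions); triangles whose three corners all lie strictly inside
    another segment's cylinder are interior at junctions and removed before
    summing face areas.
    """
    starts, ends, radii, _ = arbor.segments()
    if len(starts) == 0:
        raise EmptyArborError("arbor has no segments")
    total = 0.0
    for i in range(len(starts)):
        tris = _cylinder_mesh(starts[i], ends[i], radii[i], n_theta, n_axial)
        verts = tris.reshape(-1, 3)
        inside = _points_in_any_other_cylinder(
            verts, i, starts, ends, radii
        ).reshape(len(tris), 3)
        keep = ~inside.all(axis=1)
        kept = tris[keep]
        if len(kept):
            cross = np.cross(kept[:, 1] - kept[:, 0], kept[:, 2] - kept[:, 0])
            total += 0.5 * np.linalg.norm(cross, axis=1).sum()
    return float(total)


def bounding_hull(arbor: Arbor) -> tuple[float, float]:
    """Convex hull surface area A_b (µm²) and volume V_b (µm³)."""
    pts = arbor.positions
    if len(pts) < 4:
        raise DegenerateHullError("need >= 4 nodes for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate (coplanar/collinear) arbor: {exc}"
        ) from None
    return float(hull.area), float(hull.volume)


@dataclass
class ArborMetrics:
    """The five connectivity/cost metrics of one arbor."""

    P: float
    A_s: float
    V_m: float
    A_b: float
    V_b: float

    @property
    def P_norm(self) -> float:
        return self.P / self.A_b

    @property
    def A_s_norm(self) -> float:
        return self.A_s / self.A_b

    @property
    def V_m_norm(self) -> float:
        return self.V_m / self.V_b


def compute_arbor_metrics(
    arbor: Arbor,
    expansion: float = DEFAULT_EXPANSION,
    n_views: int = DEFAULT_N_VIEWS,
    n_theta: int = 16,
    n_axial: int = 2,
) -> ArborMetrics:
    A_b, V_b = bounding_hull(arbor)
    return ArborMetrics(
        P=profile_area(arbor, expansion, n_views),
        A_s=dendrite_surface_area(arbor, n_theta, n_axial),
        V_m=dendrite_volume(arbor),
        A_b=A_b,
        V_b=V_b,
    )


@dataclass
class BalanceCurves:
    """Smoothed normalized metrics vs D_A and the derivative ratios.

    Each normalized metric is fit with a quadratic polynomial in D_A
    (coefficients in ``fits``, numpy polyfit order), differentiated
    analytically, and the derivative ratios R_PA and R_PV are evaluated on
    ``D_A_grid``. Grid points where the denominator derivative crosses
    zero are masked (NaN) and flagged in ``singular_mask``.
    """

    D_A_grid: np.ndarray
    fits: dict
    R_PA: np.ndarray
    R_PV: np.ndarray
    singular_mask_PA: np.ndarray
    singular_mask_PV: np.ndarray


def _ratio_on_grid(num_deriv, den_deriv, grid):
    den = np.polyval(den_deriv, grid)
    num = np.polyval(num_deriv, grid)
    scale = np.max(np.abs(den)) if np.max(np.abs(den)) > 0 else 1.0
    singular = np.abs(den) < 1e-6 * scale
    ratio = np.where(singular, np.nan, num / np.where(singular, 1.0, den))
    return ratio, singular


def balance_curves(ensemble: pd.DataFrame, degree: int = 2,
                   n_grid: int = 101) -> BalanceCurves:
    """Balance ratios R_PA and R_PV across a distortion ensemble.

    ``ensemble`` needs columns ``D_A``, ``P_norm``, ``A_s_norm``,
    ``V_m_norm`` — typically the per-α ensemble means. Requires at least 4
    distinct D_A values.
    """
    d = np.asarray(ensemble["D_A"], dtype=float)
    if len(np.unique(np.round(d, 12))) < 4:
        raise ParameterError("need >= 4 distinct D_A values for balance curves")
    fits = {
        key: np.polyfit(d, np.asarray(ensemble[key], dtype=float), degree)
        for key in ("P_norm", "A_s_norm", "V_m_norm")
    }
    grid = np.linspace(d.min(), d.max(), n_grid)
    dP = np.polyder(fits["P_norm"])
    dA = np.polyder(fits["A_s_norm"])
    dV = np.polyder(fits["V_m_norm"])
    R_PA, sing_PA = _ratio_on_grid(dP, dA, grid)
    R_PV, sing_PV = _ratio_on_grid(dP, dV, grid)
    return BalanceCurves(
        D_A_grid=grid, fits=fits, R_PA=R_PA, R_PV=R_PV,
        singular_mask_PA=sing_PA, singular_mask_PV=sing_PV,
    )
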