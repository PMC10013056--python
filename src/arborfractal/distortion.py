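"""Angle-multiplier distortion of dendritic arbors.

An arbor's geometry is decomposed into a lossless local representation:
per node, the segment length from its parent, the bend angle (weave θ or
fork ϕ) between the incoming and outgoing directions, and the azimuth of
the bending plane expressed in a parallel-transported frame. Multiplying
every bend angle by a common factor α and rebuilding positions depth-first
produces a distorted arbor whose branch path lengths are exactly preserved:
α < 1 straightens the branches toward the Euclidean limit, α > 1 makes
them curl up, and α = 1 reproduces the original arbor.

Bend scaling rotates the outgoing direction about the axis normal to the
(incoming, outgoing) plane; the torsion (azimuth) is untouched. At
collinear nodes (θ = 0) the bending axis is undefined but the scaled angle
is also 0, so no axis is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ParameterError
from .morphology import Arbor

CLIP_LIMIT = np.pi - 1e-6


@dataclass
class LocalGeometry:
    """Lossless angle/length representation of a soma-stripped arbor.

    Stem roots keep an absolute position and their first segment an
    absolute direction; every other node stores (length, bend, azimuth)
    relative to its parent's parallel-transported frame.
    """

    node_ids: np.ndarray
    parents: np.ndarray
    radii: np.ndarray
    types: np.ndarray
    name: str
    soma_centroid: np.ndarray | None
    root_positions: dict[int, np.ndarray]          # stem root id -> position
    stem_directions: dict[int, np.ndarray]         # first-child id -> unit dir
    lengths: dict[int, float]                      # node id -> segment length
    bends: dict[int, float]                        # node id -> bend angle
    azimuths: dict[int, float]                     # node id -> azimuth
    children: dict[int, list[int]] = field(repr=False, default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _perpendicular(t: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to unit vector t."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t)))] = 1.0
    n = np.cross(t, ref)
    return n / np.linalg.norm(n)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def decompose_to_angles(arbor: Arbor) -> LocalGeometry:
    """Decompose a soma-stripped arbor into lengths, bends and azimuths.

    Frames are parallel-transported along each path: the frame normal is
    rotated by each bend about the bending axis, so reconstruction with
    unmodified angles reproduces the original positions exactly.
    """
    children = arbor.children_map()
    geom = LocalGeometry(
        node_ids=arbor.ids.copy(),
        parents=arbor.parents.copy(),
        radii=arbor.radii.copy(),
        types=arbor.types.copy(),
        name=arbor.name,
        soma_centroid=None if arbor.soma_centroid is None
        else arbor.soma_centroid.copy(),
        root_positions={}, stem_directions={},
        lengths={}, bends={}, azimuths={}, children=children,
    )
    pos = {int(i): arbor.positions[k] for k, i in enumerate(arbor.ids)}

    for root in arbor.root_ids():
        geom.root_positions[root] = pos[root].copy()
        # (node, parent, frame t/n/b) stack; frame is None until the first
        # segment fixes an absolute direction
        stack = [(child, root, None) for child in reversed(children[root])]
        while stack:
            node, parent, frame = stack.pop()
            d = pos[node] - pos[parent]
            L = float(np.linalg.norm(d))
            if L == 0:
                raise DegenerateGeometryError(
                    f"zero-length segment into node {node}"
                )
            d = d / L
            geom.lengths[node] = L
            if frame is None:
                # stem first segment: absolute direction, no bend
                geom.stem_directions[node] = d.copy()
                t = d
                n = _perpendicular(t)
                new_frame = (t, n, np.cross(t, n))
            else:
                t, n, b = frame
                cosb = float(np.clip(t @ d, -1.0, 1.0))
                bend = float(np.arccos(cosb))
                geom.bends[node] = bend
                if bend < 1e-12:
                    geom.azimuths[node] = 0.0
                    new_frame = (d, n, np.cross(d, n))
                else:
                    # azimuth of the bending plane in the (n, b) frame
                    psi = float(np.arctan2(d @ b, d @ n))
                    geom.azimuths[node] = psi
                    axis = np.cross(t, d)
                    axis = axis / np.linalg.norm(axis)
                    n_new = _rotate(n, axis, bend)
                    new_frame = (d, n_new, np.cross(d, n_new))
            for child in reversed(children[node]):
                stack.append((child, node, new_frame))
    return geom


def apply_angle_multiplier(geom: LocalGeometry, alpha: float) -> Arbor:
    """Rebuild an arbor with every bend angle multiplied by ``alpha``.

    Torsions (azimuths) and segment lengths are unchanged, so every branch
    path length L_B is invariant. Scaled angles are clipped just below π;
    the number of clipped angles is recorded on the returned arbor as the
    attribute ``clip_count``. Values outside the physically reasonable
    0.5-2 range used for distortion ensembles trigger a warning.
    """
    if alpha < 0:
        raise ParameterError(f"angle multiplier must be >= 0, got {alpha}")
    if not (0.5 <= alpha <= 2.0) and alpha != 0.0:
        warnings.warn(
            f"alpha = {alpha} outside the physically reasonable range [0.5, 2]",
            stacklevel=2,
        )
    pos = {}
    clip_count = 0
    for root, rpos in geom.root_positions.items():
        pos[root] = rpos.copy()
        stack = [(child, root, None) for child in reversed(geom.children[root])]
        while stack:
            node, parent, frame = stack.pop()
            L = geom.lengths[node]
            if frame is None:
                d = geom.stem_directions[node]
                n = _perpendicular(d)
            else:
                t, n, b = frame
                bend = alpha * geom.bends[node]
                if bend > CLIP_LIMIT:
                    bend = CLIP_LIMIT
                    clip_count += 1
                if bend < 1e-12:
                    d = t
                else:
                    psi = geom.azimuths[node]
                    u = np.cos(psi) * n + np.sin(psi) * b
                    d = np.cos(bend) * t + np.sin(bend) * u
                    axis = np.cross(t, d)
                    axis = axis / np.linalg.norm(axis)
                    n = _rotate(n, axis, bend)
            pos[node] = pos[parent] + L * d
            new_frame = (d, n, np.cross(d, n))
            for child in reversed(geom.children[node]):
                stack.append((child, node, new_frame))
    positions = np.array([pos[int(i)] for i in geom.node_ids])
    arbor = Arbor(
        ids=geom.node_ids.copy(),
        positions=positions,
        radii=geom.radii.copy(),
        parents=geom.parents.copy(),
        types=geom.types.copy(),
        name=f"{geom.name}_alpha{alpha:g}" if geom.name else f"alpha{alpha:g}",
        soma_centroid=None if geom.soma_centroid is None
        else geom.soma_centroid.copy(),
    )
    arbor.clip_count = clip_count
    return arbor


def distort_arbor(arbor: Arbor, alpha: float) -> Arbor:
    """Convenience: decompose + apply multiplier in one call."""
    return apply_angle_multiplier(decompose_to_angles(arbor), alpha)


# -- self-intersection report ---------------------------------------------


def _segment_pair_distances(p1, p2, q1s, q2s):
    """Min distances between segment (p1,p2) and segments (q1s[i],q2s[i]).

    Vectorized closest-point-between-segments (clamped) computation.
    """
    d1 = p2 - p1                     # (3,)
    d2 = q2s - q1s                   # (m, 3)
    r = p1 - q1s                     # (m, 3)
    a = float(d1 @ d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1                       # r·d1 per row
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > 1e-30, (b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-30, (b * s + f) / np.where(e > 1e-30, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    # re-clamp s where t was clamped
    recl = t != t_cl
    if a > 1e-30:
        s = np.where(recl, np.clip((t_cl * b - c) / a, 0.0, 1.0), s)
    closest1 = p1 + np.outer(s, d1)
    closest2 = q1s + t_cl[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


@dataclass
class IntersectionReport:
    """Pairs of non-adjacent segments closer than their clearance."""

    pairs: pd.DataFrame           # seg_i, seg_j (child node ids), distance, clearance
    n_pairs_checked: int

    @property
    def offending_fraction(self) -> float:
        if self.n_pairs_checked == 0:
            return 0.0
        return len(self.pairs) / self.n_pairs_checked


def self_intersection_report(arbor: Arbor, clearance: float | None = None
                             ) -> IntersectionReport:
    """Report segment pairs from different parts of the arbor closer than
    ``clearance`` (default: the sum of the two segment radii).

    Pairs sharing a node (consecutive segments, or siblings at a branch
    point) are excluded: their contact is topological, not a collision.
    """
    starts, ends, radii, child_ids = arbor.segments()
    idx_map = {int(i): int(p) for i, p in zip(arbor.ids, arbor.parents)}
    seg_nodes = [
        (int(c), idx_map[int(c)]) for c in child_ids
    ]
    m = len(starts)
    rows = []
    checked = 0
    for i in range(m - 1):
        q1s = starts[i + 1:]
        q2s = ends[i + 1:]
        dists = _segment_pair_distances(starts[i], ends[i], q1s, q2s)
        if clearance is None:
            clear = radii[i] + radii[i + 1:]
        else:
            clear = np.full(m - i - 1, clearance)
        ni = set(seg_nodes[i])
        share = np.array(
            [bool(ni & set(seg_nodes[j])) for j in range(i + 1, m)]
        )
        valid = ~share
        checked += int(valid.sum())
        hit = valid & (dists < clear)
        for j in np.nonzero(hit)[0]:
            rows.append(
                {
                    "seg_i": seg_nodes[i][0],
                    "seg_j": seg_nodes[i + 1 + j][0],
                    "distance": float(dists[j]),
                    "clearance": float(clear[j]),
                }
            )
    return IntersectionReport(
        pairs=pd.DataFrame(rows, columns=["seg_i", "seg_j", "distance", "clearance"]),
        n_pairs_checked=checked,
    )
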