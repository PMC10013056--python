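"""Data model and I/O for 3D dendritic arbors.

An :class:`Arbor` is a rooted forest of cylindrical segments: each node has a
3D position (µm), a radius (µm) and a parent. Soma nodes (SWC type 1) are
tagged so the arbor can be soma-stripped before analysis; after stripping,
every former soma child becomes the root of its own dendrite stem and the
soma centroid is retained for the arbor-radius statistic R_A.

A :class:`Branch` is one soma-to-tip path: an ordered polyline with its
cumulative arc length, total path length L_B and end-to-end Euclidean
distance L_E. Distinct branches from the same subtree share their proximal
sections by construction (they reference the same node ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    EmptyArborError,
    SWCParseError,
    StructuralError,
)

SOMA_TYPE = 1
DENDRITE_TYPE = 3


@dataclass
class Arbor:
    """A rooted 3D tree (forest) of cylindrical segments.

    Parameters
    ----------
    ids : (n,) int array of node ids (unique).
    positions : (n, 3) float array, µm.
    radii : (n,) float array, µm, all > 0.
    parents : (n,) int array of parent node ids; -1 marks a root.
    types : (n,) int array of SWC type codes (1 = soma).
    name : identifier string.
    soma_centroid : retained after soma stripping; None for raw arbors
        that still carry their soma nodes.
    """

    ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    types: np.ndarray
    name: str = ""
    soma_centroid: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        if self.soma_centroid is not None:
            self.soma_centroid = np.asarray(self.soma_centroid, dtype=np.float64)
        self._validate()

    def _validate(self):
        n = len(self.ids)
        if self.positions.shape != (n, 3):
            raise StructuralError("positions must be (n, 3)")
        if len(np.unique(self.ids)) != n:
            raise StructuralError("duplicate node ids")
        if not np.all(np.isfinite(self.positions)):
            raise StructuralError("non-finite node position")
        if np.any(self.radii <= 0):
            bad = self.ids[self.radii <= 0]
            raise StructuralError(f"non-positive radius at node(s) {bad.tolist()}")
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        # orphan parents and cycles
        for k, p in enumerate(self.parents):
            if p != -1 and int(p) not in self._index:
                raise StructuralError(
                    f"node {int(self.ids[k])} references absent parent {int(p)}"
                )
        self._check_acyclic()

    def _check_acyclic(self):
        state = np.zeros(len(self.ids), dtype=np.int8)  # 0 new, 1 active, 2 done
        for start in range(len(self.ids)):
            if state[start]:
                continue
            chain = []
            k = start
            while k != -1 and state[k] == 0:
                state[k] = 1
                chain.append(k)
                p = int(self.parents[k])
                k = self._index[p] if p != -1 else -1
            if k != -1 and state[k] == 1:
                raise StructuralError(
                    f"cycle through node {int(self.ids[k])}"
                )
            for c in chain:
                state[c] = 2

    # -- topology helpers -------------------------------------------------

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def children_map(self) -> dict[int, list[int]]:
        """node id -> list of child node ids (in file order)."""
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parents):
            if p != -1:
                out[int(p)].append(int(i))
        return out

    @property
    def soma_ids(self) -> set[int]:
        return set(self.ids[self.types == SOMA_TYPE].tolist())

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def root_ids(self) -> list[int]:
        return [int(i) for i in self.ids[self.parents == -1]]

    def tip_ids(self) -> list[int]:
        has_child = set(int(p) for p in self.parents if p != -1)
        return [int(i) for i in self.ids if int(i) not in has_child]

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """All parent->child segments as (starts, ends, radii, child_ids).

        The radius of a segment is the child node's radius, matching the
        cylinder-per-node SWC convention.
        """
        mask = self.parents != -1
        child_idx = np.nonzero(mask)[0]
        parent_idx = np.array(
            [self._index[int(p)] for p in self.parents[mask]], dtype=np.int64
        )
        return (
            self.positions[parent_idx],
            self.positions[child_idx],
            self.radii[child_idx],
            self.ids[child_idx],
        )

    @property
    def R_A(self) -> float:
        """Arbor radius: max Euclidean distance from the soma centroid to
        any dendrite node (µm)."""
        centroid = self.soma_centroid
        if centroid is None:
            soma_mask = self.types == SOMA_TYPE
            if not soma_mask.any():
                raise EmptyArborError("no soma nodes and no stored soma centroid")
            centroid = self.positions[soma_mask].mean(axis=0)
        dend = self.positions[self.types != SOMA_TYPE]
        if len(dend) == 0:
            raise EmptyArborError("arbor has no dendrite nodes")
        return float(np.max(np.linalg.norm(dend - centroid, axis=1)))


@dataclass
class Branch:
    """One soma-to-tip path through an arbor.

    ``points`` run from the soma-attachment end to the tip; ``cum_len`` is
    the cumulative arc length at each point (``cum_len[0] == 0``).
    """

    node_ids: list[int]
    points: np.ndarray
    cum_len: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if len(self.points) < 2:
            raise DegenerateGeometryError("branch needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps <= 0):
            k = int(np.argmin(steps))
            raise DegenerateGeometryError(
                f"coincident consecutive points at index {k} "
                f"(node {self.node_ids[k]})"
            )
        if self.cum_len is None:
            self.cum_len = np.concatenate([[0.0], np.cumsum(steps)])
        else:
            self.cum_len = np.asarray(self.cum_len, dtype=np.float64)

    @property
    def L_B(self) -> float:
        """Total path length along the branch (µm)."""
        return float(self.cum_len[-1])

    @property
    def L_E(self) -> float:
        """Euclidean distance between the two branch ends (µm)."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tip_node(self) -> int:
        return self.node_ids[-1]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AngleSet:
    """Weave angles θ (one per interior continuation node) and fork angles
    ϕ (one per child of each branching node), in radians, all in [0, π)."""

    weave: list[tuple[int, float]]
    fork: list[tuple[int, int, float]]

    def weave_by_node(self) -> dict[int, float]:
        return {nid: th for nid, th in self.weave}

    def all_angles(self) -> np.ndarray:
        return np.array([a for _, a in self.weave] + [a for _, _, a in self.fork])


# -- SWC I/O ---------------------------------------------------------------


def read_swc(path, name: str | None = None) -> Arbor:
    """Read a 7-column SWC file (``id type x y z radius parent``).

    Coordinates and radii are taken as µm. Soma nodes are those with type
    code 1. Raises :class:`SWCParseError` on malformed fields and
    :class:`StructuralError` on orphan parents or cycles.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"expected 7 fields, got {len(fields)}", lineno
                )
            try:
                nid = int(fields[0])
                ntype = int(fields[1])
                pos = [float(fields[2]), float(fields[3]), float(fields[4])]
                rad = float(fields[5])
                par = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(f"non-numeric field ({exc})", lineno) from None
            ids.append(nid)
            types.append(ntype)
            xyz.append(pos)
            radii.append(rad)
            parents.append(par)
    if not ids:
        raise EmptyArborError(f"no nodes in {path}")
    import os

    return Arbor(
        ids=np.array(ids),
        positions=np.array(xyz),
        radii=np.array(radii),
        parents=np.array(parents),
        types=np.array(types),
        name=name if name is not None else os.path.splitext(os.path.basename(str(path)))[0],
    )


def write_swc(arbor: Arbor, path) -> None:
    """Write an arbor as 7-column SWC. Floats use a round-trip ('%.17g')
    representation so read_swc(write_swc(a)) reproduces a exactly."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(arbor.n_nodes):
            x, y, z = arbor.positions[k]
            fh.write(
                f"{int(arbor.ids[k])} {int(arbor.types[k])} "
                f"{x:.17g} {y:.17g} {z:.17g} "
                f"{arbor.radii[k]:.17g} {int(arbor.parents[k])}\n"
            )


def read_segment_list(path, name: str = "") -> Arbor:
    """Read the plain-text segment-list companion format.

    CSV with header ``parent_x,parent_y,parent_z,child_x,child_y,child_z,
    radius`` (µm). Topology is recovered by exact coordinate matching of
    each segment's parent point against previously seen child points; parent
    points never seen as children become stem roots. The resulting arbor
    carries no soma nodes; the soma centroid is set to the root centroid.
    """
    df = pd.read_csv(path)
    expected = [
        "parent_x", "parent_y", "parent_z",
        "child_x", "child_y", "child_z", "radius",
    ]
    if list(df.columns) != expected:
        raise SWCParseError(f"expected columns {expected}, got {list(df.columns)}")
    point_to_id: dict[tuple, int] = {}
    ids, xyz, radii, parents, types = [], [], [], [], []

    def intern(pt, radius, parent_id):
        key = tuple(np.round(pt, 9))
        if key in point_to_id:
            return point_to_id[key]
        nid = len(ids) + 1
        point_to_id[key] = nid
        ids.append(nid)
        xyz.append(list(pt))
        radii.append(radius)
        parents.append(parent_id)
        types.append(DENDRITE_TYPE)
        return nid

    for row in df.itertuples(index=False):
        ppt = (row.parent_x, row.parent_y, row.parent_z)
        cpt = (row.child_x, row.child_y, row.child_z)
        pid = intern(ppt, row.radius, -1)
        cid = intern(cpt, row.radius, pid)
        # a child point seen before keeps its first parent assignment
        k = cid - 1
        if parents[k] == -1 and cid != pid:
            parents[k] = pid
    arbor = Arbor(
        ids=np.array(ids),
        positions=np.array(xyz),
        radii=np.array(radii),
        parents=np.array(parents),
        types=np.array(types),
        name=name,
    )
    roots = arbor.positions[arbor.parents == -1]
    arbor.soma_centroid = roots.mean(axis=0)
    return arbor


def write_segment_list(arbor: Arbor, path) -> None:
    starts, ends, radii, _ = arbor.segments()
    df = pd.DataFrame(
        {
            "parent_x": starts[:, 0], "parent_y": starts[:, 1], "parent_z": starts[:, 2],
            "child_x": ends[:, 0], "child_y": ends[:, 1], "child_z": ends[:, 2],
            "radius": radii,
        }
    )
    df.to_csv(path, index=False)


# -- core operations -------------------------------------------------------


def strip_soma(arbor: Arbor) -> Arbor:
    """Remove soma nodes, leaving only the arbor's dendrites.

    Each former soma child becomes a stem root anchored at its own first
    point. The soma centroid is retained on the returned arbor so R_A can
    still be computed.
    """
    soma_mask = arbor.types == SOMA_TYPE
    if not soma_mask.any():
        raise EmptyArborError("arbor has no soma nodes to strip")
    if soma_mask.all():
        raise EmptyArborError("arbor has no dendrite nodes")
    centroid = arbor.positions[soma_mask].mean(axis=0)
    soma_ids = set(arbor.ids[soma_mask].tolist())
    keep = ~soma_mask
    new_parents = arbor.parents[keep].copy()
    for k, p in enumerate(new_parents):
        if int(p) in soma_ids:
            new_parents[k] = -1
    return Arbor(
        ids=arbor.ids[keep],
        positions=arbor.positions[keep],
        radii=arbor.radii[keep],
        parents=new_parents,
        types=arbor.types[keep],
        name=arbor.name,
        soma_centroid=centroid,
    )


def extract_branches(arbor: Arbor) -> list[Branch]:
    """Decompose a soma-stripped arbor into its branches.

    A branch is any path from a stem root to a dendrite tip, so there is
    exactly one branch per tip and sibling branches share their proximal
    sections (the same node ids and points).
    """
    parent_of = {int(i): int(p) for i, p in zip(arbor.ids, arbor.parents)}
    branches = []
    for tip in sorted(arbor.tip_ids()):
        path = [tip]
        while parent_of[path[-1]] != -1:
            path.append(parent_of[path[-1]])
        path.reverse()
        pts = arbor.positions[[arbor.index_of(n) for n in path]]
        branches.append(Branch(node_ids=path, points=pts, name=f"{arbor.name}:{tip}"))
    return branches


def measure_angles(arbor: Arbor) -> AngleSet:
    """Measure weave angles θ and fork angles ϕ on a soma-stripped arbor.

    θ at an interior continuation node is the angle between the incoming and
    outgoing direction vectors (adjacent node positions only, no smoothing).
    At a branching node every child contributes one ϕ — its first weave
    angle after the branch point. Stem roots have no incoming direction and
    carry no angle.
    """
    children = arbor.children_map()
    weave: list[tuple[int, float]] = []
    fork: list[tuple[int, int, float]] = []
    for k, nid in enumerate(arbor.ids):
        nid = int(nid)
        p = int(arbor.parents[k])
        kids = children[nid]
        if p == -1 or not kids:
            continue
        v_in = arbor.positions[k] - arbor.positions[arbor.index_of(p)]
        n_in = np.linalg.norm(v_in)
        if n_in == 0:
            raise DegenerateGeometryError(f"zero-length segment into node {nid}")
        for child in kids:
            v_out = arbor.positions[arbor.index_of(child)] - arbor.positions[k]
            n_out = np.linalg.norm(v_out)
            if n_out == 0:
                raise DegenerateGeometryError(
                    f"zero-length segment from node {nid} to {child}"
                )
            cosang = np.clip(v_in @ v_out / (n_in * n_out), -1.0, 1.0)
            ang = float(np.arccos(cosang))
            if len(kids) == 1:
                weave.append((nid, ang))
            else:
                fork.append((nid, child, ang))
    return AngleSet(weave=weave, fork=fork)


def branch_table(branches: list[Branch]) -> pd.DataFrame:
    """Branch summary export: branch_id, tip_node, L_B, L_E, n_points."""
    return pd.DataFrame(
        {
            "branch_id": [b.name for b in branches],
            "tip_node": [b.tip_node for b in branches],
            "L_B": [b.L_B for b in branches],
            "L_E": [b.L_E for b in branches],
            "n_points": [len(b) for b in branches],
        }
    )
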