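"""Synthetic dendritic morphologies for testing the full pipeline.

The generators emulate the statistics of CA1 pyramidal basal arbors: about
32 soma-to-tip dendrites per arbor, segment lengths with a 2.4 µm median,
0.7 µm dendrite radii (1.4 µm width), an arbor radius around 100 µm and a
mild fractal weave giving branch dimensions near 1.04. Individual branches
are correlated random walks: each step bends by a folded-normal angle about
a uniformly random torsion axis. An H-tree of tunable scaling ratio
provides a deterministic fixture of known fractal dimension
D = log 2 / log(1/ratio).

All generators are fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .morphology import SOMA_TYPE, DENDRITE_TYPE, Arbor, Branch

#: weave bend magnitude (rad) for a standalone free branch, calibrated so
#: its pooled tortuosity dimension lands near the mild CA1 branch dimension
#: ~1.04; arbor-grown branches use a smaller intrinsic bend because
#: self-avoidance deflections supply part of the natural weave
NATURAL_THETA_MEAN = 0.25


def _unit(v):
    return v / np.linalg.norm(v)


def _perp(t):
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t)))] = 1.0
    return _unit(np.cross(t, ref))


def _step_direction(t, bend, azimuth):
    """Rotate unit direction t by ``bend`` about a torsion axis at
    ``azimuth`` in the plane perpendicular to t."""
    n = _perp(t)
    b = np.cross(t, n)
    u = np.cos(azimuth) * n + np.sin(azimuth) * b
    return np.cos(bend) * t + np.sin(bend) * u


def make_straight_branch(n_segments: int, seg_len: float) -> Branch:
    """A perfectly straight branch: the Euclidean limit with dimension 1."""
    if n_segments < 2:
        raise ParameterError("need >= 2 segments")
    if seg_len <= 0:
        raise ParameterError("segment length must be positive")
    n = n_segments + 1
    pts = np.zeros((n, 3))
    pts[:, 0] = seg_len * np.arange(n)
    return Branch(node_ids=list(range(1, n + 1)), points=pts, name="straight")


def make_weave_branch(
    n_segments: int,
    seg_len: float,
    theta_mean: float,
    seed: int,
    theta_sigma: float | None = None,
) -> Branch:
    """A weaving branch: correlated random walk with folded-normal bends.

    Each step bends by |N(theta_mean, theta_sigma)| (sigma defaults to
    theta_mean / 3) about a uniformly random torsion axis. theta_mean -> 0
    recovers the straight limit.
    """
    if not (0 < theta_mean <= np.pi / 4):
        raise ParameterError("theta_mean must be in (0, π/4]")
    if theta_sigma is None:
        theta_sigma = theta_mean / 3.0
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    t = np.array([1.0, 0.0, 0.0])
    for _ in range(n_segments):
        bend = abs(rng.normal(theta_mean, theta_sigma))
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        t = _unit(_step_direction(t, bend, azimuth))
        pts.append(pts[-1] + seg_len * t)
    n = len(pts)
    return Branch(
        node_ids=list(range(1, n + 1)), points=np.array(pts), name="weave"
    )


@dataclass
class ArborRecipe:
    """Parameters of the synthetic CA1-like basal arbor generator.

    Defaults are the natural study conditions: 5 stems branching out to
    ~32 tips, lognormal segment lengths with 2.4 µm median, 0.7 µm radii,
    ~100 µm radial extent, and the calibrated natural weave.
    """

    n_stems: int = 5
    target_tips: int = 32
    seg_len_median: float = 2.4      # µm
    seg_len_sigma: float = 0.35      # lognormal shape
    radius: float = 0.7              # µm, constant per arbor
    theta_mean: float = 0.15         # rad, intrinsic weave bend magnitude;
                                     # self-avoidance deflections add the rest
                                     # of the natural branch weave
    theta_sigma: float | None = None         # defaults to theta_mean / 3
    fork_phi_mean: float = 0.5       # rad, first weave angle after a fork
    max_extent: float = 100.0        # µm, radial distance where tips stop
    bifurcation_prob: float | None = None    # per-node; None = radial shells
    branch_zone: float = 0.4         # fraction of the extent containing the
                                     # bifurcation shells (CA1 basal dendrites
                                     # bifurcate close to the soma)
    hemisphere: bool = True          # basal arbors grow to one side of the soma
    stem_cone: float = 0.4           # rad: stems leave the soma inside this
                                     # half-angle cone and diverge by their
                                     # proximal bends (self-avoidance)
    repulsion_strength: float = 0.3  # self-avoidance: blend weight of the
    repulsion_radius: float = 12.0   # repulsion field (µm) from existing nodes
    seed: int = 0

    def __post_init__(self):
        if self.n_stems < 1 or self.target_tips < self.n_stems:
            raise ParameterError("need 1 <= n_stems <= target_tips")
        for name in ("seg_len_median", "radius", "theta_mean",
                     "fork_phi_mean", "max_extent"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def _stem_levels(n_stems: int, target_tips: int) -> list[int]:
    """Bifurcation generations per stem so total tips ~= target_tips."""
    base = max(0, int(np.floor(np.log2(max(target_tips / n_stems, 1)))))
    levels = [base] * n_stems
    i = 0
    while sum(2**lv for lv in levels) < target_tips and i < n_stems:
        levels[i] += 1
        if sum(2**lv for lv in levels) > target_tips:
            levels[i] -= 1
            break
        i += 1
    return levels


def make_synthetic_arbor(recipe: ArborRecipe) -> Arbor:
    """Generate a soma-rooted synthetic arbor from a recipe.

    Stems leave the soma in well-spread directions and all active tips grow
    in lockstep as correlated random walks that softly repel the dendrite
    already laid down — natural arbors are self-avoiding, and this mutual
    avoidance is what angle distortions later disturb. By default each path
    bifurcates when it first crosses one of its stem's radial shells
    (spaced out to the recipe extent), which keeps the tip count within a
    few of the target; alternatively a per-node ``bifurcation_prob`` gives
    fully stochastic topology. Tips terminate at the recipe's radial
    extent.
    """
    rng = np.random.default_rng(recipe.seed)
    theta_sigma = (
        recipe.theta_sigma if recipe.theta_sigma is not None
        else recipe.theta_mean / 3.0
    )
    mu = np.log(recipe.seg_len_median)

    ids = [1]
    positions = [np.zeros(3)]
    radii = [5.0]  # soma ball
    parents = [-1]
    types = [SOMA_TYPE]
    next_id = [2]

    def add_node(pos, parent):
        nid = next_id[0]
        next_id[0] += 1
        ids.append(nid)
        positions.append(pos)
        radii.append(recipe.radius)
        parents.append(parent)
        types.append(DENDRITE_TYPE)
        return nid

    levels = _stem_levels(recipe.n_stems, recipe.target_tips)
    # stems well-spread over the sphere (or, like basal arbors leaving the
    # soma into the stratum oriens, over one hemisphere), then given a
    # seeded random rotation of the whole arbor
    from .metrics import fibonacci_sphere

    if recipe.hemisphere:
        # stems packed into a cone about +z: they fan out into the
        # hemisphere through their own (angle-encoded) proximal bends
        n = recipe.n_stems
        k = np.arange(n) + 0.5
        z = 1.0 - (1.0 - np.cos(recipe.stem_cone)) * k / n
        az = np.pi * (1.0 + np.sqrt(5.0)) * k
        rho = np.sqrt(1.0 - z**2)
        stem_dirs = np.column_stack(
            [rho * np.cos(az), rho * np.sin(az), z]
        )
    else:
        stem_dirs = fibonacci_sphere(recipe.n_stems)
    # random rotation via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    stem_dirs = stem_dirs @ q

    max_nodes_per_path = int(8 * recipe.max_extent / recipe.seg_len_median)

    def sample_len():
        return float(np.exp(rng.normal(mu, recipe.seg_len_sigma)))

    def repel(pos, own_recent):
        """Unit repulsion direction away from nearby foreign dendrite."""
        if recipe.repulsion_strength <= 0 or len(positions) < 3:
            return None
        pts = np.asarray(positions[1:])  # skip soma
        rel = pos - pts
        d2 = np.einsum("ij,ij->i", rel, rel)
        mask = d2 < recipe.repulsion_radius**2
        for k in own_recent:
            if 0 <= k - 1 < len(mask):
                mask[k - 1] = False
        if not mask.any():
            return None
        d2m = np.maximum(d2[mask], 1e-6)
        u = (rel[mask] / d2m[:, None] ** 1.5).sum(axis=0)
        norm = np.linalg.norm(u)
        return u / norm if norm > 0 else None

    # active tips advance in lockstep so avoidance is mutual
    fork_budget = [2 * recipe.target_tips]  # guards the probabilistic mode
    tips = []
    for s in range(recipe.n_stems):
        lv = levels[s]
        shells = (recipe.max_extent * recipe.branch_zone
                  * (np.arange(1, lv + 1) / (lv + 1)))
        t0 = _unit(stem_dirs[s])
        first = t0 * sample_len()
        nid = add_node(first, 1)
        tips.append(
            {"pos": first, "t": t0, "parent": nid, "shells": shells,
             "shell_idx": 0, "steps": 1, "recent": [len(ids) - 1]}
        )
    while tips:
        new_tips = []
        for tip in tips:
            bend = abs(rng.normal(recipe.theta_mean, theta_sigma))
            azimuth = rng.uniform(0, 2 * np.pi)
            t = _unit(_step_direction(tip["t"], bend, azimuth))
            u = repel(tip["pos"], tip["recent"])
            if u is not None:
                t = _unit(t + recipe.repulsion_strength * u)
            pos = tip["pos"] + sample_len() * t
            parent = add_node(pos, tip["parent"])
            recent = (tip["recent"] + [len(ids) - 1])[-8:]
            steps = tip["steps"] + 1
            r = np.linalg.norm(pos)
            if r >= recipe.max_extent or steps >= max_nodes_per_path:
                continue
            if recipe.bifurcation_prob is not None:
                do_fork = (
                    fork_budget[0] > 0
                    and rng.uniform() < recipe.bifurcation_prob
                )
            else:
                do_fork = (
                    tip["shell_idx"] < len(tip["shells"])
                    and r >= tip["shells"][tip["shell_idx"]]
                )
            if do_fork:
                fork_budget[0] -= 1
                psi0 = rng.uniform(0, 2 * np.pi)
                for k in (0, 1):
                    phi = abs(rng.normal(recipe.fork_phi_mean,
                                         recipe.fork_phi_mean / 3))
                    t_child = _unit(_step_direction(t, phi, psi0 + k * np.pi))
                    child_pos = pos + sample_len() * t_child
                    child = add_node(child_pos, parent)
                    new_tips.append(
                        {"pos": child_pos, "t": t_child, "parent": child,
                         "shells": tip["shells"],
                         "shell_idx": tip["shell_idx"] + 1,
                         "steps": steps + 1,
                         "recent": recent + [len(ids) - 1]}
                    )
            else:
                new_tips.append(
                    {"pos": pos, "t": t, "parent": parent,
                     "shells": tip["shells"], "shell_idx": tip["shell_idx"],
                     "steps": steps, "recent": recent}
                )
        tips = new_tips

    return Arbor(
        ids=np.array(ids),
        positions=np.array(positions),
        radii=np.array(radii),
        parents=np.array(parents),
        types=np.array(types),
        name=f"synthetic_seed{recipe.seed}",
    )


def make_h_tree(levels: int, length_ratio: float,
                trunk_len: float = 120.0) -> Arbor:
    """Deterministic planar H-tree embedded in 3D (z = 0).

    The trunk leaves the soma along +y; at each generation two children
    leave perpendicular to their parent with lengths scaled by
    ``length_ratio``. Theoretical fractal dimension:
    D = log 2 / log(1 / length_ratio).
    """
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    if not (0 < length_ratio < 1):
        raise ParameterError("length_ratio must be in (0, 1)")
    ids = [1]
    positions = [np.zeros(3)]
    radii = [5.0]
    parents = [-1]
    types = [SOMA_TYPE]
    counter = [2]

    def add(pos, parent, radius=0.7):
        nid = counter[0]
        counter[0] += 1
        ids.append(nid)
        positions.append(np.asarray(pos, dtype=float))
        radii.append(radius)
        parents.append(parent)
        types.append(DENDRITE_TYPE)
        return nid

    def recurse(pos, direction, length, parent, level):
        tip = pos + direction * length
        nid = add(tip, parent)
        if level < levels:
            perp = np.array([-direction[1], direction[0], 0.0])
            for sgn in (1.0, -1.0):
                recurse(tip, sgn * perp, length * length_ratio, nid, level + 1)

    recurse(np.zeros(3), np.array([0.0, 1.0, 0.0]), trunk_len, 1, 0)
    return Arbor(
        ids=np.array(ids),
        positions=np.array(positions),
        radii=np.array(radii),
        parents=np.array(parents),
        types=np.array(types),
        name=f"htree_L{levels}_r{length_ratio:g}",
    )


def h_tree_dimension(length_ratio: float) -> float:
    """Theoretical H-tree dimension log 2 / log(1/ratio)."""
    return float(np.log(2.0) / np.log(1.0 / length_ratio))


def natural_recipe(seed: int = 0, **overrides) -> ArborRecipe:
    """The calibrated natural-statistics recipe (α = 1 study conditions)."""
    return replace(ArborRecipe(seed=seed), **overrides)
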