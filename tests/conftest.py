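"""Shared fixtures: small deterministic morphologies and the natural
synthetic ensemble with its distortion sweep (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import arborfractal as af

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from arborfractal.synthetic import ArborRecipe

ENSEMBLE_SEEDS = (1, 2, 3, 4, 5)
ENSEMBLE_ALPHAS = (0.5, 0.75, 1.0, 1.5, 2.0)


@pytest.fixture
def straight_branch():
    return af.make_straight_branch(100, 2.5)


@pytest.fixture
def weave_branch():
    return af.make_weave_branch(60, 2.4, 0.25, seed=7)


@pytest.fixture
def elbow_branch():
    """3-4-5 right triangle: legs 3 and 4 µm at a right angle."""
    pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
    return af.Branch(node_ids=[1, 2, 3], points=pts)


def simple_arbor_nodes():
    """Fig-style topology: soma, stem S, bifurcations B1 and B2, tips
    E1-E3. Returns the raw SWC-like arrays."""
    #            id type x     y    z   r  parent
    rows = [
        (1, 1, 0.0, 0.0, 0.0, 5.0, -1),     # soma
        (2, 3, 10.0, 0.0, 0.0, 1.0, 1),     # S -> B1 path
        (3, 3, 20.0, 0.0, 0.0, 1.0, 2),     # B1
        (4, 3, 30.0, 5.0, 0.0, 1.0, 3),     # B1 -> B2
        (5, 3, 40.0, 10.0, 0.0, 1.0, 4),    # B2
        (6, 3, 50.0, 20.0, 0.0, 1.0, 5),    # E1
        (7, 3, 50.0, 0.0, 0.0, 1.0, 5),     # E2
        (8, 3, 30.0, -10.0, 0.0, 1.0, 3),   # B1 -> E3
        (9, 3, 40.0, -20.0, 0.0, 1.0, 8),   # E3
    ]
    return rows


@pytest.fixture
def branched_arbor():
    rows = simple_arbor_nodes()
    return af.Arbor(
        ids=np.array([r[0] for r in rows]),
        positions=np.array([[r[2], r[3], r[4]] for r in rows]),
        radii=np.array([r[5] for r in rows]),
        parents=np.array([r[6] for r in rows]),
        types=np.array([r[1] for r in rows]),
        name="fig1d",
    )


@pytest.fixture
def natural_arbor():
    return af.make_synthetic_arbor(ArborRecipe(seed=1))


@pytest.fixture
def stripped_natural(natural_arbor):
    return af.strip_soma(natural_arbor)


@pytest.fixture(scope="session")
def natural_ensemble():
    """Stripped natural-recipe arbors plus their local-geometry decompositions."""
    arbors, geoms = [], []
    for seed in ENSEMBLE_SEEDS:
        s = af.strip_soma(af.make_synthetic_arbor(ArborRecipe(seed=seed)))
        arbors.append(s)
        geoms.append(af.decompose_to_angles(s))
    return {"arbors": arbors, "geoms": geoms}


def _mean_branch_dimension(arbor):
    vals = [
        af.fit_branch_dimension(af.coastline_scaling(b)).D
        for b in af.extract_branches(arbor)
        if b.L_E >= 40.0
    ]
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def distortion_sweep_stats(natural_ensemble):
    """Per-α ensemble means of D_A and ⟨D_BC⟩ over the natural recipe."""
    da = {al: [] for al in ENSEMBLE_ALPHAS}
    dbc = {al: [] for al in ENSEMBLE_ALPHAS}
    for geom in natural_ensemble["geoms"]:
        for al in ENSEMBLE_ALPHAS:
            distorted = af.apply_angle_multiplier(geom, al)
            da[al].append(af.arbor_dimension(distorted).D)
            dbc[al].append(_mean_branch_dimension(distorted))
    return {
        "D_A": {al: float(np.mean(v)) for al, v in da.items()},
        "mean_D_BC": {al: float(np.mean(v)) for al, v in dbc.items()},
    }
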