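"""Coastline (divider) segmentation and the D_BC / D_BCN fits."""

import numpy as np
import pytest

import arborfractal as af
from arborfractal.coastline import ScalingTable, branch_excluded
from arborfractal.errors import (
    InsufficientDataError,
    ParameterError,
    RangeError,
)


def oracle_segmentation(branch, L_R, step=1e-2, tol=1e-12):
    """Independent dense-marching oracle.

    Walks the polyline in small arc-length steps from the current ruler
    centre, records the first step at which the distance from the centre
    reaches L_R, and refines the crossing by bisection on arc length.
    """
    cum = branch.cum_len
    pts = branch.points

    def point_at(s):
        x = np.interp(s, cum, pts[:, 0])
        y = np.interp(s, cum, pts[:, 1])
        z = np.interp(s, cum, pts[:, 2])
        return np.array([x, y, z])

    L_total = branch.L_B
    s0 = 0.0
    centre = pts[0]
    n_full = 0
    while True:
        grid = np.arange(s0 + step, L_total + step / 2, step)
        if len(grid) == 0:
            break
        gx = np.interp(grid, cum, pts[:, 0])
        gy = np.interp(grid, cum, pts[:, 1])
        gz = np.interp(grid, cum, pts[:, 2])
        dist = np.sqrt(
            (gx - centre[0]) ** 2 + (gy - centre[1]) ** 2 + (gz - centre[2]) ** 2
        )
        hits = np.nonzero(dist >= L_R)[0]
        if len(hits) == 0:
            break
        k = hits[0]
        lo = grid[k] - step if k > 0 else s0
        hi = grid[k]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(point_at(mid) - centre) >= L_R:
                hi = mid
            else:
                lo = mid
        s0 = hi
        centre = point_at(s0)
        n_full += 1
    truncated = 0.0
    if s0 < L_total - 1e-9:
        truncated = float(np.linalg.norm(pts[-1] - centre))
    return n_full + truncated / L_R


class TestSegmentWithRuler:
    def test_straight_branch_exact_count(self, straight_branch):
        seg = af.segment_with_ruler(straight_branch, 10.0)
        assert seg.n_full == 25
        assert seg.truncated_len == pytest.approx(0.0, abs=1e-9)
        assert seg.N == pytest.approx(25.0)
        assert seg.L_T == pytest.approx(250.0)

    def test_fractional_truncated_ruler(self):
        """12 full rulers at L_R = 10 µm plus a 2 µm remainder count as 12.2."""
        branch = af.make_straight_branch(61, 2.0)  # 122 µm
        seg = af.segment_with_ruler(branch, 10.0)
        assert seg.n_full == 12
        assert seg.truncated_len == pytest.approx(2.0, abs=1e-9)
        assert seg.N == pytest.approx(12.2, abs=1e-12)

    def test_endpoints_lie_on_branch(self, weave_branch):
        seg = af.segment_with_ruler(weave_branch, 7.0)
        cum = weave_branch.cum_len
        pts = weave_branch.points
        for e in seg.ruler_endpoints:
            d = np.min(np.linalg.norm(pts - e, axis=1))
            # endpoint is on some segment: project onto each segment
            best = np.inf
            for a, b in zip(pts[:-1], pts[1:]):
                ab = b - a
                t = np.clip((e - a) @ ab / (ab @ ab), 0, 1)
                best = min(best, np.linalg.norm(a + t * ab - e))
            assert best < 1e-6
        assert np.allclose(seg.ruler_endpoints[0], pts[0])
        assert np.allclose(seg.ruler_endpoints[-1], pts[-1])

    def test_full_rulers_have_exact_length(self, weave_branch):
        seg = af.segment_with_ruler(weave_branch, 6.0)
        steps = np.linalg.norm(np.diff(seg.ruler_endpoints, axis=0), axis=1)
        n = seg.n_full
        assert np.allclose(steps[:n], 6.0, atol=1e-9)

    def test_zigzag_matches_oracle(self):
        # planar zigzag, 5 µm legs at right angles
        pts = [np.zeros(3)]
        d = np.array([1.0, 0, 0])
        for k in range(12):
            pts.append(pts[-1] + 5.0 * d)
            d = np.array([d[1], d[0], 0.0]) if k % 2 == 0 else np.array(
                [d[1], -d[0], 0.0])
        branch = af.Branch(node_ids=list(range(1, 14)), points=np.array(pts))
        seg = af.segment_with_ruler(branch, 6.0)
        assert seg.N == pytest.approx(oracle_segmentation(branch, 6.0), abs=1e-6)

    def test_matches_oracle_on_random_branches(self):
        """Exact quadratic marching equals dense-sampling oracle, 100 branches."""
        rng = np.random.default_rng(42)
        for k in range(100):
            branch = af.make_weave_branch(
                30, 2.4, float(rng.uniform(0.1, 0.6)), seed=int(rng.integers(2**31))
            )
            L_R = float(rng.uniform(4.0, 15.0))
            seg = af.segment_with_ruler(branch, L_R)
            assert seg.N == pytest.approx(
                oracle_segmentation(branch, L_R), abs=1e-6
            ), f"branch {k}, L_R={L_R}"

    def test_invalid_ruler_length(self, straight_branch):
        with pytest.raises(ParameterError):
            af.segment_with_ruler(straight_branch, 0.0)


class TestCoastlineScaling:
    def test_straight_branch_counts(self, straight_branch):
        # 100 µm branch
        branch = af.make_straight_branch(40, 2.5)
        table = af.coastline_scaling(branch, [4.0, 8.0, 16.0, 32.0])
        assert np.allclose(table.counts, [25.0, 12.5, 6.25, 3.125])
        assert np.allclose(table.normalized, np.array([4, 8, 16, 32]) / 100.0)

    def test_single_fractional_ruler(self):
        branch = af.make_straight_branch(2, 1.0)  # 2 µm long
        table = af.coastline_scaling(branch, [8.0])
        assert table.counts[0] == pytest.approx(0.25)
        assert table.counts[0] < 1

    def test_counts_non_increasing(self, weave_branch):
        table = af.coastline_scaling(weave_branch)
        assert np.all(np.diff(table.counts) <= 1e-9)

    def test_scale_invariance(self, weave_branch):
        """Scaling coordinates and rulers by k leaves N unchanged."""
        k = 3.7
        scaled = af.Branch(
            node_ids=weave_branch.node_ids, points=weave_branch.points * k
        )
        grid = np.array([5.0, 10.0, 20.0])
        n1 = af.coastline_scaling(weave_branch, grid).counts
        n2 = af.coastline_scaling(scaled, grid * k).counts
        assert np.allclose(n1, n2, atol=1e-9)


class TestFitBranchDimension:
    @pytest.mark.parametrize("exponent", [1.0, 1.5])
    def test_exact_power_law(self, exponent):
        scales = np.geomspace(4, 40, 10)
        table = ScalingTable(
            scales=scales, normalized=scales / 100.0,
            counts=50.0 * scales ** (-exponent),
        )
        est = af.fit_branch_dimension(table)
        assert est.D == pytest.approx(exponent, abs=1e-12)
        assert est.stderr == pytest.approx(0.0, abs=1e-10)
        assert est.method == "D_BC"

    def test_straight_branch_dimension_one(self, straight_branch):
        est = af.fit_branch_dimension(af.coastline_scaling(straight_branch))
        assert est.D == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_independent_regression(self, weave_branch):
        table = af.coastline_scaling(weave_branch)
        est = af.fit_branch_dimension(table)
        # independent oracle: numpy polyfit on the same restricted rows
        mask = (table.scales >= 4.0) & (table.scales <= 40.0)
        slope = np.polyfit(
            np.log10(table.scales[mask]), np.log10(table.counts[mask]), 1
        )[0]
        assert est.D == pytest.approx(-slope, abs=1e-10)

    def test_too_few_rows_raises(self):
        scales = np.array([4.0, 8.0])
        table = ScalingTable(scales=scales, normalized=scales,
                             counts=np.array([10.0, 5.0]))
        with pytest.raises(InsufficientDataError):
            af.fit_branch_dimension(table)

    def test_short_branch_excluded(self):
        short = af.make_straight_branch(10, 2.0)  # L_E = 20 < 40
        assert branch_excluded(short)
        long = af.make_straight_branch(30, 2.0)  # L_E = 60
        assert not branch_excluded(long)


class TestPooledNormalizedDimension:
    def test_identical_straight_branches(self):
        branches = [af.make_straight_branch(40, 2.5) for _ in range(2)]
        est = af.pooled_normalized_dimension(branches)
        assert est.D == pytest.approx(1.0, abs=1e-6)
        assert est.method == "D_BCN"

    def test_no_shared_range_raises(self):
        # L_E differ by more than the grid's dynamic range (10x)
        b1 = af.make_straight_branch(10, 2.0)    # 20 µm
        b2 = af.make_straight_branch(100, 4.0)   # 400 µm
        with pytest.raises(RangeError):
            af.pooled_normalized_dimension([b1, b2])

    def test_recovers_generator_exponent(self):
        """Pooled fit on branches with a known common scaling exponent."""
        rng = np.random.default_rng(5)
        branches = [
            af.make_weave_branch(60, 2.4, 0.25, seed=int(rng.integers(2**31)))
            for _ in range(30)
        ]
        pooled = af.pooled_normalized_dimension(branches)
        per_branch = np.mean([
            af.fit_branch_dimension(af.coastline_scaling(b)).D
            for b in branches if not branch_excluded(b)
        ])
        # pooled and mean per-branch agree on a homogeneous ensemble
        assert pooled.D == pytest.approx(per_branch, abs=0.01)
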