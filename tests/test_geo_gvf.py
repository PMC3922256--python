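import numpy as np
import pytest

from dgfseg.core_io import ContractError, RunConfig
from dgfseg.geo_gvf import (
    SnakeState,
    VectorField,
    binary_edge_indicator,
    compute_binary_gvf,
    evolve_snake,
    external_force,
    geometric_term,
    gvf_residual,
    snake_step,
)
from dgfseg.initialization import RegionPartition
from dgfseg.pipeline import segment
from scipy.spatial import cKDTree


def step_edge_strip(H=50, W=60, col=30, sline=45):
    """Binary half-plane step restricted to the upper rows."""
    B = np.zeros((H, W), dtype=np.uint8)
    B[:sline, col:] = 1
    return B, RegionPartition(sline, H)


def band_strip(H=90, W=120, top=20, height=6, sline=80):
    """Horizontal dark band, like the mouth-opening strip."""
    B = np.zeros((H, W), dtype=np.uint8)
    B[top : top + height, 8 : W - 8] = 1
    return B, RegionPartition(sline, H)


class TestComputeBinaryGVF:
    def test_constant_map_stays_zero(self):
        B = np.zeros((30, 30), dtype=np.uint8)
        part = RegionPartition(25, 30)
        f = compute_binary_gvf(B, w=0.2, iters=10, part=part)
        assert (f.u == 0).all() and (f.v == 0).all()

    def test_field_matches_gradient_at_strong_edge(self):
        """Fixed point: V -> grad B where |grad B| is maximal."""
        B, part = step_edge_strip()
        f = compute_binary_gvf(B, w=0.2, iters=12000, part=part)
        sub = B[: part.sline].astype(float)
        br, bc = np.gradient(sub)
        mag = np.hypot(br, bc)
        r, c = np.unravel_index(np.argmax(mag), mag.shape)
        err = np.hypot(f.u[r, c] - br[r, c], f.v[r, c] - bc[r, c])
        assert err <= 1e-3

    def test_diffusion_reaches_flat_region(self):
        B, part = step_edge_strip()
        f = compute_binary_gvf(B, w=0.2, iters=500, part=part)
        assert np.hypot(f.u[20, 20], f.v[20, 20]) > 0  # 10 px from the edge

    def test_zero_below_sline(self):
        B, part = step_edge_strip()
        f = compute_binary_gvf(B, w=0.2, iters=50, part=part)
        assert (f.u[part.sline :] == 0).all() and (f.v[part.sline :] == 0).all()

    def test_converged_residual_small_everywhere(self):
        B, part = step_edge_strip()
        f = compute_binary_gvf(B, w=0.2, iters=6000, part=part)
        assert gvf_residual(B, f, w=0.2, part=part) <= 1e-3

    def test_invalid_parameters(self):
        B, part = step_edge_strip()
        with pytest.raises(ContractError):
            compute_binary_gvf(B, w=0.0, iters=10, part=part)
        with pytest.raises(ContractError):
            compute_binary_gvf(B, w=0.2, iters=0, part=part)


def _arc(row, c0, c1, interior_row):
    cols = np.arange(c0, c1 + 1, dtype=float)
    pts = np.column_stack([np.full_like(cols, float(row)), cols])
    return SnakeState(pts, 1.0, 1.0, (float(interior_row), float(0.5 * (c0 + c1))))


class TestGeometricTerm:
    def test_flat_region_unit_outward(self):
        B, _ = band_strip()
        st = _arc(60, 20, 100, interior_row=75)
        G = geometric_term(B, st)
        mags = np.hypot(G[:, 0], G[:, 1])
        assert np.allclose(mags[5:-5], 1.0, atol=1e-6)
        assert (G[5:-5, 0] < 0).all()  # outward = up, away from the interior point

    def test_small_on_strong_edge(self):
        B, _ = band_strip(top=30, height=8)
        st = _arc(38, 20, 100, interior_row=60)  # on the band's lower edge
        G = geometric_term(B, st, sigma=1.0)
        mags = np.hypot(G[:, 0], G[:, 1])
        assert mags[10:-10].max() <= 0.1

    def test_bounded_by_one(self, rng):
        B, _ = band_strip()
        pts = np.column_stack([rng.uniform(10, 70, 30), np.sort(rng.uniform(10, 110, 30))])
        st = SnakeState(pts, 1.0, 1.0, (85.0, 60.0))
        G = geometric_term(B, st)
        assert np.hypot(G[:, 0], G[:, 1]).max() <= 1.0 + 1e-12

    def test_repeated_points_rejected(self):
        pts = np.array([[10.0, 10.0]] * 6)
        with pytest.raises(ContractError):
            SnakeState(pts, 1.0, 1.0, (0, 0)).normals()


class TestExternalForceSwitch:
    def test_three_regimes(self, cfg):
        """Propulsion far away, vector flow near the edge, retreat inside."""
        B, part = band_strip(H=90, W=120, top=20, height=6, sline=80)
        V = compute_binary_gvf(B, cfg.w, cfg.gvf_iters, part)
        st = _arc(60, 20, 100, interior_row=75)
        G = geometric_term(B, st)
        mid = len(st.points) // 2

        far = external_force(st, V, G, cfg, B.astype(float))
        assert np.allclose(far[mid], G[mid])  # |V| < theta_v at 34 px away

        near = _arc(27, 20, 100, interior_row=75)  # 1 px below the strip
        Gn = geometric_term(B, near)
        fn = external_force(near, V, Gn, cfg, B.astype(float))
        vs = V.sample(near.points)
        assert np.allclose(fn[mid], vs[mid])  # attraction regime

        inside = _arc(23, 20, 100, interior_row=75)  # inside the dark strip
        Gi = geometric_term(B, inside)
        fi = external_force(inside, V, Gi, cfg, B.astype(float))
        n = inside.normals()
        assert np.allclose(fi[mid], -n[mid])  # retreat regime


class TestSnakeStep:
    def test_straight_line_stationary_without_external_force(self, cfg):
        st = _arc(40, 10, 60, interior_row=70)
        V = VectorField(np.zeros((90, 90)), np.zeros((90, 90)))
        G = np.zeros_like(st.points)
        out = snake_step(st, V, G, cfg)
        assert np.abs(out.points - st.points).max() < 1e-9

    def test_internal_forces_reduce_curvature(self, cfg):
        cols = np.linspace(10, 90, 81)
        rows = 40 + 3 * np.sin(cols / 3)
        st = SnakeState(np.column_stack([rows, cols]), 1.0, 1.0, (70.0, 50.0))
        V = VectorField(np.zeros((100, 100)), np.zeros((100, 100)))

        def total_curv(s):
            dd = np.diff(s.points, 2, axis=0)
            return np.abs(dd).sum()

        c0 = total_curv(st)
        for _ in range(10):
            st = snake_step(st, V, np.zeros_like(st.points), cfg)
        assert total_curv(st) < c0

    def test_far_point_moves_outward_at_unit_speed(self, cfg):
        """Where V ~ 0 and g_B = 1 the switch propels along +n at the step size."""
        B, _ = band_strip()
        st = _arc(60, 20, 100, interior_row=75)
        V = VectorField(np.zeros_like(B, dtype=float), np.zeros_like(B, dtype=float))
        G = geometric_term(B, st)
        out = snake_step(st, V, G, cfg)
        mid = len(st.points) // 2
        disp = out.points[mid] - st.points[mid]
        assert disp[0] == pytest.approx(-cfg.snake_step, rel=0.10)
        assert abs(disp[1]) < 0.05


class TestEvolveSnake:
    def test_zero_max_iters_returns_init(self, cfg):
        B, part = band_strip()
        V = compute_binary_gvf(B, cfg.w, 10, part)
        st = _arc(60, 20, 100, interior_row=75)
        out, iters, converged = evolve_snake(st, V, B, cfg, max_iters=0)
        assert out is st and iters == 0 and not converged

    def test_stable_when_initialized_on_the_edge(self, cfg):
        """An arc on the strip's tongue-side edge drifts <= 0.5 px."""
        B, part = band_strip(top=30, height=6)
        V = compute_binary_gvf(B, cfg.w, cfg.gvf_iters, part)
        st = _arc(36, 20, 100, interior_row=60)
        out, _, _ = evolve_snake(st, V, B, cfg, max_iters=100)
        d, _ = cKDTree(st.points).query(out.points)
        assert d.mean() <= 0.5

    def test_symmetric_band_gives_symmetric_arc(self, cfg):
        """No over-learning: equal tractive forces on both sides of the strip."""
        B, part = band_strip(H=90, W=121, top=24, height=6)
        V = compute_binary_gvf(B, cfg.w, cfg.gvf_iters, part)
        st = _arc(45, 15, 105, interior_row=70)
        out, _, _ = evolve_snake(st, V, B, cfg)
        pts = out.points
        mirrored = np.column_stack([pts[:, 0], 120.0 - pts[:, 1]])
        d, _ = cKDTree(pts).query(mirrored)
        assert d.max() <= 1.0

    def test_recovers_generator_upper_boundary(self, cfg, scene0):
        res = segment(scene0.image, cfg, keep_intermediates=True)
        win = res.intermediates["window"]
        snake = res.intermediates["snake"][0]
        pts = snake.points + [win.row0, win.col0]
        tc = scene0.tongue_contour().points
        upper_truth = tc[tc[:, 0] <= scene0.sline + 1]
        d, _ = cKDTree(upper_truth).query(pts)
        assert d.mean() <= 2.0, d.mean()

    def test_geometric_term_needed_for_far_initialization(self, cfg):
        """Without G_B a far-sagging arc finds no force and stays put."""
        B, part = band_strip(H=110, W=120, top=15, height=6, sline=100)
        V = compute_binary_gvf(B, cfg.w, cfg.gvf_iters, part)
        cols = np.arange(10, 111, dtype=float)
        sag = 21.0 + 60.0 * (1 - ((cols - 60) / 50) ** 2)  # middle ~60 px below
        st = SnakeState(np.column_stack([sag, cols]), 1.0, 1.0, (95.0, 60.0))

        def err(state):
            edge_cols = np.arange(8, 112, dtype=float)
            edge = np.column_stack([np.full_like(edge_cols, 20.5), edge_cols])
            d, _ = cKDTree(edge).query(state.points)
            return d.mean()

        with_g, _, _ = evolve_snake(st, V, B, cfg, max_iters=600)
        without_g, _, _ = evolve_snake(st, V, B, cfg, max_iters=600, use_geometric=False)
        assert err(without_g) >= 3 * err(with_g)
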