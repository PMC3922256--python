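import numpy as np
import pytest

from dgfseg.core_io import ContractError, Contour, contour_to_mask
from dgfseg.initialization import (
    FeaturePoints,
    InitializationError,
    RegionPartition,
    binarize_upper,
    build_initial_contour,
    detect_angular_points,
    detect_tip_and_root,
    init_level_set,
    partition,
    remove_nose,
)
from dgfseg.saliency import Window, compute_saliency_map, crop, detect_saliency_windows, select_tongue_window
from dgfseg.synthetic_data import SceneSpec, generate_scene


def _cropped(scene, pad=10):
    sal = compute_saliency_map(scene.image)
    w0 = select_tongue_window(detect_saliency_windows(sal, 2))
    H, W = scene.image.shape[:2]
    win = Window(max(w0.row0 - pad, 0), max(w0.col0 - pad, 0), min(w0.row1 + pad, H), min(w0.col1 + pad, W))
    return crop(scene.image, win), win


class TestAngularPoints:
    @pytest.mark.parametrize("seed", [0, 2, 6])
    def test_within_8px_of_truth(self, seed):
        scene = generate_scene(SceneSpec(seed=seed))
        sub, win = _cropped(scene)
        la, ra = detect_angular_points(sub)
        fp = scene.feature_points
        lt = (fp.left_angular[0] - win.row0, fp.left_angular[1] - win.col0)
        rt = (fp.right_angular[0] - win.row0, fp.right_angular[1] - win.col0)
        assert np.hypot(la[0] - lt[0], la[1] - lt[1]) <= 8
        assert np.hypot(ra[0] - rt[0], ra[1] - rt[1]) <= 8

    def test_constant_image_fails(self):
        with pytest.raises(InitializationError):
            detect_angular_points(np.full((64, 64, 3), 0.5))

    def test_left_is_left_of_right(self, scene0):
        sub, _ = _cropped(scene0)
        la, ra = detect_angular_points(sub)
        assert la[1] < ra[1]


class TestTipAndRoot:
    def test_geometric_contracts_and_accuracy(self, scene0):
        sub, win = _cropped(scene0)
        la, ra = detect_angular_points(sub)
        tip, root = detect_tip_and_root(sub, (la, ra))
        assert tip[0] > max(la[0], ra[0])
        assert root[0] < min(la[0], ra[0])
        true_tip_row = scene0.feature_points.tip[0] - win.row0
        # detection is biased at-or-below the true tip, never far above
        assert tip[0] >= true_tip_row - 5
        assert tip[0] <= true_tip_row + 6

    def test_initial_contour_encloses_true_lower_boundary(self):
        """Shrinking precondition: init lies outside/on the truth below sline."""
        for seed in (0, 5, 9):
            scene = generate_scene(SceneSpec(seed=seed))
            sub, win = _cropped(scene)
            la, ra = detect_angular_points(sub)
            tip, root = detect_tip_and_root(sub, (la, ra))
            contour = build_initial_contour(FeaturePoints(la, ra, tip, root))
            init_mask = contour_to_mask(contour, sub.shape[:2])
            truth = scene.tongue_mask[win.row0 : win.row1, win.col0 : win.col1]
            sline = partition(FeaturePoints(la, ra, tip, root), sub.shape[0]).sline
            # every true tongue pixel below sline+2 is inside the initial contour
            missed = truth[sline + 2 :] & ~init_mask[sline + 2 :]
            assert missed.sum() <= 10, (seed, missed.sum())

    def test_no_edge_on_midline_fails(self):
        img = np.full((64, 64, 3), 0.5)
        with pytest.raises(InitializationError):
            detect_tip_and_root(img, ((20, 10), (20, 54)))


FP_EXAMPLE = FeaturePoints((60, 30), (60, 98), (150, 64), (40, 64))


class TestBuildInitialContour:
    def test_example_extremes(self):
        c = build_initial_contour(FP_EXAMPLE)
        assert c.closed
        assert c.points[:, 0].max() == pytest.approx(150, abs=0.5)
        assert c.points[:, 0].min() == pytest.approx(40, abs=1.0)
        assert c.points[:, 1].min() == pytest.approx(30, abs=0.5)
        assert c.points[:, 1].max() == pytest.approx(98, abs=0.5)

    def test_symmetric_points_give_symmetric_contour(self):
        c = build_initial_contour(FP_EXAMPLE)
        mid = 64.0
        lower = c.points[c.points[:, 0] > 60.5]
        for row, col in lower[:: max(len(lower) // 20, 1)]:
            mirrored_col = 2 * mid - col
            d = np.abs(lower - [row, mirrored_col]).sum(axis=1).min()
            assert d < 1.5

    def test_upper_chords_inside_tongue(self, noiseless_scene):
        """Swelling precondition: the straight upper segments lie in the body."""
        scene = noiseless_scene
        fp = scene.feature_points
        c = build_initial_contour(
            FeaturePoints(fp.left_angular, fp.right_angular, fp.tip, fp.root)
        )
        upper = c.points[c.points[:, 0] < min(fp.left_angular[0], fp.right_angular[0]) - 0.5]
        inside = sum(
            scene.tongue_mask[int(round(r)), int(round(col))] for r, col in upper
        )
        assert inside >= 0.97 * len(upper)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ContractError):
            build_initial_contour(FeaturePoints((60, 30), (60, 98), (150, 20), (40, 64)))


class TestPartition:
    @pytest.mark.parametrize("rows,expected", [((60, 60), 60), ((58, 62), 60), ((58, 61), 60)])
    def test_sline_is_rounded_mean(self, rows, expected):
        fp = FeaturePoints((rows[0], 30), (rows[1], 98), (150, 64), (40, 64))
        assert partition(fp, 200).sline == expected

    def test_bounds_enforced(self):
        with pytest.raises(ContractError):
            RegionPartition(0, 100)
        with pytest.raises(ContractError):
            RegionPartition(100, 100)


class TestBinarizeUpper:
    def _three_level_image(self):
        """Dark strip between lip and tongue levels, as in the mouth region."""
        img = np.full((60, 40, 3), 0.6)  # lip-bright
        img[20:28] = 0.1  # dark strip
        img[28:50] = 0.45  # tongue
        return img

    def test_dark_strip_maps_to_one(self):
        img = self._three_level_image()
        B = binarize_upper(img, RegionPartition(50, 60))
        assert B[20:28].all()
        assert B[:20].sum() == 0 and B[28:].sum() == 0

    def test_rows_below_sline_are_zero(self, scene0):
        sub, _ = _cropped(scene0)
        part = RegionPartition(40, sub.shape[0])
        B = binarize_upper(sub, part)
        assert B[40:].sum() == 0

    def test_extracts_strip_not_tongue_on_scene(self, scene0):
        sub, win = _cropped(scene0)
        sline = scene0.sline - win.row0
        B = binarize_upper(sub, RegionPartition(sline, sub.shape[0]))
        gap = scene0.gap_mask[win.row0 : win.row1, win.col0 : win.col1]
        tongue = scene0.tongue_mask[win.row0 : win.row1, win.col0 : win.col1]
        assert (B & gap[: B.shape[0]]).sum() >= 0.9 * B.sum()
        assert (B & tongue[: B.shape[0]]).sum() <= 0.05 * tongue[:sline].sum() + 5

    def test_constant_region_rejected(self):
        img = np.full((40, 40, 3), 0.5)
        with pytest.raises(ContractError):
            binarize_upper(img, RegionPartition(20, 40))


class TestRemoveNose:
    def _binary(self, dark_rows):
        b = np.zeros((80, 60), dtype=np.uint8)
        for r in dark_rows:
            b[r, 20:40] = 1
        return b

    def test_twice_height_rule(self):
        fp = FeaturePoints((60, 10), (60, 50), (75, 30), (45, 30))
        win = remove_nose(self._binary(range(30, 41)), fp)
        assert win.row0 == 30 - 2 * 11  # height 11 -> cut at 8

    def test_empty_dark_region_is_noop(self):
        fp = FeaturePoints((60, 10), (60, 50), (75, 30), (45, 30))
        win = remove_nose(self._binary([]), fp)
        assert (win.row0, win.row1) == (0, 80)

    def test_top_clamped_at_zero(self):
        fp = FeaturePoints((60, 10), (60, 50), (75, 30), (45, 30))
        win = remove_nose(self._binary(range(5, 30)), fp)
        assert win.row0 == 0


class TestInitLevelSet:
    def test_exact_three_values_and_signs(self):
        c = Contour(np.array([[5.0, 5.0], [5.0, 20.0], [20.0, 20.0], [20.0, 5.0]]))
        part = RegionPartition(10, 30)
        phi = init_level_set(c, (30, 30), rho=2.0, part=part)
        assert set(np.unique(phi)) == {-2.0, 0.0, 2.0}
        assert phi[12, 12] == -2.0  # strictly inside
        assert phi[5, 12] == 0.0  # on the contour
        assert phi[0, 0] == 2.0  # outside

    def test_rho_must_be_positive(self):
        c = Contour(np.array([[2.0, 2.0], [2.0, 8.0], [8.0, 8.0]]))
        with pytest.raises(ContractError):
            init_level_set(c, (12, 12), rho=0.0, part=None)

    def test_open_contour_rejected(self):
        c = Contour(np.array([[2.0, 2.0], [2.0, 8.0], [8.0, 8.0]]), closed=False)
        with pytest.raises(ContractError):
            init_level_set(c, (12, 12), rho=1.0, part=None)
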