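"""End-to-end double geo-vector flow segmentation.

Stage order: saliency map -> two candidate windows -> adopt the smaller
-> crop -> feature points (angular, tip, root) -> nose removal -> initial
contour -> row partition at sline -> level-set + binary-map
initialization -> geodesic flow (lower rows) -> zero-contour extraction
-> binary-GVF snake (upper rows) -> join the two arcs -> rasterize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Contour, RunConfig, as_rgb_image, contour_to_mask, rgb_to_gray
from .geodesic_levelset import edge_indicator, evolve_geodesic, extract_zero_contour
from .geo_gvf import SnakeState, VectorField, compute_binary_gvf, compute_gvf, evolve_snake
from .initialization import (
    FeaturePoints,
    binarize_upper,
    build_initial_contour,
    detect_angular_points,
    detect_tip_and_root,
    init_level_set,
    partition,
    remove_nose,
)
from .saliency import Window, compute_saliency_map, crop, detect_saliency_windows, select_tongue_window

#: padding added around the adopted saliency window before cropping (px)
WINDOW_PAD = 10


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial artifacts."""

    def __init__(self, stage: str, cause: Exception, artifacts: dict):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.artifacts = artifacts


@dataclass
class SegmentationResult:
    mask: np.ndarray
    contour: Contour
    window: Window
    feature_points: FeaturePoints  # in full-image coordinates
    sline: int                     # in full-image coordinates
    iterations: dict
    converged: dict
    config: RunConfig
    intermediates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "window": self.window.to_dict(),
            "feature_points": self.feature_points.to_dict(),
            "sline": self.sline,
            "iterations": self.iterations,
            "converged": self.converged,
            "config_echo": self.config.to_dict(),
        }


def _split_lower_arc(loop: Contour, sline: int) -> np.ndarray:
    """Contiguous run of zero-contour points at or below the partition row."""
    pts = loop.points
    below = pts[:, 0] >= sline - 0.5
    if below.all():
        return pts
    if not below.any():
        raise ValueError("zero contour lies entirely above the partition line")
    # rotate so the loop starts in the upper part, then take the longest run
    start = int(np.flatnonzero(~below)[0])
    rolled = np.roll(below, -start)
    pts_r = np.roll(pts, -start, axis=0)
    idx = np.flatnonzero(rolled)
    # longest contiguous stretch of True
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)
    seg = max(segments, key=len)
    return pts_r[seg]


def segment(
    image: np.ndarray,
    cfg: RunConfig | None = None,
    *,
    use_geometric: bool = True,
    upper_map: str = "binary",
    keep_intermediates: bool = False,
) -> SegmentationResult:
    """Segment the tongue body in a face/tongue scene.

    ``use_geometric=False`` (drop the propulsion term) and
    ``upper_map="gray"`` (drive the upper snake by the gray map instead
    of the binary map) are ablation switches used to reproduce the
    method's design comparisons; both default to the published pipeline.
    """
    if cfg is None:
        cfg = RunConfig()
    image = as_rgb_image(image)
    art: dict = {}

    def stage(name, fn, *a, **kw):
        try:
            out = fn(*a, **kw)
        except Exception as exc:
            raise StageError(name, exc, art) from exc
        art[name] = out
        return out

    sal = stage("saliency_map", compute_saliency_map, image)
    wins = stage("saliency_windows", detect_saliency_windows, sal, 2)
    win0 = stage("select_window", select_tongue_window, wins)
    H, W = image.shape[:2]
    win = Window(
        max(win0.row0 - WINDOW_PAD, 0),
        max(win0.col0 - WINDOW_PAD, 0),
        min(win0.row1 + WINDOW_PAD, H),
        min(win0.col1 + WINDOW_PAD, W),
    )
    art["window"] = win
    sub = stage("crop", crop, image, win)

    la, ra = stage("angular_points", detect_angular_points, sub)
    tip, root = stage("tip_and_root", detect_tip_and_root, sub, (la, ra), sigma=cfg.sigma)
    fp = FeaturePoints(la, ra, tip, root)
    part = partition(fp, sub.shape[0])
    B = stage("binarize_upper", binarize_upper, sub, part)

    nose_win = stage("remove_nose", remove_nose, B, fp)
    if nose_win.row0 > 0:
        sub = sub[nose_win.row0 :]
        win = Window(win.row0 + nose_win.row0, win.col0, win.row1, win.col1)
        fp = fp.shifted(-nose_win.row0)
        part = partition(fp, sub.shape[0])
        B = stage("binarize_upper", binarize_upper, sub, part)
        art["window"] = win

    contour0 = stage("initial_contour", build_initial_contour, fp)
    phi0 = stage("init_level_set", init_level_set, contour0, sub.shape[:2], cfg.rho, part)
    g = stage("edge_indicator", edge_indicator, rgb_to_gray(sub), cfg.sigma)
    phi, it_geo, conv_geo = stage("geodesic", evolve_geodesic, phi0, g, cfg, part)
    loop = stage("zero_contour", extract_zero_contour, phi)
    lower_arc = stage("split_lower", _split_lower_arc, loop, part.sline)

    if upper_map == "binary":
        Vfield = stage("gvf", compute_binary_gvf, B, cfg.w, cfg.gvf_iters, part)
        upper_input = B
        region_stop = True
    elif upper_map == "gray":
        gray_upper = rgb_to_gray(sub).copy()
        gray_upper[part.sline :] = 0.0
        Vfield = stage("gvf", compute_gvf, gray_upper, cfg.w, cfg.gvf_iters, part)
        upper_input = gray_upper
        region_stop = False
    else:
        raise ValueError(f"unknown upper_map {upper_map!r}")

    mid_col = 0.5 * (fp.left_angular[1] + fp.right_angular[1])
    interior = (part.sline + 0.25 * (fp.tip[0] - part.sline), mid_col)
    init_arc = _chord_arc(fp)
    snake0 = SnakeState(init_arc, cfg.alpha, cfg.beta, interior)
    snake, it_snk, conv_snk = stage(
        "snake",
        evolve_snake,
        snake0,
        Vfield,
        upper_input,
        cfg,
        use_geometric=use_geometric,
        use_region_stop=region_stop,
    )

    final = _join_arcs(snake.points, lower_arc)
    full_pts = final.points + np.array([win.row0, win.col0], dtype=float)
    full_contour = Contour(full_pts, closed=True)
    mask = contour_to_mask(full_contour, image.shape[:2])

    return SegmentationResult(
        mask=mask,
        contour=full_contour,
        window=win,
        feature_points=fp.shifted(win.row0, win.col0),
        sline=part.sline + win.row0,
        iterations={"geodesic": it_geo, "snake": it_snk},
        converged={"geodesic": conv_geo, "snake": conv_snk},
        config=cfg,
        intermediates=art if keep_intermediates else {},
    )


def _chord_arc(fp: FeaturePoints) -> np.ndarray:
    """Straight segments left angular -> root -> right angular, ~1 px spaced."""
    pts = []
    for p, q in (
        (fp.left_angular, fp.root),
        (fp.root, fp.right_angular),
    ):
        n = max(int(round(np.hypot(q[0] - p[0], q[1] - p[1]))), 2)
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        pts.append(np.column_stack([p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])]))
    pts.append(np.asarray(fp.right_angular, dtype=float)[None])
    return np.vstack(pts)


def _join_arcs(upper: np.ndarray, lower: np.ndarray) -> Contour:
    """Close the contour: upper arc left->right, lower arc right->left."""
    if upper[0, 1] > upper[-1, 1]:
        upper = upper[::-1]
    if lower[0, 1] < lower[-1, 1]:
        lower = lower[::-1]
    return Contour(np.vstack([upper, lower]), closed=True)
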