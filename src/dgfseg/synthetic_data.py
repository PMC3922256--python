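"""Deterministic synthetic tongue-scene generator with exact ground truth.

Each scene emulates the structure the segmentation method assumes: a
roughly convex dark-red tongue body protruding below the two mouth
corners ("angular points"), a thin dark mouth-opening strip between the
tongue root and the upper lip, a lip band of distinct color above it,
facial skin elsewhere, and optionally a shaded nose block above the lip.

The tongue is the region between two quadratic arcs that meet at the
angular points: the upper arc passes through the tongue-root apex, the
lower arc through the tongue tip. This gives pixel-perfect masks and
feature points for free, which the detector, flow and metric tests use
as ground truth. Scenes are deliberately simplified (no teeth, no
coating texture): the method's claims concern boundary geometry and
color contrast, which these scenes control directly.

Class palettes mirror the four clinical tongue-color classes. The red
class sets the tongue color nearly equal to the lip color, the known
hard case; light-white and carmoisine keep strong tongue/lip contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from skimage import measure

from .core_io import ContractError, Contour

#: shared scene colors (RGB in [0, 1])
SKIN = (0.80, 0.60, 0.52)
LIP = (0.72, 0.34, 0.36)
MOUTH = (0.10, 0.06, 0.07)

#: per-class tongue colors; the red tongue is nearly lip-colored
CLASS_TONGUE = {
    "light_white": (0.78, 0.44, 0.47),
    "red": (0.70, 0.32, 0.34),
    "purple": (0.55, 0.32, 0.45),
    "carmoisine": (0.62, 0.16, 0.28),
}

#: tongue-lip RGB distance below which a palette counts as "hard"
HARD_CONTRAST_THRESHOLD = 0.15


@dataclass(frozen=True)
class NoseSpec:
    height: int = 18
    width: int = 44
    gap_above_lip: int = 6
    shade: float = 0.82  # nose color = shade * skin


@dataclass(frozen=True)
class SceneSpec:
    H: int = 256
    W: int = 256
    center_col: int = 128
    left_angular_row: int = 108
    right_angular_row: int = 108
    half_width: int = 62
    root_height: int = 30          # apex of the upper arc above the mean angular row
    tip_depth: int = 92            # tongue tip below the mean angular row
    lip_thickness: int = 10
    mouth_gap_height: int = 6
    #: columns over which the dark strip thins out toward each mouth
    #: corner (the lips close onto the tongue there, so the immediate
    #: corner neighborhood is dominated by the tongue/lip junction)
    corner_taper: int = 10
    nose: Optional[NoseSpec] = None
    tongue_color: tuple = CLASS_TONGUE["carmoisine"]
    lip_color: tuple = LIP
    skin_color: tuple = SKIN
    mouth_color: tuple = MOUTH
    noise_sigma: float = 0.02
    seed: int = 0
    class_tag: str = "carmoisine"

    @property
    def mean_angular_row(self) -> float:
        return 0.5 * (self.left_angular_row + self.right_angular_row)

    @property
    def tip_row(self) -> int:
        return int(round(self.mean_angular_row + self.tip_depth))

    @property
    def root_apex_row(self) -> int:
        return int(round(self.mean_angular_row - self.root_height))

    def tongue_lip_contrast(self) -> float:
        t = np.asarray(self.tongue_color)
        l = np.asarray(self.lip_color)
        return float(np.linalg.norm(t - l))

    def validate(self) -> None:
        if self.mouth_gap_height < 1:
            raise ContractError("mouth_gap_height must be >= 1")
        c0 = self.center_col - self.half_width
        c1 = self.center_col + self.half_width
        lip_top = self.root_apex_row - self.mouth_gap_height - self.lip_thickness
        top = lip_top
        if self.nose is not None:
            top = lip_top - self.nose.gap_above_lip - self.nose.height
        if not (c0 >= 5 and c1 <= self.W - 6 and self.tip_row <= self.H - 6 and top >= 2):
            raise ContractError("tongue scene does not fit in the frame with a 5 px margin")
        if self.root_apex_row >= min(self.left_angular_row, self.right_angular_row):
            raise ContractError("tongue root apex must lie above both angular rows")
        pairs = [
            (self.tongue_color, self.lip_color),
            (self.tongue_color, self.skin_color),
            (self.tongue_color, self.mouth_color),
            (self.lip_color, self.skin_color),
            (self.lip_color, self.mouth_color),
            (self.skin_color, self.mouth_color),
        ]
        for a, b in pairs:
            if np.linalg.norm(np.asarray(a) - np.asarray(b)) < 0.02:
                raise ContractError("scene colors must be pairwise distinct")


@dataclass
class SceneTruth:
    image: np.ndarray
    tongue_mask: np.ndarray
    feature_points: "FeaturePointsTruth"
    nose_mask: np.ndarray
    class_tag: str
    spec: SceneSpec
    gap_mask: np.ndarray
    sline: int

    def tongue_contour(self) -> Contour:
        """Closed sub-pixel boundary of the true tongue mask."""
        padded = np.pad(self.tongue_mask.astype(float), 1)
        loops = measure.find_contours(padded, 0.5)
        pts = max(loops, key=len) - 1.0
        return Contour(pts, closed=True)


@dataclass(frozen=True)
class FeaturePointsTruth:
    left_angular: tuple
    right_angular: tuple
    tip: tuple
    root: tuple


def _quad_through(p0, p1, p2) -> np.poly1d:
    cols = np.array([p0[1], p1[1], p2[1]], dtype=float)
    rows = np.array([p0[0], p1[0], p2[0]], dtype=float)
    return np.poly1d(np.polyfit(cols, rows, 2))


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render one scene; fully determined by ``spec`` (incl. its seed)."""
    spec.validate()
    H, W = spec.H, spec.W
    c0 = spec.center_col - spec.half_width
    c1 = spec.center_col + spec.half_width
    la = (spec.left_angular_row, c0)
    ra = (spec.right_angular_row, c1)
    apex = (spec.root_apex_row, spec.center_col)
    tip = (spec.tip_row, spec.center_col)

    upper = _quad_through(la, apex, ra)
    lower = _quad_through(la, tip, ra)

    img = np.empty((H, W, 3))
    img[:] = spec.skin_color
    tongue_mask = np.zeros((H, W), dtype=np.uint8)
    gap_mask = np.zeros((H, W), dtype=np.uint8)
    nose_mask = np.zeros((H, W), dtype=np.uint8)

    cols = np.arange(c0, c1 + 1)
    ub = np.rint(upper(cols)).astype(int)
    lb = np.rint(lower(cols)).astype(int)
    taper = max(spec.corner_taper, 1)
    for c, u, l in zip(cols, ub, lb):
        d = min(c - c0, c1 - c)
        gap_c = min(spec.mouth_gap_height, int(spec.mouth_gap_height * d / taper))
        lip_top = u - gap_c - spec.lip_thickness
        img[lip_top : u - gap_c, c] = spec.lip_color
        if gap_c > 0:
            img[u - gap_c : u, c] = spec.mouth_color
            gap_mask[u - gap_c : u, c] = 1
        if l >= u:
            img[u : l + 1, c] = spec.tongue_color
            tongue_mask[u : l + 1, c] = 1

    if spec.nose is not None:
        lip_top_center = spec.root_apex_row - spec.mouth_gap_height - spec.lip_thickness
        n1 = lip_top_center - spec.nose.gap_above_lip
        n0 = n1 - spec.nose.height
        nc0 = spec.center_col - spec.nose.width // 2
        nc1 = nc0 + spec.nose.width
        img[n0:n1, nc0:nc1] = np.asarray(spec.skin_color) * spec.nose.shade
        nose_mask[n0:n1, nc0:nc1] = 1

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    fp = FeaturePointsTruth(
        left_angular=la,
        right_angular=ra,
        tip=tip,
        root=(spec.root_apex_row + 2, spec.center_col),
    )
    return SceneTruth(
        image=img,
        tongue_mask=tongue_mask,
        feature_points=fp,
        nose_mask=nose_mask,
        class_tag=spec.class_tag,
        spec=spec,
        gap_mask=gap_mask,
        sline=int(round(spec.mean_angular_row)),
    )


def generate_suite(
    n: int, seed: int = 0, class_mix: dict[str, float] | None = None
) -> list[SceneTruth]:
    """``n`` reproducible scenes with randomized-but-seeded geometry.

    Scene ``i`` uses seed ``seed + i``. Hard cases are included by
    construction: the red palette (tongue nearly lip-colored), occasional
    nose blocks, and asymmetric angular rows.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    classes = list(CLASS_TONGUE)
    if class_mix is None:
        probs = np.full(len(classes), 1.0 / len(classes))
    else:
        probs = np.array([class_mix.get(c, 0.0) for c in classes], dtype=float)
        if probs.sum() <= 0:
            raise ContractError("class_mix must give positive total weight")
        probs = probs / probs.sum()

    scenes = []
    for i in range(n):
        scene_seed = seed + i
        rng = np.random.default_rng(scene_seed)
        tag = classes[rng.choice(len(classes), p=probs)]
        ang = int(rng.integers(102, 116))
        asym = int(rng.integers(-4, 5))
        spec = SceneSpec(
            center_col=int(rng.integers(120, 137)),
            left_angular_row=ang,
            right_angular_row=ang + asym,
            half_width=int(rng.integers(54, 67)),
            root_height=int(rng.integers(24, 35)),
            tip_depth=int(rng.integers(80, 101)),
            lip_thickness=int(rng.integers(9, 13)),
            mouth_gap_height=int(rng.integers(5, 8)),
            nose=NoseSpec() if rng.random() < 0.3 else None,
            tongue_color=CLASS_TONGUE[tag],
            seed=scene_seed,
            class_tag=tag,
        )
        scenes.append(generate_scene(spec))
    return scenes
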