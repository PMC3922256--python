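"""Feature-point detection and contour/region initialization.

Four feature points seed the segmentation of the refined (cropped)
tongue image: the two *angular points* (mouth corners, Harris corners at
the lip-tongue junctions), the *tongue tip* (lowest strong horizontal
edge on the vertical midline) and the *tongue root* (a point just below
the dark mouth-opening strip, strictly inside the tongue). From them the
initial contour is built: a smooth lower arc through angular points and
tip that encloses the true lower boundary (so the geodesic flow can only
shrink onto it), and straight upper segments through the root that lie
inside the tongue body (so the snake can only swell outward).

The region is partitioned at ``sline``, the (mean) angular-point row:
rows above it evolve under the binary-map snake, rows below under the
geodesic level-set flow. The level-set matrix is initialized
piecewise-constant: -rho strictly inside the contour, 0 on it, +rho
outside, which fixes the shrinking propagation direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.ndimage import label as nd_label
from skimage.draw import polygon_perimeter
from skimage.feature import corner_harris, corner_peaks
from skimage.filters import threshold_otsu

from .core_io import ContractError, Contour, as_binary_mask, as_rgb_image, contour_to_mask, rgb_to_gray
from .saliency import Window

#: exponent < 1 that bows the initial lower arc outward between its anchors
INIT_BULGE_EXPONENT = 0.65
#: the dark mouth strip never covers more than this fraction of the upper crop
DARK_FRACTION_MAX = 0.35
#: fraction of the midline gradient maximum that counts as a "strong" edge
EDGE_STRENGTH_FRACTION = 0.5


class InitializationError(RuntimeError):
    """Raised when feature points cannot be detected."""


@dataclass(frozen=True)
class FeaturePoints:
    """The four seed points, all in (row, col) crop coordinates."""

    left_angular: tuple
    right_angular: tuple
    tip: tuple
    root: tuple

    def __post_init__(self) -> None:
        if not self.left_angular[1] < self.right_angular[1]:
            raise ContractError("left angular point must be left of the right one")
        ang_rows = (self.left_angular[0], self.right_angular[0])
        if not self.tip[0] > max(ang_rows):
            raise ContractError("tongue tip must lie below both angular points")
        if not self.root[0] < min(ang_rows):
            raise ContractError("tongue root must lie above both angular points")

    @property
    def angular_rows(self) -> tuple:
        return (self.left_angular[0], self.right_angular[0])

    def shifted(self, drow: float, dcol: float = 0.0) -> "FeaturePoints":
        def mv(p):
            return (p[0] + drow, p[1] + dcol)

        return FeaturePoints(
            mv(self.left_angular), mv(self.right_angular), mv(self.tip), mv(self.root)
        )

    def to_dict(self) -> dict:
        return {
            "left_angular": list(map(float, self.left_angular)),
            "right_angular": list(map(float, self.right_angular)),
            "tip": list(map(float, self.tip)),
            "root": list(map(float, self.root)),
        }


@dataclass(frozen=True)
class RegionPartition:
    """Row split of the refined image: rows < sline are the upper part."""

    sline: int
    H: int

    def __post_init__(self) -> None:
        if not 0 < self.sline < self.H:
            raise ContractError(f"sline {self.sline} outside (0, {self.H})")


def detect_angular_points(image: np.ndarray, *, harris_sigma: float = 2.5) -> tuple:
    """The two mouth-corner points, one per horizontal half of the crop.

    Harris corner responses are searched inside a central row band
    (25-80 % of the crop height) to exclude the nose region and border
    artifacts. In each horizontal half the *lowest* sufficiently strong
    candidate is taken: the mouth corner is the bottom-most corner-like
    junction of the mouth complex (strip ends, lip ends and the
    tongue-lip-skin junction all cluster there, and the true junction is
    the lowest of them when the tongue-lip contrast makes it visible).
    Only rough locations are required downstream.
    """
    img = as_rgb_image(image)
    gray = rgb_to_gray(img)
    H, W = gray.shape
    response = corner_harris(gray, sigma=harris_sigma)
    peaks = corner_peaks(response, min_distance=5, threshold_rel=0.02, exclude_border=2)
    if len(peaks) == 0:
        raise InitializationError("no corner candidates found")
    r0, r1 = int(0.25 * H), int(0.80 * H)
    band = peaks[(peaks[:, 0] >= r0) & (peaks[:, 0] <= r1)]
    if len(band) == 0:
        band = peaks
    left = band[band[:, 1] < W / 2]
    right = band[band[:, 1] >= W / 2]
    if len(left) == 0 or len(right) == 0:
        raise InitializationError("could not find a corner in each horizontal half")

    def lowest_strong(cands):
        resp = response[cands[:, 0], cands[:, 1]]
        strong = cands[resp >= 0.2 * resp.max()]
        return strong[np.argmax(strong[:, 0])]

    lp = lowest_strong(left)
    rp = lowest_strong(right)
    lp = _refine_corner(img, tuple(lp), tuple(rp), side="left")
    rp = _refine_corner(img, tuple(rp), tuple(lp), side="right")
    return (int(lp[0]), int(lp[1])), (int(rp[0]), int(rp[1]))


#: RGB distance to the tongue seed color below which a pixel counts as tongue
TONGUE_COLOR_TOL = 0.12
#: search half-size around the rough Harris corner (px)
CORNER_SEARCH_RADIUS = 15


def _refine_corner(img: np.ndarray, rough: tuple, other: tuple, side: str) -> tuple:
    """Snap a rough mouth-corner estimate to the tongue's lateral extreme.

    A tongue color seed is sampled well inside the body; within a window
    around the rough corner, the laterally extreme pixels of the
    tongue-colored set mark the true junction. When the tongue color is
    close to the lip color the set merges with the lip, the extreme
    column degenerates into an extended edge, and the refinement is
    ambiguous -- the rough (Harris) estimate is then kept. This is the
    known hard case of low tongue-lip contrast.
    """
    H, W = img.shape[:2]
    seed_row = int(min(rough[0] + 0.3 * (H - rough[0]), H - 4))
    seed_col = int(round(0.5 * (rough[1] + other[1])))
    patch = img[max(seed_row - 3, 0) : seed_row + 4, max(seed_col - 3, 0) : seed_col + 4]
    seed = np.median(patch.reshape(-1, 3), axis=0)
    r0 = max(int(rough[0]) - CORNER_SEARCH_RADIUS, 0)
    r1 = min(int(rough[0]) + CORNER_SEARCH_RADIUS + 1, H)
    c0 = max(int(rough[1]) - CORNER_SEARCH_RADIUS, 0)
    c1 = min(int(rough[1]) + CORNER_SEARCH_RADIUS + 1, W)
    window = img[r0:r1, c0:c1]
    dist = np.sqrt(((window - seed) ** 2).sum(axis=2))
    m = dist < TONGUE_COLOR_TOL
    # drop small speckle components (noise hits) but keep the thin corner wedge
    labels, n_lab = nd_label(m)
    if n_lab == 0:
        return rough
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= 12)
    if len(keep) == 0:
        return rough
    m = np.isin(labels, keep)
    rows, cols = np.nonzero(m)
    extreme = cols.min() if side == "left" else cols.max()
    near = np.abs(cols - extreme) <= 1
    span = rows[near].max() - rows[near].min()
    if span > 6:  # extended vertical edge: tongue merged with lip, ambiguous
        return rough
    return (int(r0 + rows[near].max()), int(c0 + extreme))


def detect_tip_and_root(
    image: np.ndarray, angular: tuple, *, sigma: float = 1.5
) -> tuple:
    """Locate the tongue tip and root on the vertical midline.

    The tip is the *lowest* strong vertical-gradient row below the
    angular row, which biases the detection at or below the true tip --
    exactly what the shrinking geodesic flow requires. The root is
    placed a few pixels below the first strong edge found scanning
    upward from the angular row (the tongue / mouth-opening transition),
    strictly inside the tongue.
    """
    img = as_rgb_image(image)
    gray = gaussian_filter(rgb_to_gray(img), sigma)
    H, W = gray.shape
    (lr, lc), (rr, rc) = angular
    mid = int(round(0.5 * (lc + rc)))
    c0, c1 = max(mid - 2, 0), min(mid + 3, W)
    profile = gray[:, c0:c1].mean(axis=1)
    grad = np.abs(np.gradient(gaussian_filter1d(profile, 1.0)))

    low0 = int(max(lr, rr)) + 3
    below = grad[low0:]
    if len(below) == 0 or below.max() <= 1e-6:
        raise InitializationError("no edge found on the midline below the angular row")
    thr = EDGE_STRENGTH_FRACTION * below.max()
    tip_row = low0 + int(np.flatnonzero(below >= thr)[-1])

    up1 = int(min(lr, rr)) - 3
    above = grad[:up1]
    if len(above) == 0 or above.max() <= 1e-6:
        raise InitializationError("no edge found on the midline above the angular row")
    thr_up = EDGE_STRENGTH_FRACTION * above.max()
    edge_row = int(np.flatnonzero(above >= thr_up)[-1])  # lowest strong edge above
    root_row = min(edge_row + 3, up1 - 1)
    if root_row <= 0:
        raise InitializationError("root point degenerate")
    return (int(tip_row), mid), (int(root_row), mid)


def build_initial_contour(fp: FeaturePoints) -> Contour:
    """Closed initial contour from the four feature points.

    Lower half: the quadratic arc through left angular point, tip and
    right angular point, bowed outward between the anchors (depth
    profile raised to an exponent < 1) so that it encloses any true
    boundary through the same three points. Upper half: straight
    segments angular -> root -> angular, guaranteed inside the tongue.
    Sampled at ~1 px arc spacing.
    """
    la, ra, tip, root = fp.left_angular, fp.right_angular, fp.tip, fp.root
    if not (la[1] < tip[1] < ra[1]):
        raise ContractError("tip column must lie between the angular columns")

    cols = np.linspace(la[1], ra[1], max(int(round(ra[1] - la[1])), 8) + 1)
    chord = np.interp(cols, [la[1], ra[1]], [la[0], ra[0]])
    quad = np.poly1d(
        np.polyfit([la[1], tip[1], ra[1]], [la[0], tip[0], ra[0]], 2)
    )(cols)
    depth = np.maximum(quad - chord, 0.0)
    dmax = depth.max()
    if dmax <= 0:
        raise ContractError("degenerate lower arc: tip not below the angular chord")
    lower_rows = chord + dmax * (depth / dmax) ** INIT_BULGE_EXPONENT

    def segment(p, q):
        n = max(int(round(np.hypot(q[0] - p[0], q[1] - p[1]))), 2)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[1:]
        return np.column_stack([p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])])

    upper = np.vstack(
        [np.asarray(ra, float)[None], segment(ra, root), np.asarray(root, float)[None], segment(root, la)]
    )
    lower = np.column_stack([lower_rows, cols])
    pts = np.vstack([lower, upper])
    return Contour(pts, closed=True)


def partition(fp: FeaturePoints, H: int) -> RegionPartition:
    """sline = rounded mean of the two angular rows."""
    sline = int(round(0.5 * (fp.left_angular[0] + fp.right_angular[0])))
    return RegionPartition(sline=sline, H=H)


def binarize_upper(image: np.ndarray, part: RegionPartition) -> np.ndarray:
    """Binary map of the upper rows: dark mouth-opening region -> 1.

    The upper crop mixes skin, lip, the tongue's top sliver and the dark
    mouth-opening strip. A two-class Otsu split is refined recursively:
    while the dark class covers more than ``DARK_FRACTION_MAX`` of the
    region it still contains lip or tongue pixels (the strip's height is
    at most about twice the lip thickness, so it can never occupy a
    third of the upper crop) and the dark class is re-split. All rows at
    or below ``sline`` are 0.
    """
    gray = rgb_to_gray(as_rgb_image(image))
    region = gray[: part.sline]
    if region.size == 0 or region.max() - region.min() < 1e-6:
        raise ContractError("upper region is constant; cannot threshold")
    vals = region.ravel()
    t = float(threshold_otsu(vals))
    for _ in range(5):
        dark = vals[vals < t]
        if len(dark) <= DARK_FRACTION_MAX * len(vals):
            break
        if len(np.unique(dark)) < 2:
            break
        t = float(threshold_otsu(dark))
    mask = np.zeros(gray.shape, dtype=np.uint8)
    mask[: part.sline] = (region < t).astype(np.uint8)
    return mask


def remove_nose(binary: np.ndarray, fp: FeaturePoints) -> Window:
    """Crop window that discards rows far above the upper lip.

    The dark mouth-opening region (value 1 between root and upper lip)
    has some height h; assuming the upper lip is at most twice that
    thick, every row above ``top(dark) - 2 h`` is skin/nose and is cut.
    With no dark region the window is the identity (no-op).
    """
    b = as_binary_mask(binary)
    H, W = b.shape
    c0 = int(np.floor(min(fp.left_angular[1], fp.right_angular[1])))
    c1 = int(np.ceil(max(fp.left_angular[1], fp.right_angular[1])))
    top_limit = int(np.floor(fp.root[0]))
    region = b[: max(top_limit, 0), max(c0, 0) : min(c1 + 1, W)]
    rows = np.flatnonzero(region.sum(axis=1) >= 3)
    if len(rows) == 0:
        return Window(0, 0, H, W)
    top_dark, bottom_dark = int(rows[0]), int(rows[-1])
    height = bottom_dark - top_dark + 1
    new_top = max(0, top_dark - 2 * height)
    return Window(new_top, 0, H, W)


def init_level_set(
    contour: Contour, shape: tuple[int, int], rho: float, part: RegionPartition | None = None
) -> np.ndarray:
    """Piecewise-constant level-set matrix: -rho inside, 0 on, +rho outside.

    The negative interior makes the zero level set shrink under the
    geodesic flow. The output contains exactly the values {-rho, 0, +rho}.
    """
    if rho <= 0:
        raise ContractError("rho must be positive")
    if not contour.closed:
        raise ContractError("level-set initialization needs a closed contour")
    inside = contour_to_mask(contour, shape)
    phi = np.full(shape, float(rho))
    phi[inside == 1] = -float(rho)
    pts = contour.as_closed_array()
    rr, cc = polygon_perimeter(
        np.round(pts[:, 0]).astype(int), np.round(pts[:, 1]).astype(int), shape=shape, clip=True
    )
    phi[rr, cc] = 0.0
    return phi
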