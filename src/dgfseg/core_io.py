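"""Shared types, image/mask/contour I/O and geometry conventions.

Conventions used throughout the package:

* images are ``float64`` arrays with intensities in ``[0, 1]``; RGB images
  are ``(H, W, 3)``, gray images ``(H, W)``;
* binary masks are ``uint8`` arrays with values in ``{0, 1}``;
* all coordinates are ``(row, col)``, 0-based, row increasing downward;
  pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import yaml
from PIL import Image, UnidentifiedImageError

# sRGB luminance weights, the standard "gray map" conversion
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class ImageDecodeError(ValueError):
    """Raised when a raster file cannot be decoded."""


class ContractError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# array validation helpers
# ---------------------------------------------------------------------------

def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ContractError(f"RGB image must be (H, W, 3), got {a.shape}")
    if a.shape[0] < 16 or a.shape[1] < 16:
        raise ContractError(f"image too small: {a.shape[:2]} (minimum 16x16)")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ContractError("RGB intensities must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2:
        raise ContractError(f"gray image must be 2-D, got shape {a.shape}")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ContractError("gray intensities must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ContractError(f"mask values must be in {{0, 1}}, got {vals[:8]}")
    return a.astype(np.uint8)


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance gray map of an RGB image (values stay in [0, 1])."""
    return as_rgb_image(image) @ _LUMA


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Ordered polyline of ``(row, col)`` coordinates, optionally closed.

    A closed contour implicitly joins the last point back to the first;
    the closing point is *not* duplicated in ``points``.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContractError(f"contour points must be (N, 2), got {pts.shape}")
        if self.closed and len(pts) < 3:
            raise ContractError("a closed contour needs at least 3 points")
        if len(pts) >= 2:
            same = np.all(np.isclose(pts[1:], pts[:-1]), axis=1)
            if same.any():
                pts = np.concatenate([pts[:1], pts[1:][~same]])
        if self.closed and len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if self.closed and len(pts) < 3:
            raise ContractError("closed contour degenerates to fewer than 3 distinct points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def as_closed_array(self) -> np.ndarray:
        """Points with the first vertex appended again when closed."""
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points

    def length(self) -> float:
        seg = np.diff(self.as_closed_array(), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def resample(self, spacing: float = 1.0) -> "Contour":
        """Resample at approximately uniform arc-length ``spacing`` (pixels)."""
        pts = self.as_closed_array()
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= 0:
            return Contour(self.points.copy(), self.closed)
        n = max(int(round(total / spacing)), 3 if self.closed else 2)
        if self.closed:
            t = np.linspace(0.0, total, n, endpoint=False)
        else:
            t = np.linspace(0.0, total, n)
        rows = np.interp(t, s, pts[:, 0])
        cols = np.interp(t, s, pts[:, 1])
        return Contour(np.column_stack([rows, cols]), self.closed)


def contour_to_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour: 1 where the pixel center is inside or on it.

    Pixel centers lie at integer ``(row, col)``; boundary pixels are included,
    which makes area metrics deterministic.
    """
    if not contour.closed:
        raise ContractError("contour_to_mask requires a closed contour")
    H, W = shape
    pts = contour.points
    # shapely is (x, y) = (col, row)
    ring = np.column_stack([pts[:, 1], pts[:, 0]])
    poly = shapely.Polygon(ring)
    mask = np.zeros((H, W), dtype=np.uint8)

    r0 = max(int(np.floor(pts[:, 0].min())), 0)
    r1 = min(int(np.ceil(pts[:, 0].max())), H - 1)
    c0 = max(int(np.floor(pts[:, 1].min())), 0)
    c1 = min(int(np.ceil(pts[:, 1].max())), W - 1)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    centers = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
    if not poly.is_valid:
        poly = shapely.make_valid(poly)  # repairs minor self-intersections
    if poly.area > 0:
        hit = shapely.covers(poly, centers)
    else:
        # zero-area sliver: keep only boundary pixels
        boundary = shapely.LineString(np.vstack([ring, ring[:1]]))
        hit = shapely.dwithin(boundary, centers, 1e-9)
    mask[rr.ravel()[hit], cc.ravel()[hit]] = 1
    return mask


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/BMP raster as an RGB float image in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"), dtype=float)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageDecodeError(f"cannot decode image {path}: {exc}") from exc
    return as_rgb_image(rgb / 255.0)


def write_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(image, dtype=float)
    data = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data).save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel {0, 255} PNG as a {0, 1} mask."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageDecodeError(f"cannot decode mask {path}: {exc}") from exc
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    m = as_binary_mask(mask)
    Image.fromarray((m * 255).astype(np.uint8), mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# contour I/O (CSV: index,row,col; JSON: {closed, points})
# ---------------------------------------------------------------------------

def write_contour_csv(contour: Contour, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "row", "col"])
        for i, (r, c) in enumerate(contour.points):
            writer.writerow([i, f"{r:.6f}", f"{c:.6f}"])


def read_contour_csv(path: str | Path, closed: bool = True) -> Contour:
    pts = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            pts.append((float(rec["row"]), float(rec["col"])))
    return Contour(np.asarray(pts), closed=closed)


def write_contour_json(contour: Contour, path: str | Path) -> None:
    payload = {"closed": contour.closed, "points": contour.points.tolist()}
    Path(path).write_text(json.dumps(payload))


def read_contour_json(path: str | Path) -> Contour:
    payload = json.loads(Path(path).read_text())
    return Contour(np.asarray(payload["points"], dtype=float), closed=bool(payload["closed"]))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of the segmentation pipeline.

    The geodesic-flow weights follow the published setting mu=1, lam=3,
    nu=0.5, and the snake viscosity alpha=1, beta=1. ``tau`` is the
    explicit-Euler step of the level-set update and must satisfy the
    stability guard ``tau * mu < 0.25``.
    """

    mu: float = 1.0            # distance-regularization weight
    lam: float = 3.0           # weighted-length (edge attraction) weight
    nu: float = 0.5            # weighted-area (balloon/shrink) weight
    tau: float = 0.2           # level-set time step
    rho: float = 2.0           # level-set initialization constant (Eq. binary init)
    sigma: float = 1.0         # Gaussian smoothing std-dev for edge indicators (px)
    alpha: float = 1.0         # snake tension
    beta: float = 1.0          # snake rigidity
    w: float = 0.2             # GVF smoothing weight
    geodesic_iters: int = 1200
    gvf_iters: int = 200
    snake_iters: int = 400
    seed: int = 0
    # numerical details (documented defaults; rarely changed)
    dirac_eps: float = 1.5     # regularized-Dirac half-width (px)
    theta_v: float = 0.05      # GVF-vs-geometric-term switch threshold
    snake_step: float = 0.5    # snake time step (px per unit external force)
    norm_mode: str = "diagonal"  # distance normalizer: diagonal | ref-contour-length

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.rho <= 0 or self.sigma <= 0:
            raise ContractError("tau, rho and sigma must be positive")
        if self.tau * self.mu >= 0.25:
            raise ContractError(
                f"unstable level-set step: tau*mu = {self.tau * self.mu:.3g} >= 0.25"
            )
        for name in ("geodesic_iters", "gvf_iters", "snake_iters"):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be >= 1")
        if self.w <= 0:
            raise ContractError("GVF smoothing weight w must be positive")
        if self.norm_mode not in ("diagonal", "ref-contour-length"):
            raise ContractError(f"unknown norm_mode {self.norm_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})
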