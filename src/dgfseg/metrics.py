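"""Boundary and area error metrics for segmentation evaluation.

Boundary errors between an automatic contour and a manual reference are
the symmetric Hausdorff distance (worst nearest-point distance) and the
symmetric mean distance to the closest point, both computed point-to-
point on contours resampled at ~1 px arc spacing and reported normalized
by the image diagonal (in percent). Area errors are the FP/FN/TP volume
fractions of the automatic mask relative to the reference-mask area, so
TP + FN = 100 exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import ContractError, Contour, as_binary_mask


@dataclass
class MetricsReport:
    norm_hd: float
    norm_md: float
    fp: float
    fn: float
    tp: float
    raw_hd: float
    raw_md: float

    def to_dict(self) -> dict:
        return asdict(self)


def _points(contour: Contour, resample: bool) -> np.ndarray:
    pts = contour.resample(1.0).points if resample else contour.points
    if len(pts) == 0:
        raise ContractError("empty contour")
    return pts


def _directed(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point of ``a`` to its nearest point of ``b``."""
    d, _ = cKDTree(b).query(a)
    return d


def hausdorff(a: Contour, b: Contour, *, resample: bool = True) -> float:
    """Symmetric Hausdorff distance between two contours (pixels)."""
    pa, pb = _points(a, resample), _points(b, resample)
    return float(max(_directed(pa, pb).max(), _directed(pb, pa).max()))


def mean_distance(a: Contour, b: Contour, *, resample: bool = True) -> float:
    """Symmetric mean nearest-point distance (pixels).

    The two directed mean distances are averaged, so the result does not
    depend on which contour has more points.
    """
    pa, pb = _points(a, resample), _points(b, resample)
    return float(0.5 * (_directed(pa, pb).mean() + _directed(pb, pa).mean()))


def normalize_distance(d: float, shape: tuple[int, int], *, ref_length: float | None = None) -> float:
    """Express a pixel distance in percent of the image diagonal.

    With ``ref_length`` given, the reference-contour length is used as the
    normalizer instead (alternative convention, exposed for comparability).
    """
    if d < 0:
        raise ContractError("distance must be >= 0")
    if ref_length is not None:
        denom = ref_length
    else:
        H, W = shape
        denom = float(np.hypot(H, W))
    return 100.0 * d / denom


def volume_fractions(auto: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """FP, FN and TP volume fractions (percent of the reference area)."""
    a = as_binary_mask(auto).astype(bool)
    r = as_binary_mask(ref).astype(bool)
    if a.shape != r.shape:
        raise ContractError(f"shape mismatch: {a.shape} vs {r.shape}")
    n_ref = int(r.sum())
    if n_ref == 0:
        raise ContractError("reference mask is empty")
    tp = 100.0 * np.count_nonzero(a & r) / n_ref
    fn = 100.0 * np.count_nonzero(r & ~a) / n_ref
    fp = 100.0 * np.count_nonzero(a & ~r) / n_ref
    return fp, fn, tp


def evaluate(
    auto_mask: np.ndarray,
    ref_mask: np.ndarray,
    auto_contour: Contour | None = None,
    ref_contour: Contour | None = None,
    *,
    norm_mode: str = "diagonal",
) -> MetricsReport:
    """Full metrics report for one segmentation against a reference.

    Contours default to the mask boundaries (extracted at the 0.5 level).
    """
    from skimage import measure

    def boundary(mask: np.ndarray) -> Contour:
        padded = np.pad(as_binary_mask(mask).astype(float), 1)
        loops = measure.find_contours(padded, 0.5)
        if not loops:
            raise ContractError("mask has no boundary")
        return Contour(max(loops, key=len) - 1.0, closed=True)

    ac = auto_contour if auto_contour is not None else boundary(auto_mask)
    rc = ref_contour if ref_contour is not None else boundary(ref_mask)
    hd = hausdorff(ac, rc)
    md = mean_distance(ac, rc)
    ref_len = rc.length() if norm_mode == "ref-contour-length" else None
    fp, fn, tp = volume_fractions(auto_mask, ref_mask)
    shape = np.asarray(ref_mask).shape
    return MetricsReport(
        norm_hd=normalize_distance(hd, shape, ref_length=ref_len),
        norm_md=normalize_distance(md, shape, ref_length=ref_len),
        fp=fp,
        fn=fn,
        tp=tp,
        raw_hd=hd,
        raw_md=md,
    )
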