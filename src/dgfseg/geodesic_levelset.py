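"""Distance-regularized geodesic level-set flow for the lower contour.

The zero level set of a scalar field Phi is evolved by

    dPhi/dt = mu [ lap(Phi) - div(grad Phi / |grad Phi|) ]        (distance regularization)
            + lam delta_eps(Phi) div( g grad Phi / |grad Phi| )   (weighted length / edge attraction)
            + nu  g delta_eps(Phi)                                (weighted area / shrink)

with the edge indicator g = 1 / (1 + |grad(G_sigma * I)|^2). The
distance-penalty (mu) term keeps Phi close to a signed distance
function, so no explicit re-initialization is ever performed. Updates
are restricted to rows at or below the partition line ``sline``; rows
above keep their initial values bit-exactly, which freezes the upper
half of the initial contour while the lower half shrinks onto the
tongue boundary.

Image intensities are taken on the native 8-bit scale (0-255) when the
edge-indicator gradient is formed: the published weight regime
(mu=1, lam=3, nu=0.5) presumes gradients of that magnitude, and with
unit-interval intensities g would stay ~1 everywhere and never stop the
curve.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, laplace

from .core_io import ContractError, Contour, RunConfig, as_gray_image
from .initialization import RegionPartition
from skimage import measure

#: gradient-norm guard added under square roots
EPS_NORM = 1e-10
#: intensity scale applied before the edge-indicator gradient
EDGE_SCALE = 255.0
#: zero-level set must be unchanged this many consecutive iterations
CONVERGENCE_PATIENCE = 20


class DivergenceError(RuntimeError):
    """Raised when the level-set update produces non-finite values."""


class EmptyContourError(RuntimeError):
    """Raised when a level set has no zero crossing."""


def edge_indicator(image: np.ndarray, sigma: float, *, scale: float = EDGE_SCALE) -> np.ndarray:
    """g = 1 / (1 + |grad(G_sigma * I)|^2), with I on the 0-``scale`` range.

    g == 1 wherever the smoothed gradient vanishes and approaches 0 at
    strong edges.
    """
    if sigma <= 0:
        raise ContractError("sigma must be positive")
    gray = as_gray_image(image) * scale
    sm = gaussian_filter(gray, sigma, mode="nearest")
    gr, gc = np.gradient(sm)
    return 1.0 / (1.0 + gr**2 + gc**2)


def curvature(phi: np.ndarray) -> np.ndarray:
    """kappa = div(grad Phi / |grad Phi|), central differences, norm-guarded."""
    phi = np.asarray(phi, dtype=float)
    if not np.isfinite(phi).all():
        raise ContractError("phi must be finite")
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr**2 + gc**2 + EPS_NORM)
    nr, nc = gr / norm, gc / norm
    return np.gradient(nr, axis=0) + np.gradient(nc, axis=1)


def dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    """Regularized Dirac: (1/2eps)(1 + cos(pi phi / eps)) on |phi| <= eps."""
    out = np.zeros_like(phi)
    band = np.abs(phi) <= eps
    out[band] = (1.0 / (2.0 * eps)) * (1.0 + np.cos(np.pi * phi[band] / eps))
    return out


def _rhs(phi: np.ndarray, g: np.ndarray, g_r: np.ndarray, g_c: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """The three-term right-hand side S(phi) of the evolution equation."""
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr**2 + gc**2 + EPS_NORM)
    nr, nc = gr / norm, gc / norm
    kappa = np.gradient(nr, axis=0) + np.gradient(nc, axis=1)
    lap = laplace(phi, mode="nearest")
    delta = dirac(phi, cfg.dirac_eps)

    reg = cfg.mu * (lap - kappa)
    length = cfg.lam * delta * (g * kappa + g_r * nr + g_c * nc)
    area = cfg.nu * g * delta
    terms = {"distance-regularization": reg, "weighted-length": length, "weighted-area": area}
    for name, t in terms.items():
        if not np.isfinite(t).all():
            raise DivergenceError(f"non-finite values in the {name} term")
    return reg + length + area


def geodesic_step(
    phi: np.ndarray, g: np.ndarray, cfg: RunConfig, part: RegionPartition, *, tau: float | None = None
) -> np.ndarray:
    """One explicit Euler step, applied to rows >= sline only.

    ``tau`` overrides the configured step size; tau = 0 gives the
    identity (useful for testing the update in isolation).
    """
    if tau is None:
        tau = cfg.tau
    phi = np.asarray(phi, dtype=float)
    if tau == 0:
        return phi.copy()
    g_r, g_c = np.gradient(g)
    out = phi.copy()
    s = part.sline
    rs = max(s - 2, 0)  # include 2 frozen rows so the stencil sees true values
    sub = _rhs(phi[rs:], g[rs:], g_r[rs:], g_c[rs:], cfg)
    out[s:] = phi[s:] + tau * sub[s - rs :]
    if not np.isfinite(out).all():
        raise DivergenceError("non-finite level set after update")
    return out


def evolve_geodesic(
    phi0: np.ndarray,
    g: np.ndarray,
    cfg: RunConfig,
    part: RegionPartition,
    *,
    max_iters: int | None = None,
) -> tuple[np.ndarray, int, bool]:
    """Iterate the restricted flow until the zero-level pixel set settles.

    Convergence means the {Phi < 0} pixel set is unchanged for
    ``CONVERGENCE_PATIENCE`` consecutive iterations. No re-initialization
    is performed; the mu-term keeps Phi well conditioned.
    """
    if max_iters is None:
        max_iters = cfg.geodesic_iters
    phi = np.asarray(phi0, dtype=float).copy()
    if max_iters == 0:
        return phi, 0, False
    g = np.asarray(g, dtype=float)
    g_r, g_c = np.gradient(g)
    s = part.sline
    rs = max(s - 2, 0)

    prev_set = phi < 0
    stable = 0
    it = 0
    for it in range(1, max_iters + 1):
        try:
            sub = _rhs(phi[rs:], g[rs:], g_r[rs:], g_c[rs:], cfg)
        except DivergenceError as exc:
            raise DivergenceError(f"iteration {it}: {exc}") from exc
        phi[s:] += cfg.tau * sub[s - rs :]
        if not np.isfinite(phi).all():
            raise DivergenceError(f"non-finite level set at iteration {it}")
        cur = phi < 0
        if (cur == prev_set).all():
            stable += 1
            if stable >= CONVERGENCE_PATIENCE:
                return phi, it, True
        else:
            stable = 0
            prev_set = cur
    return phi, it, False


def extract_zero_contour(phi: np.ndarray) -> Contour:
    """Ordered closed polyline of the Phi = 0 isoline (sub-pixel).

    Marching squares with linear interpolation; the longest loop is
    returned when the level set has several.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.min() >= 0 or phi.max() <= 0:
        raise EmptyContourError("level set has no zero crossing")
    loops = measure.find_contours(phi, 0.0)
    if not loops:
        raise EmptyContourError("no zero contour found")
    pts = max(loops, key=lambda a: len(a))
    closed = bool(np.allclose(pts[0], pts[-1]))
    return Contour(pts, closed=closed)


def sdf_band_error(phi: np.ndarray, band: float = 3.0) -> float:
    """Mean | |grad Phi| - 1 | over the band |Phi| <= band.

    Diagnostic for how close Phi stays to a signed distance function.
    """
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr**2 + gc**2)
    sel = np.abs(phi) <= band
    if not sel.any():
        return 0.0
    return float(np.abs(norm[sel] - 1.0).mean())
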