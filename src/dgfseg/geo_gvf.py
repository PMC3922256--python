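"""Binary-map gradient vector flow and the Geo-GVF snake (upper contour).

The external field V_B is obtained by diffusing the gradient of the
binary upper map B (dark mouth-opening strip = 1):

    dV_B/dt = w lap(V_B) - |grad B|^2 (V_B - grad B)

so V_B relaxes to grad B at the strip edges and spreads smoothly into
flat regions, restricted to the upper partition rows (no force below
``sline``). The snake is the open arc between the two pinned angular
points, evolved semi-implicitly:

    dC/dt = alpha C'' - beta C'''' + F_ext

The published external force max(V_B, G_B) — vector-flow attraction
where it is significant, geometric outward propulsion G_B = g_B n where
it vanishes — is realized as a three-regime switch per contour point p:

* p inside the dark region (B >= 1/2): retreat along -n. The binary map
  marks non-tongue territory in the upper part; stepping back the moment
  the curve crosses into it is what makes the map prevent over-learning,
  and it pins the equilibrium to the strip's tongue-side edge.
* |V_B(p)| >= theta_v: the vector flow V_B(p) (near-boundary regime).
* otherwise: G_B(p) = g_B(p) n(p), the edge-stopped outward propulsion
  (far-field regime; g_B is the edge indicator of the smoothed B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, laplace, map_coordinates

from .core_io import ContractError, RunConfig, as_binary_mask
from .geodesic_levelset import EDGE_SCALE
from .initialization import RegionPartition


class GVFDivergenceError(RuntimeError):
    """Raised when the GVF iteration produces non-finite values."""


@dataclass
class VectorField:
    """Per-pixel 2-vector external force field (rows >= sline are zero)."""

    u: np.ndarray  # row component
    v: np.ndarray  # col component

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear samples (N, 2) of the field at (row, col) points."""
        pts = np.asarray(points, dtype=float).T
        fu = map_coordinates(self.u, pts, order=1, mode="nearest")
        fv = map_coordinates(self.v, pts, order=1, mode="nearest")
        return np.column_stack([fu, fv])


@dataclass
class SnakeState:
    """Open upper-contour arc with pinned endpoints (the angular points)."""

    points: np.ndarray
    alpha: float = 1.0
    beta: float = 1.0
    interior_point: tuple = (0.0, 0.0)  # reference inside the tongue, orients normals

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
            raise ContractError("snake needs an (N>=5, 2) point array")
        self.points = pts

    def resample(self, spacing: float = 1.0) -> "SnakeState":
        pts = self.points
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            raise ContractError("degenerate snake: zero arc length")
        n = max(int(round(s[-1] / spacing)) + 1, 5)
        t = np.linspace(0.0, s[-1], n)
        rows = np.interp(t, s, pts[:, 0])
        cols = np.interp(t, s, pts[:, 1])
        return SnakeState(np.column_stack([rows, cols]), self.alpha, self.beta, self.interior_point)

    def normals(self) -> np.ndarray:
        """Unit outward normals (pointing away from the interior point)."""
        pts = self.points
        tang = np.gradient(pts, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        if (norm < 1e-12).any():
            raise ContractError("degenerate normal: repeated snake points")
        tang = tang / norm[:, None]
        n = np.column_stack([-tang[:, 1], tang[:, 0]])
        away = pts - np.asarray(self.interior_point, dtype=float)
        flip = (n * away).sum(axis=1) < 0
        n[flip] = -n[flip]
        return n


def compute_gvf(map_2d: np.ndarray, w: float, iters: int, part: RegionPartition) -> VectorField:
    """Gradient vector flow of an arbitrary scalar map on the upper rows.

    The time step satisfies the 4-neighbor diffusion stability bound for
    the given smoothing weight ``w``. The field is identically zero on
    rows >= sline ("no force in the under part").
    """
    if w <= 0 or iters < 1:
        raise ContractError("need w > 0 and iters >= 1")
    b = np.asarray(map_2d, dtype=float)
    s = part.sline
    sub = b[:s]
    br, bc = np.gradient(sub)
    mag2 = br**2 + bc**2
    # diffusion explicit within its 4-neighbor stability bound, reaction
    # semi-implicit (unconditionally stable, same fixed point)
    dt = min(1.0, 0.25 / w)
    damp = 1.0 / (1.0 + dt * mag2)
    u, v = br.copy(), bc.copy()
    for it in range(iters):
        u = damp * (u + dt * (w * laplace(u, mode="nearest") + mag2 * br))
        v = damp * (v + dt * (w * laplace(v, mode="nearest") + mag2 * bc))
        if it % 50 == 0 and not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise GVFDivergenceError(
                f"GVF diverged at iteration {it}; reduce w or the implied time step"
            )
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise GVFDivergenceError("GVF diverged; reduce w or the implied time step")
    U = np.zeros_like(b)
    V = np.zeros_like(b)
    U[:s], V[:s] = u, v
    return VectorField(U, V)


def compute_binary_gvf(
    B: np.ndarray, w: float, iters: int, part: RegionPartition
) -> VectorField:
    """GVF of the binary upper map (dark mouth-opening region = 1)."""
    return compute_gvf(as_binary_mask(B).astype(float), w, iters, part)


def gvf_residual(B: np.ndarray, field: VectorField, w: float, part: RegionPartition) -> float:
    """Max norm of w lap(V) - |grad B|^2 (V - grad B) on the upper rows."""
    b = as_binary_mask(B).astype(float)
    s = part.sline
    sub = b[:s]
    br, bc = np.gradient(sub)
    mag2 = br**2 + bc**2
    ru = w * laplace(field.u[:s], mode="nearest") - mag2 * (field.u[:s] - br)
    rv = w * laplace(field.v[:s], mode="nearest") - mag2 * (field.v[:s] - bc)
    return float(np.hypot(ru, rv).max())


def binary_edge_indicator(B: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """g_B = 1 / (1 + |grad(G_sigma * B)|^2), B on the 0-255 scale."""
    b = np.asarray(B, dtype=float) * EDGE_SCALE
    sm = gaussian_filter(b, sigma, mode="nearest")
    gr, gc = np.gradient(sm)
    return 1.0 / (1.0 + gr**2 + gc**2)


def geometric_term(
    B: np.ndarray, contour: SnakeState, sigma: float = 1.0, *, g_map: np.ndarray | None = None
) -> np.ndarray:
    """G_B(p) = g_B(p) * n(p): outward unit normal scaled by the edge factor.

    In flat regions of B the smoothed gradient vanishes, g_B = 1 and the
    term propels the curve outward at unit strength; on a strong binary
    edge g_B ~ 0 and the propulsion stops.
    """
    if g_map is None:
        g_map = binary_edge_indicator(B, sigma)
    n = contour.normals()
    g = map_coordinates(g_map, contour.points.T, order=1, mode="nearest")
    return g[:, None] * n


def _internal_matrix(n: int, alpha: float, beta: float, dt: float) -> np.ndarray:
    """(I - dt*(alpha D2 - beta D4)) with pinned first/last rows.

    D4 uses linear-extrapolation ghosts next to the pinned endpoints so a
    straight, evenly spaced arc is exactly stationary.
    """
    A = np.zeros((n, n))
    for i in range(1, n - 1):
        A[i, i - 1] += alpha
        A[i, i] += -2 * alpha
        A[i, i + 1] += alpha
    for i in range(1, n - 1):
        stencil = {i - 2: -1.0, i - 1: 4.0, i: -6.0, i + 1: 4.0, i + 2: -1.0}
        row: dict[int, float] = {}
        for j, c in stencil.items():
            cb = beta * c
            if j < 0:  # ghost x_{-1} = 2 x_0 - x_1
                row[0] = row.get(0, 0.0) + 2 * cb
                row[1] = row.get(1, 0.0) - cb
            elif j > n - 1:  # ghost x_n = 2 x_{n-1} - x_{n-2}
                row[n - 1] = row.get(n - 1, 0.0) + 2 * cb
                row[n - 2] = row.get(n - 2, 0.0) - cb
            else:
                row[j] = row.get(j, 0.0) + cb
        for j, c in row.items():
            A[i, j] += c
    M = np.eye(n) - dt * A
    M[0, :] = 0.0
    M[0, 0] = 1.0
    M[-1, :] = 0.0
    M[-1, -1] = 1.0
    return M


def external_force(
    state: SnakeState,
    V: VectorField,
    G: np.ndarray,
    cfg: RunConfig,
    B: np.ndarray | None = None,
    *,
    use_geometric: bool = True,
) -> np.ndarray:
    """Per-point external force under the three-regime switch."""
    pts = state.points
    f_v = V.sample(pts)
    mag = np.hypot(f_v[:, 0], f_v[:, 1])
    strong = mag >= cfg.theta_v
    F = np.where(strong[:, None], f_v, G if use_geometric else 0.0)
    if B is not None:
        bval = map_coordinates(np.asarray(B, dtype=float), pts.T, order=1, mode="nearest")
        overshoot = bval >= 0.5
        n = state.normals()
        F = np.where(overshoot[:, None], -n, F)
    return F


def snake_step(
    state: SnakeState,
    V: VectorField,
    G: np.ndarray,
    cfg: RunConfig,
    *,
    B: np.ndarray | None = None,
    dt: float | None = None,
    use_geometric: bool = True,
) -> SnakeState:
    """One semi-implicit internal solve plus explicit external force.

    Endpoints are pinned (zero force, identity rows in the system).
    """
    pts = state.points
    n = len(pts)
    if np.asarray(G).shape != pts.shape:
        raise ContractError("geometric term must provide one vector per point")
    if dt is None:
        dt = cfg.snake_step
    F = external_force(state, V, G, cfg, B, use_geometric=use_geometric)
    F[0] = 0.0
    F[-1] = 0.0
    M = _internal_matrix(n, state.alpha, state.beta, dt)
    rhs = pts + dt * F
    rhs[0] = pts[0]
    rhs[-1] = pts[-1]
    try:
        new_pts = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ContractError(f"singular internal-force system: {exc}") from exc
    return SnakeState(new_pts, state.alpha, state.beta, state.interior_point)


def evolve_snake(
    init: SnakeState,
    V: VectorField,
    B: np.ndarray,
    cfg: RunConfig,
    *,
    max_iters: int | None = None,
    use_geometric: bool = True,
    use_region_stop: bool = True,
) -> tuple[SnakeState, int, bool]:
    """Iterate snake steps with per-iteration arc-length resampling.

    Converged when the maximum point displacement stays below 0.05 px
    for 10 consecutive iterations; the step size is halved (up to three
    times) when the displacement plateaus, which damps the limit-cycle
    flutter of the regime switch near the boundary.
    """
    if max_iters is None:
        max_iters = cfg.snake_iters
    state = init
    if max_iters == 0:
        return state, 0, False
    g_map = binary_edge_indicator(B, sigma=1.0)
    b_float = as_binary_mask(B).astype(float) if use_region_stop else None
    dt = cfg.snake_step
    calm = 0
    halvings = 0
    anchor = state.points.mean(axis=0)
    it = 0
    for it in range(1, max_iters + 1):
        G = geometric_term(B, state, g_map=g_map)
        new = snake_step(state, V, G, cfg, B=b_float, dt=dt, use_geometric=use_geometric)
        disp = float(np.hypot(*(new.points - state.points).T).max())
        state = new.resample(1.0)
        if disp < 0.05:
            calm += 1
            if calm >= 10:
                return state, it, True
        else:
            calm = 0
        # step-size annealing: when the arc oscillates in place (the switch's
        # limit cycle at the boundary) rather than travelling, halve the step
        if it % 30 == 0 and halvings < 4:
            centroid = state.points.mean(axis=0)
            if np.hypot(*(centroid - anchor)) < 1.5 * dt:
                dt *= 0.5
                halvings += 1
            anchor = centroid
    return state, it, False
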