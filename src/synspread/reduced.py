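"""Single-region two-compartment phase-plane analysis.

Collapsing the network model to one well-mixed region gives a planar system
for the normal (N) and misfolded (M) populations:

    dN/dt = alpha - beta1 * N - (1 - beta1) * g(M) * N
    dM/dt = (1 - beta1) * g(M) * N - beta2 * M

with the saturating transmission probability

    g(M) = 1 - exp(M * ln(1 - gamma)) = 1 - (1 - gamma)^M.

Synthesis inflow alpha and linear clearances beta1 N, beta2 M are the
continuous-time counterparts of the per-step synthesis/clearance fractions;
the (1 - beta1) factor carries the "only agents that survive clearance can be
infected" structure of the discrete update into the flow.  On the disease-free
axis (M = 0) the flow balances at N = alpha / beta1, and when beta1 = beta2 the
two nullclines intersect once more at a positive-M endemic point; with
alpha = 5000, beta1 = beta2 = 0.5, gamma = 0.001 the two fixed points sit at
(10000, 0) and (5017.15, 4982.85).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class ReducedModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReducedParams:
    """alpha: synthesis inflow (agents/time); beta1/beta2: clearance rates of
    normal/misfolded agents (1/time); gamma: baseline per-agent transmission
    probability."""

    alpha: float
    beta1: float
    beta2: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta1, self.beta2, self.gamma) <= 0:
            raise ReducedModelError("all reduced-model parameters must be > 0")
        if self.gamma >= 1 or self.beta1 >= 1:
            raise ReducedModelError("gamma and beta1 must be < 1 (probabilities)")


@dataclass(frozen=True)
class FixedPoint:
    N: float
    M: float
    stability: str  # 'stable' | 'unstable' | 'saddle'


def _g(M, p: ReducedParams):
    """Saturating transmission probability 1 - (1 - gamma)^M."""
    return -np.expm1(np.asarray(M, dtype=float) * np.log1p(-p.gamma))


def reduced_derivatives(N, M, p: ReducedParams) -> tuple[np.ndarray, np.ndarray]:
    """(dN/dt, dM/dt) of the reduced system; M = 0 is flow invariant."""
    N = np.asarray(N, dtype=float)
    M = np.asarray(M, dtype=float)
    if (N < 0).any() or (M < 0).any():
        raise ReducedModelError("populations must be >= 0")
    flux = (1.0 - p.beta1) * _g(M, p) * N
    dN = p.alpha - p.beta1 * N - flux
    dM = flux - p.beta2 * M
    if dN.ndim == 0:
        return float(dN), float(dM)
    return dN, dM


def nullclines(p: ReducedParams, M_grid: np.ndarray) -> pd.DataFrame:
    """N-nullcline and M-nullcline sampled on an M grid (for plotting)."""
    M = np.asarray(M_grid, dtype=float)
    g = _g(M, p)
    n_null = p.alpha / (p.beta1 + (1.0 - p.beta1) * g)          # dN/dt = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m_null = np.where(g > 0, p.beta2 * M / ((1.0 - p.beta1) * g), np.nan)  # dM/dt = 0
    return pd.DataFrame({"M": M, "N_nullcline": n_null, "M_nullcline": m_null})


def find_fixed_points(
    p: ReducedParams,
    m_grid: np.ndarray | None = None,
    xtol: float = 1e-10,
) -> list[FixedPoint]:
    """All nonnegative nullcline intersections, classified.

    The disease-free point (alpha / beta1, 0) always exists.  Positive-M
    intersections are found by restricting the flow to the N-nullcline
    N(M) = alpha / (beta1 + (1 - beta1) g(M)) and locating sign changes of
    dM/dt on an M grid (default: 1e4 log-spaced points spanning
    [1e-6, 10 alpha / beta2]), refined with Brent's method.
    """
    if m_grid is None:
        m_grid = np.logspace(-6, np.log10(10.0 * p.alpha / p.beta2), 10_000)
    m_grid = np.asarray(m_grid, dtype=float)

    def h(M: float) -> float:
        g = _g(M, p)
        N = p.alpha / (p.beta1 + (1.0 - p.beta1) * g)
        return (1.0 - p.beta1) * g * N - p.beta2 * M

    vals = np.array([h(m) for m in m_grid])
    roots: list[float] = []
    for a, b, va, vb in zip(m_grid[:-1], m_grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(float(a))
        elif va * vb < 0:
            try:
                roots.append(float(brentq(h, a, b, xtol=xtol)))
            except RuntimeError as err:  # pragma: no cover - brentq is robust
                raise ReducedModelError(f"root refinement failed in [{a}, {b}]") from err
    # de-duplicate near-coincident roots from adjacent brackets
    uniq: list[float] = []
    for r in roots:
        if not uniq or abs(r - uniq[-1]) > 1e-6 * max(1.0, abs(r)):
            uniq.append(r)

    fps = [FixedPoint(p.alpha / p.beta1, 0.0, "")]
    for M in uniq:
        g = _g(M, p)
        fps.append(FixedPoint(p.alpha / (p.beta1 + (1.0 - p.beta1) * g), M, ""))
    return [
        FixedPoint(fp.N, fp.M, classify_fixed_point(p, fp).stability) for fp in fps
    ]


def classify_fixed_point(p: ReducedParams, fp: FixedPoint, marginal_tol: float = 1e-8) -> FixedPoint:
    """Label a fixed point from the eigenvalues of a finite-difference Jacobian."""
    scale = max(abs(fp.N), abs(fp.M), 1.0)
    h = 1e-6 * scale

    def f(x):
        return np.array(reduced_derivatives(max(x[0], 0.0), max(x[1], 0.0), p))

    x0 = np.array([fp.N, fp.M], dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        J[:, j] = (f(x0 + e) - f(x0 - e)) / (2 * h)
    ev = np.linalg.eigvals(J)
    re = ev.real
    if (np.abs(re) < marginal_tol).any():
        raise ReducedModelError(
            f"marginal fixed point at (N={fp.N:.6g}, M={fp.M:.6g}): "
            f"eigenvalue real parts {re}"
        )
    if (re < 0).all():
        label = "stable"
    elif (re > 0).all():
        label = "unstable"
    else:
        label = "saddle"
    return FixedPoint(fp.N, fp.M, label)


def reduced_map_step(N: float, M: float, p: ReducedParams, dt: float = 0.01,
                     S: float = 1.0) -> tuple[float, float]:
    """One step of the discrete single-region map (for comparison).

    Mirrors the per-step network update with synthesis inflow alpha * dt,
    clearance fractions 1 - exp(-beta dt) and infection of survivors with
    probability 1 - (1 - gamma)^(M dt / S).
    """
    clear1 = 1.0 - np.exp(-p.beta1 * dt)
    clear2 = 1.0 - np.exp(-p.beta2 * dt)
    inf = -np.expm1(M * dt / S * np.log1p(-p.gamma))
    flux = np.exp(-p.beta1 * dt) * inf * N
    return (
        N + p.alpha * dt - clear1 * N - flux,
        M + flux - clear2 * M,
    )
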