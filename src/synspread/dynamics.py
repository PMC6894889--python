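"""Mean-field agent-based S-I-R dynamics on a connectome.

Agents are individual alpha-synuclein proteins.  Normal (susceptible) agents
are synthesized per voxel at rate alpha_i, cleared at rate beta_i, and walk
the network: per unit time an agent in region i stays with probability rho_i
or enters edge (i, j) with probability (1 - rho_i) w_ij / sum_j w_ij; an agent
in edge (i, j) exits into region j with probability v / l_ij.  Misfolded
(infected) agents share the same mobility and clearance.  Normal agents that
survive clearance misfold with probability 1 - exp(-M_i / S_i * dt), i.e. the
chance of meeting at least one of the M_i misfolded agents, with the baseline
transmission rate set to the reciprocal of region size.

The default integration is deterministic (subpopulation means, real valued);
a stochastic integer-agent variant with the same expected increments is
provided for validation.  All per-step operators accept leading batch
dimensions, which the epicenter scans exploit.

The infection fraction is evaluated literally as ``1 - exp(-x)``.  For
``x`` below ~1.1e-16 this is exactly 0 in double precision, so sufficiently
small misfolded populations cannot transmit at all.  That floor is what makes
the regional spread threshold (see :mod:`synspread.epicenter`) finite and
region dependent; do not "fix" it with ``expm1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .connectome import Connectome
from .profiles import RegionalProfiles


class DynamicsError(RuntimeError):
    """Raised when the integrator is handed or produces an invalid state."""


@dataclass
class SimulationParams:
    """Knobs of the spreading simulation.

    dt : time step (unit time = 1, default 0.01).
    rho : per-region stay probability (scalar or per-region), default 0.5.
    k1, k2 : atrophy weights for direct toxicity and deafferentation;
        must satisfy k1 + k2 = 1 (default 0.5 / 0.5).
    fc_k : functional-connectivity influence k >= 0 (0 = ignore FC).
    v : edge-traversal speed factor; exit probability becomes v / l_ij.
    tol : equilibrium tolerance on the per-step state change.
    max_steps : S-I-R horizon in steps for :func:`simulate`.
    growth_max_steps : safety cap for the growth-to-equilibrium iteration.
    seed_region / seed_amount : where and how much misfolded protein to inject.
    update_mode : 'asynchronous' (propagation then reactions, the default)
        or 'synchronous' (both increments from the pre-step state).
    record_stride : trajectory sampling interval in steps.
    rng_seed : seed for the stochastic variant.
    """

    dt: float = 0.01
    rho: float | np.ndarray = 0.5
    k1: float = 0.5
    k2: float = 0.5
    fc_k: float = 0.0
    v: float = 1.0
    tol: float = 1e-7
    max_steps: int = 10_000
    growth_max_steps: int = 2_000_000
    seed_region: Optional[str] = None
    seed_amount: float = 1.0
    update_mode: str = "asynchronous"
    record_stride: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DynamicsError("dt must be > 0")
        rho = np.asarray(self.rho, dtype=float)
        if ((rho <= 0) | (rho >= 1)).any():
            raise DynamicsError("rho must lie strictly in (0, 1)")
        if self.k1 < 0 or self.k2 < 0 or abs(self.k1 + self.k2 - 1.0) > 1e-12:
            raise DynamicsError("k1, k2 must be >= 0 with k1 + k2 = 1")
        if self.fc_k < 0:
            raise DynamicsError("fc_k must be >= 0")
        if self.v <= 0:
            raise DynamicsError("v must be > 0")
        if self.tol <= 0:
            raise DynamicsError("tol must be > 0")
        if self.update_mode not in ("asynchronous", "synchronous"):
            raise DynamicsError("update_mode must be 'asynchronous' or 'synchronous'")

    def replace(self, **changes) -> "SimulationParams":
        return replace(self, **changes)


@dataclass
class SystemState:
    """Region and edge populations of normal (N) and misfolded (M) agents.

    Arrays may carry leading batch dimensions: region quantities are
    ``(..., n)``, edge quantities ``(..., n, n)`` with the first edge index
    the source region.  ``L`` is cumulative atrophy, ``r_prev`` the misfolded
    proportion at the previous step (used by the deafferentation term).
    """

    N: np.ndarray
    M: np.ndarray
    N_edge: np.ndarray
    M_edge: np.ndarray
    L: np.ndarray
    r_prev: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n: int, batch: tuple[int, ...] = ()) -> "SystemState":
        return cls(
            N=np.zeros(batch + (n,)),
            M=np.zeros(batch + (n,)),
            N_edge=np.zeros(batch + (n, n)),
            M_edge=np.zeros(batch + (n, n)),
            L=np.zeros(batch + (n,)),
            r_prev=np.zeros(batch + (n,)),
        )

    def copy(self) -> "SystemState":
        return SystemState(
            self.N.copy(), self.M.copy(), self.N_edge.copy(), self.M_edge.copy(),
            self.L.copy(), self.r_prev.copy(), self.t,
        )

    def total_N(self) -> np.ndarray:
        """Total normal agents (regions + edges), per batch element."""
        return self.N.sum(axis=-1) + self.N_edge.sum(axis=(-2, -1))

    def total_M(self) -> np.ndarray:
        return self.M.sum(axis=-1) + self.M_edge.sum(axis=(-2, -1))

    def misfolded_proportion(self) -> np.ndarray:
        """r_i = M_i / (N_i + M_i), defined as 0 where both vanish."""
        tot = self.N + self.M
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot > 0, self.M / np.where(tot > 0, tot, 1.0), 0.0)
        return r

    def check(self) -> None:
        for name in ("N", "M", "N_edge", "M_edge", "L"):
            a = getattr(self, name)
            if not np.isfinite(a).all():
                raise DynamicsError(f"non-finite values in {name} at step {self.t}")
            if (a < 0).any():
                raise DynamicsError(f"negative values in {name} at step {self.t}")


@dataclass
class Trajectory:
    """Recorded simulation output at a fixed stride."""

    times: np.ndarray                 # step indices, strictly increasing
    N: np.ndarray                     # (T, n)
    M: np.ndarray                     # (T, n)
    density: np.ndarray               # misfolded density M_i / S_i, (T, n)
    atrophy: np.ndarray               # cumulative L, (T, n)
    region_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise DynamicsError("trajectory times must be strictly increasing")


# ---------------------------------------------------------------------------
# elementary probabilities


def edge_exit_probability(l_ij: float | np.ndarray, v: float = 1.0) -> float | np.ndarray:
    """Per-unit-time probability v / l_ij of exiting an edge of length l_ij."""
    l_ij = np.asarray(l_ij, dtype=float)
    if (v > l_ij).any():
        raise DynamicsError("speed v must not exceed edge length (probability > 1)")
    out = v / l_ij
    return float(out) if out.ndim == 0 else out


def infection_probability(M_i, S_i, dt: float):
    """Fraction of surviving normal agents misfolded within dt.

    ``1 - exp(-M_i / S_i * dt)``; deliberately evaluated with ``exp`` so the
    fraction is exactly zero once the exponent drops below double-precision
    resolution (the finite-spread-threshold mechanism).
    """
    M_i = np.asarray(M_i, dtype=float)
    if (M_i < 0).any():
        raise DynamicsError("misfolded population must be >= 0")
    out = 1.0 - np.exp(-(M_i / np.asarray(S_i, dtype=float)) * dt)
    return float(out) if out.ndim == 0 else out


def clearance_fraction(beta_i, dt: float):
    """Fraction of agents cleared within dt: 1 - exp(-beta * dt)."""
    beta_i = np.asarray(beta_i, dtype=float)
    if ((beta_i <= 0) | (beta_i >= 1)).any():
        raise DynamicsError("clearance rate must lie strictly in (0, 1)")
    out = 1.0 - np.exp(-beta_i * dt)
    return float(out) if out.ndim == 0 else out


def region_transition_probabilities(
    i: int,
    c: Connectome,
    rho_i: float = 0.5,
    fc: Optional[np.ndarray] = None,
    fc_k: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial distribution over {stay} + outgoing edges of region i.

    Returns ``(p, neighbors)`` where ``p[0]`` is the stay probability rho_i and
    ``p[1:]`` the probabilities of entering edge (i, j) for each neighbor j,
    FC-rescaled by exp(fc_k * fc(i, j)) when an FC matrix is supplied.
    """
    w = c.weights[i]
    neighbors = np.flatnonzero(w > 0)
    if neighbors.size == 0:
        raise DynamicsError(f"region {c.region_names[i]!r} is isolated")
    scale = np.ones_like(w) if fc is None else np.exp(fc_k * np.asarray(fc, dtype=float)[i])
    if fc is not None and (np.asarray(fc)[i] < 0).any():
        raise DynamicsError("FC entries must be >= 0 (zero negatives on load)")
    ew = scale[neighbors] * w[neighbors]
    p_edges = (1.0 - rho_i) * ew / ew.sum()
    return np.concatenate(([1.0 - p_edges.sum()], p_edges)), neighbors


# ---------------------------------------------------------------------------
# the step engine


class Engine:
    """Precomputed per-step operators for one (connectome, profiles, params, fc).

    All methods operate on raw arrays and broadcast over leading batch
    dimensions.  Public module functions wrap this for single states.
    """

    def __init__(
        self,
        c: Connectome,
        profiles: RegionalProfiles,
        params: SimulationParams,
        fc: Optional[np.ndarray] = None,
    ):
        if list(profiles.region_names) != list(c.region_names):
            raise DynamicsError("profiles and connectome regions do not match")
        n = c.n_regions
        self.c, self.params = c, params
        dt = params.dt
        rho = np.broadcast_to(np.asarray(params.rho, dtype=float), (n,))
        mask = c.edge_mask
        if fc is not None:
            fc = np.asarray(fc, dtype=float)
            if fc.shape != (n, n):
                raise DynamicsError(f"FC matrix must be ({n}, {n})")
            if (fc < 0).any():
                raise DynamicsError("FC entries must be >= 0 (zero negatives on load)")
        scale = np.ones((n, n)) if fc is None else np.exp(params.fc_k * fc)
        ew = np.where(mask, scale * c.weights, 0.0)
        rowsum = ew.sum(axis=1, keepdims=True)
        self.share = np.divide(ew, rowsum, out=np.zeros_like(ew), where=rowsum > 0)
        self.leave_frac = np.where(mask.any(axis=1), (1.0 - rho) * dt, 0.0)
        with np.errstate(divide="ignore"):
            exit_p = np.where(mask, params.v / np.where(mask, c.lengths, 1.0), 0.0)
        if (exit_p > 1).any():
            raise DynamicsError("v / l_ij exceeds 1 on some edge")
        self.exit_frac = exit_p * dt
        self.alphaS_dt = profiles.synthesis_rate * c.sizes * dt
        beta = profiles.clearance_rate
        self.surv = np.exp(-beta * dt)
        self.clear_frac = 1.0 - self.surv
        self.gamma0_dt = dt / c.sizes.astype(float)
        # deafferentation weights: in-strengths normalized per receiving region
        colsum = c.weights.sum(axis=0, keepdims=True)
        self.deaff = np.divide(c.weights, colsum, out=np.zeros_like(c.weights), where=colsum > 0)
        self.dt = dt

    # -- sub-steps ---------------------------------------------------------

    def mobility_increments(self, R: np.ndarray, E: np.ndarray):
        """Increments of one species' region (R) and edge (E) populations.

        Region i loses (1 - rho_i) R_i dt into its edges (split by share)
        and gains sum_j (v / l_ji) E_ji dt from incoming edges.  The exchange
        conserves the species total exactly.
        """
        leave = R * self.leave_frac
        gain_e = leave[..., :, None] * self.share
        exit_e = E * self.exit_frac
        dR = exit_e.sum(axis=-2) - leave
        dE = gain_e - exit_e
        return dR, dE

    def react_increments(self, N, M):
        """Synthesis, clearance and infection increments."""
        inf = 1.0 - np.exp(-self.gamma0_dt * M)  # exact-zero floor intended
        flux = self.surv * inf * N
        dN = self.alphaS_dt - self.clear_frac * N - flux
        dM = flux - self.clear_frac * M
        return dN, dM

    def growth_increments(self, N):
        return self.alphaS_dt - self.clear_frac * N

    # -- full steps --------------------------------------------------------

    def step_arrays(self, N, M, Ne, Me, infect: bool = True):
        """One full step on raw arrays; returns updated copies."""
        if self.params.update_mode == "synchronous":
            dN, dNe = self.mobility_increments(N, Ne)
            dM, dMe = self.mobility_increments(M, Me)
            rN, rM = self.react_increments(N, M) if infect else (self.growth_increments(N), 0.0)
            return N + dN + rN, M + dM + rM, Ne + dNe, Me + dMe
        dN, dNe = self.mobility_increments(N, Ne)
        N, Ne = N + dN, Ne + dNe
        dM, dMe = self.mobility_increments(M, Me)
        M, Me = M + dM, Me + dMe
        if infect:
            rN, rM = self.react_increments(N, M)
            N, M = N + rN, M + rM
        else:
            N = N + self.growth_increments(N)
        return N, M, Ne, Me

    def atrophy_delta(self, r_now, r_prev):
        direct = 1.0 - np.exp(-r_now * self.dt)
        remote = 1.0 - np.exp(-r_prev * self.dt)
        k1, k2 = self.params.k1, self.params.k2
        return k1 * direct + k2 * (remote[..., None, :] @ self.deaff)[..., 0, :]


# ---------------------------------------------------------------------------
# public operations


def propagation_substep(
    state: SystemState,
    c: Connectome,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    profiles: Optional[RegionalProfiles] = None,
    engine: Optional[Engine] = None,
) -> SystemState:
    """Apply only the mobility exchange (both species); conserves totals."""
    eng = engine or Engine(c, profiles or _unit_profiles(c), params, fc)
    s = state.copy()
    dN, dNe = eng.mobility_increments(s.N, s.N_edge)
    dM, dMe = eng.mobility_increments(s.M, s.M_edge)
    s.N, s.N_edge = s.N + dN, s.N_edge + dNe
    s.M, s.M_edge = s.M + dM, s.M_edge + dMe
    return s


def _unit_profiles(c: Connectome) -> RegionalProfiles:
    z = np.zeros(c.n_regions)
    return RegionalProfiles(c.region_names, z, z)


def growth_step(
    state: SystemState,
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    engine: Optional[Engine] = None,
) -> SystemState:
    """One disease-free step: mobility plus synthesis/clearance of N."""
    if state.M.any() or state.M_edge.any():
        raise DynamicsError("growth_step requires a misfolding-free state")
    eng = engine or Engine(c, profiles, params, fc)
    s = state.copy()
    s.N, s.M, s.N_edge, s.M_edge = eng.step_arrays(s.N, s.M, s.N_edge, s.M_edge, infect=False)
    s.t += 1
    s.check()
    return s


def growth_to_equilibrium(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    init: Optional[SystemState] = None,
    engine: Optional[Engine] = None,
) -> tuple[SystemState, np.ndarray]:
    """Iterate the disease-free growth until the state stops changing.

    Convergence requires the largest absolute per-step change across regional
    and edge populations to fall below ``params.tol``.  Returns the
    equilibrium state and the regional density N_i / S_i.
    """
    eng = engine or Engine(c, profiles, params, fc)
    state = init.copy() if init is not None else SystemState.zeros(c.n_regions)
    N, Ne = state.N, state.N_edge
    M = np.zeros_like(N)
    Me = np.zeros_like(Ne)
    for step in range(params.growth_max_steps):
        N2, _, Ne2, _ = eng.step_arrays(N, M, Ne, Me, infect=False)
        resid = max(np.abs(N2 - N).max(), np.abs(Ne2 - Ne).max())
        N, Ne = N2, Ne2
        if resid < params.tol:
            break
    else:
        raise DynamicsError(
            f"growth did not converge within {params.growth_max_steps} steps "
            f"(residual {resid:.3e} > tol {params.tol:.1e})"
        )
    out = SystemState(N=N, M=M, N_edge=Ne, M_edge=Me,
                      L=np.zeros_like(N), r_prev=np.zeros_like(N), t=step + 1)
    out.check()
    return out, N / c.sizes


def seed_infection(
    state: SystemState,
    region: int | str,
    amount: float,
    c: Optional[Connectome] = None,
) -> SystemState:
    """Inject misfolded agents into a region (adds agents, N untouched)."""
    if amount <= 0:
        raise DynamicsError("seed amount must be > 0")
    if isinstance(region, str):
        if c is None:
            raise DynamicsError("a Connectome is required to resolve region names")
        region = c.index_of(region)
    if not 0 <= region < state.M.shape[-1]:
        raise DynamicsError(f"region index {region} out of range")
    s = state.copy()
    s.M[..., region] += amount
    return s


def sir_step(
    state: SystemState,
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    engine: Optional[Engine] = None,
) -> SystemState:
    """One full S-I-R step: propagation, then synthesis/clearance/infection.

    Also accrues atrophy from the misfolded proportions before and after.
    """
    eng = engine or Engine(c, profiles, params, fc)
    s = state.copy()
    r_before = s.misfolded_proportion()
    s.N, s.M, s.N_edge, s.M_edge = eng.step_arrays(s.N, s.M, s.N_edge, s.M_edge, infect=True)
    s.L = s.L + eng.atrophy_delta(s.misfolded_proportion(), s.r_prev)
    s.r_prev = r_before
    s.t += 1
    s.check()
    return s


def atrophy_increment(
    r_now: np.ndarray,
    r_prev: np.ndarray,
    c: Connectome,
    k1: float = 0.5,
    k2: float = 0.5,
    dt: float = 0.01,
) -> np.ndarray:
    """Atrophy accrued in dt: direct toxicity plus deafferentation.

    ``dL_i = k1 (1 - e^{-r_i(t) dt})
    + k2 sum_j [w_ji / sum_j w_ji] (1 - e^{-r_j(t-1) dt})``.
    """
    r_now = np.asarray(r_now, dtype=float)
    r_prev = np.asarray(r_prev, dtype=float)
    for r in (r_now, r_prev):
        if ((r < 0) | (r > 1)).any():
            raise DynamicsError("misfolded proportions must lie in [0, 1]")
    if abs(k1 + k2 - 1.0) > 1e-12 or k1 < 0 or k2 < 0:
        raise DynamicsError("k1, k2 must be >= 0 with k1 + k2 = 1")
    colsum = c.weights.sum(axis=0, keepdims=True)
    deaff = np.divide(c.weights, colsum, out=np.zeros_like(c.weights), where=colsum > 0)
    return k1 * (1.0 - np.exp(-r_now * dt)) + k2 * ((1.0 - np.exp(-r_prev * dt)) @ deaff)


def simulate(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    equilibrium: Optional[SystemState] = None,
) -> Trajectory:
    """Full deterministic run: grow to equilibrium, seed, spread, accrue atrophy.

    ``equilibrium`` may be supplied to reuse a previously solved disease-free
    state (it is not mutated).  Deterministic given its inputs.
    """
    if params.seed_region is None:
        raise DynamicsError("params.seed_region must be set for simulate()")
    eng = Engine(c, profiles, params, fc)
    if equilibrium is None:
        equilibrium, _ = growth_to_equilibrium(c, profiles, params, fc, engine=eng)
    state = seed_infection(equilibrium, params.seed_region, params.seed_amount, c)
    n = c.n_regions
    stride = max(int(params.record_stride), 1)
    n_rec = params.max_steps // stride + 1
    times = np.empty(n_rec, dtype=int)
    recN = np.empty((n_rec, n))
    recM = np.empty((n_rec, n))
    recL = np.empty((n_rec, n))
    N, M, Ne, Me = state.N.copy(), state.M.copy(), state.N_edge.copy(), state.M_edge.copy()
    L = np.zeros(n)
    r_prev = np.zeros(n)
    k = 0
    times[k], recN[k], recM[k], recL[k] = 0, N, M, L
    for step in range(1, params.max_steps + 1):
        tot = N + M
        r_before = np.where(tot > 0, M / np.where(tot > 0, tot, 1.0), 0.0)
        N, M, Ne, Me = eng.step_arrays(N, M, Ne, Me, infect=True)
        tot = N + M
        r_now = np.where(tot > 0, M / np.where(tot > 0, tot, 1.0), 0.0)
        L = L + eng.atrophy_delta(r_now, r_prev)
        r_prev = r_before
        if step % stride == 0:
            k += 1
            times[k], recN[k], recM[k], recL[k] = step, N, M, L
    if not (np.isfinite(N).all() and np.isfinite(M).all()):
        raise DynamicsError("simulation produced non-finite populations")
    return Trajectory(
        times=times[: k + 1],
        N=recN[: k + 1],
        M=recM[: k + 1],
        density=recM[: k + 1] / c.sizes,
        atrophy=recL[: k + 1],
        region_names=list(c.region_names),
        meta={
            "seed_region": params.seed_region,
            "seed_amount": params.seed_amount,
            "dt": params.dt,
            "fc_k": params.fc_k,
            "update_mode": params.update_mode,
        },
    )


def simulate_stochastic(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    rng_seed: Optional[int] = None,
    n_replicates: int = 1,
    n_steps: Optional[int] = None,
    seed_disease: bool = True,
) -> tuple[Trajectory, np.ndarray]:
    """Integer-agent stochastic variant of :func:`simulate`.

    Synthesis is Poisson with mean alpha_i S_i dt, clearance and infection are
    binomial thinnings, mobility is multinomial; expected increments match the
    deterministic engine.  Runs ``n_replicates`` chains batched from an empty
    state for ``n_steps`` (default ``params.max_steps``); misfolded agents are
    injected at step 0 when ``seed_disease`` is set and a seed region is named.

    Returns the mean trajectory across replicates plus the final per-replicate
    regional N (shape ``(n_replicates, n)``), handy for moment checks.
    """
    rng = np.random.default_rng(params.rng_seed if rng_seed is None else rng_seed)
    eng = Engine(c, profiles, params, fc)
    n = c.n_regions
    B = int(n_replicates)
    steps = int(params.max_steps if n_steps is None else n_steps)
    N = np.zeros((B, n), dtype=np.int64)
    M = np.zeros((B, n), dtype=np.int64)
    Ne = np.zeros((B, n, n), dtype=np.int64)
    Me = np.zeros((B, n, n), dtype=np.int64)
    if seed_disease and params.seed_region is not None:
        amt = int(round(params.seed_amount))
        if amt <= 0:
            raise DynamicsError("stochastic seeding needs a positive integer amount")
        M[:, c.index_of(params.seed_region)] += amt
    stride = max(int(params.record_stride), 1)
    recs: list[tuple[int, np.ndarray, np.ndarray]] = [(0, N.mean(0), M.mean(0))]
    leave_p = np.clip(eng.leave_frac, 0.0, 1.0)
    exit_p = np.clip(eng.exit_frac, 0.0, 1.0)
    pvals = eng.share / np.maximum(eng.share.sum(axis=1, keepdims=True), 1e-300)
    has_edges = eng.share.sum(axis=1) > 0
    for step in range(1, steps + 1):
        for pop, epop in ((N, Ne), (M, Me)):
            leavers = rng.binomial(pop, leave_p)
            exits = rng.binomial(epop, exit_p)
            pop -= leavers
            pop += exits.sum(axis=1)
            epop -= exits
            for i in np.flatnonzero(has_edges):
                epop[:, i, :] += rng.multinomial(leavers[:, i], pvals[i])
        synth = rng.poisson(np.broadcast_to(eng.alphaS_dt, (B, n)))
        clearedN = rng.binomial(N, eng.clear_frac)
        clearedM = rng.binomial(M, eng.clear_frac)
        inf_frac = 1.0 - np.exp(-eng.gamma0_dt * M)
        infected = rng.binomial(N - clearedN, inf_frac)
        N = N + synth - clearedN - infected
        M = M - clearedM + infected
        if step % stride == 0:
            recs.append((step, N.mean(0), M.mean(0)))
    times = np.array([r[0] for r in recs])
    recN = np.stack([r[1] for r in recs])
    recM = np.stack([r[2] for r in recs])
    traj = Trajectory(
        times=times, N=recN, M=recM, density=recM / c.sizes,
        atrophy=np.zeros_like(recN), region_names=list(c.region_names),
        meta={"stochastic": True, "n_replicates": B, "rng_seed": params.rng_seed if rng_seed is None else rng_seed},
    )
    return traj, N.astype(float)
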