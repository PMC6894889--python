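"""Epicenter identification: spread thresholds and arrival times.

The spread threshold of a region is the minimal amount of misfolded protein
that, injected into the disease-free equilibrium there, triggers an outbreak
instead of extinction.  It plays the role the basic reproduction number R0
plays in classical well-mixed epidemic models, but here it can only be found
numerically: following the original procedure, amounts are scanned upward on
a fixed grid (start and step default to 1e-13 agents) until the disease no
longer extinguishes.  Because outbreak probability is monotone in the seeded
amount, a bracketing bisection over the same grid returns the identical
amount at a fraction of the cost; both are provided and must agree.

Operationally, "outbreak" means the total misfolded population is still
growing in the second half of a fixed observation window and has exceeded the
injected amount; near-threshold dynamics are slow, so a pure endpoint test
misclassifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .connectome import Connectome
from .dynamics import Engine, SimulationParams, SystemState, Trajectory, growth_to_equilibrium
from .profiles import RegionalProfiles


class EpicenterError(RuntimeError):
    pass


@dataclass
class ThresholdResult:
    """Per-region spread thresholds (agents) and their -log10 transform."""

    region_names: list[str]
    threshold: np.ndarray
    scan_step: float
    outbreak_horizon: int
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def neg_log10_threshold(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.threshold)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "threshold": self.threshold,
                "neg_log10": self.neg_log10_threshold,
            },
            index=pd.Index(self.region_names, name="region"),
        )
        df["rank"] = df["threshold"].rank(method="min").astype("Int64")
        return df


@dataclass
class ArrivalTimes:
    """Steps until each region's misfolded amount first exceeds the cutoff."""

    region_names: list[str]
    steps: np.ndarray  # float; np.inf where never reached
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"arrival_step": self.steps},
            index=pd.Index(self.region_names, name="region"),
        )


def _batched_outbreak(
    eng: Engine,
    equilibrium: SystemState,
    regions: np.ndarray,
    amounts: np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Outbreak flags for a batch of (seed region, amount) probes."""
    if horizon < 2:
        raise EpicenterError("outbreak horizon must be at least 2 steps")
    B = len(regions)
    n = equilibrium.N.shape[-1]
    N = np.broadcast_to(equilibrium.N, (B, n)).copy()
    Ne = np.broadcast_to(equilibrium.N_edge, (B, n, n)).copy()
    M = np.zeros((B, n))
    Me = np.zeros((B, n, n))
    M[np.arange(B), regions] = amounts
    half = horizon // 2
    tot_half = None
    for step in range(1, horizon + 1):
        N, M, Ne, Me = eng.step_arrays(N, M, Ne, Me, infect=True)
        if step == half:
            tot_half = M.sum(axis=1) + Me.sum(axis=(1, 2))
    tot_end = M.sum(axis=1) + Me.sum(axis=(1, 2))
    return (tot_end > tot_half) & (tot_end > amounts)


def is_outbreak(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    region: int | str,
    amount: float,
    fc: Optional[np.ndarray] = None,
    outbreak_horizon: int = 20_000,
    equilibrium: Optional[SystemState] = None,
    engine: Optional[Engine] = None,
) -> bool:
    """Does seeding ``amount`` misfolded agents at ``region`` start an epidemic?

    Simulates from the disease-free equilibrium for ``outbreak_horizon`` steps;
    outbreak iff total misfolded mass at the horizon exceeds both its value at
    the half-horizon and the seeded amount.
    """
    if amount <= 0:
        raise EpicenterError("seed amount must be > 0")
    idx = c.index_of(region) if isinstance(region, str) else int(region)
    eng = engine or Engine(c, profiles, params, fc)
    if equilibrium is None:
        equilibrium, _ = growth_to_equilibrium(c, profiles, params, fc, engine=eng)
    return bool(
        _batched_outbreak(eng, equilibrium, np.array([idx]), np.array([amount]), outbreak_horizon)[0]
    )


def spread_threshold(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    region: int | str,
    start: float = 1e-13,
    step: float = 1e-13,
    fc: Optional[np.ndarray] = None,
    outbreak_horizon: int = 20_000,
    method: str = "scan",
    max_amount: float = 1e-3,
    equilibrium: Optional[SystemState] = None,
    engine: Optional[Engine] = None,
) -> float:
    """Minimal seed amount on the grid {start, start+step, ...} that outbreaks.

    ``method='scan'`` is the literal linear scan; ``'bisect'`` brackets by
    doubling and bisects over the same grid, which by monotonicity of the
    outbreak indicator returns the identical amount.
    """
    if start <= 0 or step <= 0:
        raise EpicenterError("start and step must be > 0")
    if method not in ("scan", "bisect"):
        raise EpicenterError("method must be 'scan' or 'bisect'")
    idx = c.index_of(region) if isinstance(region, str) else int(region)
    eng = engine or Engine(c, profiles, params, fc)
    if equilibrium is None:
        equilibrium, _ = growth_to_equilibrium(c, profiles, params, fc, engine=eng)

    def probe(amount: float) -> bool:
        return bool(
            _batched_outbreak(eng, equilibrium, np.array([idx]), np.array([amount]), outbreak_horizon)[0]
        )

    if probe(start):
        raise EpicenterError(
            f"disease already spreads at the start amount {start:g}; lower it"
        )
    if method == "scan":
        amount = start
        while amount <= max_amount:
            amount += step
            if probe(amount):
                return amount
        raise EpicenterError(f"no outbreak up to max_amount {max_amount:g}")
    # bisect over multiples m: amount(m) = start + m * step, m >= 0
    lo, hi = 0, 1
    while not probe(start + hi * step):
        lo, hi = hi, hi * 2
        if start + hi * step > max_amount:
            raise EpicenterError(f"no outbreak up to max_amount {max_amount:g}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if probe(start + mid * step):
            hi = mid
        else:
            lo = mid
    return start + hi * step


def all_spread_thresholds(
    c: Connectome,
    profiles: RegionalProfiles,
    params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    start: float = 1e-13,
    step: float = 1e-13,
    outbreak_horizon: int = 20_000,
    max_amount: float = 1e-3,
) -> ThresholdResult:
    """Spread threshold for every region (batched bracketing bisection).

    All regions' probes advance together, so each bisection round costs a
    single batched simulation.  Per-region failures (no outbreak reachable,
    outbreak already at the start amount) are collected, not fatal; the
    affected entries are NaN.
    """
    n = c.n_regions
    eng = Engine(c, profiles, params, fc)
    equilibrium, _ = growth_to_equilibrium(c, profiles, params, fc, engine=eng)
    errors: dict[str, str] = {}
    thresholds = np.full(n, np.nan)

    regions = np.arange(n)
    at_start = _batched_outbreak(
        eng, equilibrium, regions, np.full(n, start), outbreak_horizon
    )
    for i in np.flatnonzero(at_start):
        errors[c.region_names[i]] = f"outbreak already at start amount {start:g}"
    active = ~at_start

    lo = np.zeros(n, dtype=np.int64)
    hi = np.ones(n, dtype=np.int64)
    bracketed = np.zeros(n, dtype=bool)
    # phase 1: geometric expansion until each region's hi amount outbreaks
    while True:
        probe_mask = active & ~bracketed
        if not probe_mask.any():
            break
        idxs = np.flatnonzero(probe_mask)
        amounts = start + hi[idxs] * step
        over = amounts > max_amount
        for i in idxs[over]:
            errors[c.region_names[i]] = f"no outbreak up to max_amount {max_amount:g}"
            active[i] = False
        idxs = idxs[~over]
        if idxs.size == 0:
            continue
        out = _batched_outbreak(eng, equilibrium, idxs, start + hi[idxs] * step, outbreak_horizon)
        bracketed[idxs[out]] = True
        grow = idxs[~out]
        lo[grow] = hi[grow]
        hi[grow] *= 2
    # phase 2: bisection on the shared grid
    while True:
        open_mask = active & bracketed & (hi - lo > 1)
        if not open_mask.any():
            break
        idxs = np.flatnonzero(open_mask)
        mid = (lo[idxs] + hi[idxs]) // 2
        out = _batched_outbreak(eng, equilibrium, idxs, start + mid * step, outbreak_horizon)
        hi[idxs[out]] = mid[out]
        lo[idxs[~out]] = mid[~out]
    done = active & bracketed
    thresholds[done] = start + hi[done] * step
    return ThresholdResult(
        region_names=list(c.region_names),
        threshold=thresholds,
        scan_step=step,
        outbreak_horizon=outbreak_horizon,
        errors=errors,
    )


def arrival_times(trajectory: Trajectory, cutoff: float = 1.0) -> ArrivalTimes:
    """First recorded step at which each region's misfolded amount > cutoff."""
    if trajectory.M.size == 0:
        raise EpicenterError("empty trajectory")
    exceeded = trajectory.M > cutoff
    first = np.argmax(exceeded, axis=0)
    never = ~exceeded.any(axis=0)
    steps = trajectory.times[first].astype(float)
    steps[never] = np.inf
    return ArrivalTimes(list(trajectory.region_names), steps, cutoff)
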