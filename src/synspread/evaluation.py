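"""Model-fit evaluation against a regional atrophy map.

The simulated marker (cumulative atrophy L, or misfolded density M/S) is
correlated with the empirical atrophy t-map at every recorded time, yielding
a fit curve whose peak summarizes the model.  Early frames, where the rank
correlation is unstable because misfolded density is still changing fast, are
masked out.  Null-model comparisons use add-one permutation p-values on the
peak fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Connectome, centrality_metrics
from .dynamics import SimulationParams, Trajectory, simulate
from .profiles import RegionalProfiles


class EvaluationError(ValueError):
    pass


@dataclass
class AtrophyMap:
    """Per-region atrophy scalar (t-statistic semantics).

    ``excluded_regions`` are dropped from every fit computation; the model's
    seed region is excluded by default downstream because its empirical
    atrophy estimate is unreliable at small structure sizes.
    """

    region_names: list[str]
    values: np.ndarray
    excluded_regions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_names),):
            raise EvaluationError("atrophy values must match region count")
        if not np.isfinite(self.values).all():
            raise EvaluationError("atrophy values must be finite")
        unknown = self.excluded_regions - set(self.region_names)
        if unknown:
            raise EvaluationError(f"excluded regions not in map: {sorted(unknown)}")


@dataclass
class FitCurve:
    """Correlation between simulated and empirical atrophy over time."""

    times: np.ndarray
    values: np.ndarray          # correlation per time; NaN where undefined
    method: str                 # 'spearman' | 'pearson'
    early_mask: np.ndarray      # True = discard (early frame or undefined)

    @property
    def peak(self) -> tuple[float, float]:
        return peak_fit(self)


def early_frame_mask(traj: Trajectory, rel_change: float = 0.01) -> np.ndarray:
    """True for frames where any region's misfolded density is still changing
    by more than ``rel_change`` relative between consecutive recordings."""
    d = traj.density
    if d.shape[0] < 2:
        raise EvaluationError("need at least 2 recorded frames")
    prev, now = d[:-1], d[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(now - prev) / np.where(prev != 0, np.abs(prev), 1.0)
        rel = np.where((prev == 0) & (now != 0), np.inf, rel)
    mask = np.zeros(d.shape[0], dtype=bool)
    mask[1:] = np.nanmax(rel, axis=1) > rel_change
    return mask


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan  # constant vector: correlation undefined, masked not fatal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            return float(stats.spearmanr(x, y).statistic)
        # both vectors z-scored first; leaves Pearson r unchanged but keeps
        # exported scatter data on a common scale
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        return float(stats.pearsonr(zx, zy).statistic)


def fit_curve(
    traj: Trajectory,
    atrophy: AtrophyMap,
    method: str = "spearman",
    predictor: str = "simulated_atrophy",
    rel_change: float = 0.01,
    exclude_seed: bool = True,
) -> FitCurve:
    """Correlate the chosen simulated marker with empirical atrophy per frame.

    ``predictor`` is ``'simulated_atrophy'`` (cumulative L) or
    ``'misfolded_density'`` (M_i / S_i).  Excluded regions (map exclusions
    plus, by default, the simulation's seed region) are dropped.
    """
    if method not in ("spearman", "pearson"):
        raise EvaluationError("method must be 'spearman' or 'pearson'")
    preds = {"simulated_atrophy": traj.atrophy, "misfolded_density": traj.density}
    if predictor not in preds:
        raise EvaluationError(f"predictor must be one of {sorted(preds)}")
    excluded = set(atrophy.excluded_regions)
    if exclude_seed and traj.meta.get("seed_region") is not None:
        excluded.add(traj.meta["seed_region"])
    common = [r for r in traj.region_names if r in set(atrophy.region_names) - excluded]
    if len(common) < 3:
        raise EvaluationError(f"only {len(common)} regions left after exclusions; need >= 3")
    ti = [traj.region_names.index(r) for r in common]
    ai = [atrophy.region_names.index(r) for r in common]
    X = preds[predictor][:, ti]
    y = atrophy.values[ai]
    values = np.array([_correlate(x, y, method) for x in X])
    mask = early_frame_mask(traj, rel_change) | ~np.isfinite(values)
    return FitCurve(times=traj.times.copy(), values=values, method=method, early_mask=mask)


def peak_fit(fc: FitCurve) -> tuple[float, float]:
    """(time, value) of the maximum fit over unmasked frames; earliest on ties."""
    ok = ~fc.early_mask & np.isfinite(fc.values)
    if not ok.any():
        raise EvaluationError("all frames are masked; no peak fit")
    vals = np.where(ok, fc.values, -np.inf)
    best = int(np.argmax(vals))  # argmax returns the earliest maximizer
    return float(fc.times[best]), float(fc.values[best])


def permutation_pvalue(real_fit: float, null_fits: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= real}) / (n_null + 1)."""
    null_fits = np.asarray(null_fits, dtype=float)
    if null_fits.size == 0:
        raise EvaluationError("need at least one null value")
    return float((1 + np.sum(null_fits >= real_fit)) / (null_fits.size + 1))


def static_predictor_fits(
    c: Connectome,
    profiles: RegionalProfiles,
    atrophy: AtrophyMap,
    exclude_seed_region: Optional[str] = None,
) -> pd.DataFrame:
    """Correlation of atrophy with static network and expression predictors.

    Rows: degree, strength, eigenvector centrality, SNCA z, GBA z.
    Columns: spearman, pearson.  Constant predictors yield NaN.
    """
    metrics = centrality_metrics(c)
    excluded = set(atrophy.excluded_regions)
    if exclude_seed_region:
        excluded.add(exclude_seed_region)
    common = [r for r in c.region_names if r in set(atrophy.region_names) - excluded]
    if len(common) < 3:
        raise EvaluationError("need at least 3 aligned regions")
    ci = [c.region_names.index(r) for r in common]
    ai = [atrophy.region_names.index(r) for r in common]
    y = atrophy.values[ai]
    predictors = {
        "degree": metrics["degree"].to_numpy()[ci].astype(float),
        "strength": metrics["strength"].to_numpy()[ci],
        "eigenvector": metrics["eigenvector"].to_numpy()[ci],
        "snca_z": profiles.snca_z[ci],
        "gba_z": profiles.gba_z[ci],
    }
    rows = {
        name: {
            "spearman": _correlate(x, y, "spearman"),
            "pearson": _correlate(x, y, "pearson"),
        }
        for name, x in predictors.items()
    }
    return pd.DataFrame(rows).T.rename_axis("predictor")


def parameter_sweep(
    c: Connectome,
    profiles: RegionalProfiles,
    atrophy: AtrophyMap,
    grid: dict[str, list],
    base_params: SimulationParams,
    fc: Optional[np.ndarray] = None,
    method: str = "spearman",
    predictor: str = "simulated_atrophy",
    previous: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run simulate + fit_curve over a parameter grid; long-format results.

    Grid keys: ``rho``, ``k1`` (k2 follows as 1 - k1), ``fc_k``, ``v``, and
    ``transform`` (rate transform name).  Per-point failures are recorded in
    the ``error`` column and the sweep continues.  Pass a ``previous`` result
    frame to resume: already-computed points are carried over, not re-run.
    """
    allowed = {"rho", "k1", "fc_k", "v", "transform"}
    bad = set(grid) - allowed
    if bad:
        raise EvaluationError(f"unsupported sweep parameters: {sorted(bad)}")
    keys = sorted(grid)
    done: dict[tuple, dict] = {}
    if previous is not None:
        for _, row in previous.iterrows():
            done[tuple(row[k] for k in keys)] = row.to_dict()
    records = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        if combo in done:
            records.append(done[combo])
            continue
        rec = dict(point)
        try:
            prof = profiles.with_transform(point["transform"]) if "transform" in point else profiles
            changes = {k: v for k, v in point.items() if k in ("rho", "fc_k", "v")}
            if "k1" in point:
                changes["k1"] = point["k1"]
                changes["k2"] = 1.0 - point["k1"]
            params = base_params.replace(**changes)
            traj = simulate(c, prof, params, fc)
            t_peak, v_peak = peak_fit(fit_curve(traj, atrophy, method, predictor))
            rec.update(peak_time=t_peak, peak_fit=v_peak, error="")
        except Exception as err:  # noqa: BLE001 - sweep must survive bad points
            rec.update(peak_time=np.nan, peak_fit=np.nan, error=str(err))
        records.append(rec)
    return pd.DataFrame.from_records(records)
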