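"""Synthetic inputs with the statistical structure the model assumes.

Real inputs (a tractography consensus connectome, microarray expression
z-scores, resting-state FC, a patient atrophy t-map) are heavy and access
restricted; these generators emulate their relevant structure so every stage
of the pipeline can be exercised and validated end to end:

* a geometric random network — edge probability decays with euclidean
  distance, weights are distance-modulated log-normal, fiber lengths are
  slightly distorted euclidean distances;
* per-region standard-normal gene z-scores with an optional expression
  hotspot;
* structure-coupled functional connectivity and matching AR(1) time series;
* a ground-truth atrophy map forward-simulated from a known seed region with
  additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .connectome import Connectome, SubjectStack
from .dynamics import SimulationParams, Trajectory, simulate
from .evaluation import AtrophyMap
from .profiles import RegionalProfiles, zscore


class SynthesisError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    """Generator settings (defaults mirror the 42-region study setup)."""

    n_regions: int = 42
    target_density: float = 0.35
    box_size: float = 60.0          # mm; single-hemisphere spatial scale
    distance_decay: float = 20.0    # mm; edge-probability decay scale
    weight_sigma: float = 0.5       # log-normal weight dispersion
    length_distortion: tuple[float, float] = (1.0, 1.3)  # fiber-length inflation over euclidean
    mean_size: float = 200.0        # voxels per region
    size_sigma: float = 0.0         # log-normal size dispersion (0 = uniform sizes)
    hotspot_region: Optional[int] = None
    hotspot_boost: float = 0.0      # added to the SNCA z-score before restandardizing
    fc_coupling: float = 0.7
    fc_noise: float = 0.3
    rng_seed: int = 0

    def replace(self, **changes) -> "SyntheticSpec":
        return replace(self, **changes)


def _rng(spec_or_seed) -> np.random.Generator:
    if isinstance(spec_or_seed, np.random.Generator):
        return spec_or_seed
    if isinstance(spec_or_seed, SyntheticSpec):
        return np.random.default_rng(spec_or_seed.rng_seed)
    return np.random.default_rng(spec_or_seed)


def generate_connectome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Connectome:
    """Geometric weighted network at the requested binary density.

    Coordinates are uniform in a cube; the minimum-spanning tree over
    euclidean distance is always kept (connectivity), and the remaining edges
    are the highest-scoring pairs under a distance-decaying random score, so
    the final density matches the target within one edge.
    """
    rng = _rng(rng if rng is not None else spec)
    n = spec.n_regions
    if n < 2:
        raise SynthesisError("need at least 2 regions")
    n_possible = n * (n - 1) // 2
    m = int(round(spec.target_density * n_possible))
    if m < n - 1:
        raise SynthesisError(
            f"density {spec.target_density} gives {m} edges; "
            f"{n - 1} needed to connect {n} regions"
        )
    coords = rng.uniform(0.0, spec.box_size, size=(n, 3))
    dist = squareform(pdist(coords))
    decay = np.exp(-dist / spec.distance_decay)
    score = decay * rng.uniform(0.0, 1.0, size=(n, n))
    score = np.triu(score, k=1)

    mst = minimum_spanning_tree(dist).toarray() > 0
    mst = np.triu(mst | mst.T, k=1)
    forced_i, forced_j = np.nonzero(mst)
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(-score[iu, ju])
    keep = np.zeros((n, n), dtype=bool)
    keep[forced_i, forced_j] = True
    for k in order:
        if keep.sum() >= m:
            break
        keep[iu[k], ju[k]] = True

    weights = np.zeros((n, n))
    ki, kj = np.nonzero(keep)
    weights[ki, kj] = decay[ki, kj] * rng.lognormal(0.0, spec.weight_sigma, size=len(ki))
    weights = weights + weights.T

    lo, hi = spec.length_distortion
    lengths = np.zeros((n, n))
    lengths[ki, kj] = np.maximum(dist[ki, kj] * rng.uniform(lo, hi, size=len(ki)), 1.0)
    lengths = lengths + lengths.T

    sizes = np.maximum(
        np.round(rng.lognormal(np.log(spec.mean_size), spec.size_sigma, size=n)), 1
    ).astype(int)
    names = [f"region_{i:02d}" for i in range(n)]
    return Connectome(names, weights, lengths, sizes, coords)


def generate_profiles(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> RegionalProfiles:
    """Independent standard-normal z-scores per gene; optional SNCA hotspot
    (boost added, then the vector is restandardized)."""
    rng = _rng(rng if rng is not None else spec)
    n = spec.n_regions
    snca = rng.standard_normal(n)
    gba = rng.standard_normal(n)
    if spec.hotspot_region is not None and spec.hotspot_boost:
        snca[spec.hotspot_region] += spec.hotspot_boost
        snca = zscore(snca)
    names = [f"region_{i:02d}" for i in range(n)]
    return RegionalProfiles(names, snca, gba)


def generate_subject_stack(
    consensus: Connectome,
    n_subjects: int,
    dropout_prob: float = 0.2,
    weight_noise: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> SubjectStack:
    """Per-subject matrices: weak edges drop out more often, kept weights are
    jittered multiplicatively (log-normal)."""
    rng = _rng(rng)
    n = consensus.n_regions
    iu, ju = np.nonzero(np.triu(consensus.edge_mask, k=1))
    w = consensus.weights[iu, ju]
    # rank fraction in (0, 1]: 1 for the weakest edge -> most likely to drop
    rank_frac = (np.argsort(np.argsort(-w)) + 1) / len(w)
    keep_p = 1.0 - dropout_prob * rank_frac
    mats, lens = [], []
    for _ in range(n_subjects):
        kept = rng.uniform(size=len(w)) < keep_p
        jitter = rng.lognormal(0.0, weight_noise, size=len(w))
        W = np.zeros((n, n))
        L = np.zeros((n, n))
        W[iu[kept], ju[kept]] = w[kept] * jitter[kept]
        L[iu[kept], ju[kept]] = consensus.lengths[iu[kept], ju[kept]] * rng.lognormal(
            0.0, 0.05, size=kept.sum()
        )
        mats.append(W + W.T)
        lens.append(np.maximum(L + L.T, np.where((L + L.T) > 0, 1.0, 0.0)))
    return SubjectStack(mats, lens, list(consensus.region_names))


def generate_fc(
    c: Connectome,
    coupling: float = 0.7,
    noise: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Structure-coupled FC: blend of symmetrized row-normalized weights and
    symmetric Gaussian noise; unit diagonal, negatives zeroed, capped at 1."""
    if not 0 <= coupling <= 1:
        raise SynthesisError("coupling must lie in [0, 1]")
    rng = _rng(rng)
    n = c.n_regions
    rowsum = c.weights.sum(axis=1, keepdims=True)
    Wn = np.divide(c.weights, rowsum, out=np.zeros_like(c.weights), where=rowsum > 0)
    S = (Wn + Wn.T) / 2
    R = rng.normal(0.0, noise, size=(n, n))
    R = (R + R.T) / 2
    fc = coupling * S + (1.0 - coupling) * R
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, 0.0, 1.0)


def generate_timeseries(
    c: Connectome,
    n_timepoints: int = 200,
    coupling: float = 0.7,
    ar_coef: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """AR(1) regional time series with structure-coupled innovations
    (T x n); feeds the series mode of the FC null."""
    if n_timepoints < 2:
        raise SynthesisError("need at least 2 time points")
    rng = _rng(rng)
    n = c.n_regions
    rowsum = c.weights.sum(axis=1, keepdims=True)
    Wn = np.divide(c.weights, rowsum, out=np.zeros_like(c.weights), where=rowsum > 0)
    B = coupling * (Wn + Wn.T) / 2 + np.eye(n)
    cov = B @ B.T
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d) + 1e-9 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    x = np.zeros((n_timepoints, n))
    innov = rng.standard_normal((n_timepoints, n)) @ chol.T
    for t in range(1, n_timepoints):
        x[t] = ar_coef * x[t - 1] + innov[t]
    return x


def generate_atrophy(
    c: Connectome,
    profiles: RegionalProfiles,
    seed_region: str | int,
    t_obs: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    params: SimulationParams | None = None,
    fc: Optional[np.ndarray] = None,
    return_trajectory: bool = False,
) -> AtrophyMap | tuple[AtrophyMap, Trajectory]:
    """Forward-simulated ground-truth atrophy observed at step ``t_obs``.

    Runs the full model seeded at ``seed_region``, takes cumulative atrophy at
    ``t_obs``, z-scores it across regions and adds Gaussian noise of SD
    ``noise_sd`` (in z units).
    """
    rng = _rng(rng)
    name = c.region_names[seed_region] if isinstance(seed_region, (int, np.integer)) else seed_region
    if params is None:
        params = SimulationParams(seed_region=name, seed_amount=1.0, max_steps=t_obs)
    if params.max_steps < t_obs:
        raise SynthesisError("t_obs exceeds the simulation horizon")
    traj = simulate(c, profiles, params, fc)
    k = int(np.searchsorted(traj.times, t_obs))
    k = min(k, len(traj.times) - 1)
    if traj.M[k].sum() < params.seed_amount:
        raise SynthesisError(
            "misfolded population extinct before t_obs; seed a larger amount"
        )
    values = zscore(traj.atrophy[k]) + rng.normal(0.0, noise_sd, size=c.n_regions)
    amap = AtrophyMap(list(c.region_names), values)
    return (amap, traj) if return_trajectory else amap


def generate_bundle(spec: SyntheticSpec) -> dict:
    """Convenience: one coherent input set (connectome, profiles, FC)."""
    rng = _rng(spec)
    c = generate_connectome(spec, rng)
    profiles = generate_profiles(spec, rng)
    fc = generate_fc(c, spec.fc_coupling, spec.fc_noise, rng)
    return {"connectome": c, "profiles": profiles, "fc": fc}
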