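"""Control conditions: rewired and spatial network nulls, gene and FC nulls.

Each null destroys exactly one ingredient of the model while preserving the
rest: degree-preserving rewiring scrambles topology, node-position permutation
scrambles spatial embedding, gene shuffles scramble regional vulnerability,
and FC permutation scrambles coactivation structure.  Fiber lengths for edges
that do not exist in the empirical network are imputed from a linear
regression of length on inter-region euclidean distance fitted on the
empirical edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .connectome import Connectome, ConnectomeError, median_intervoxel_distance


class NullModelError(RuntimeError):
    pass


@dataclass
class NullEnsemble:
    kind: str  # rewired | spatial | gene_shuffle | gene_uniform | fc_null
    realizations: list
    rng_seed: int
    n_realizations: int


def _edge_distances(
    c: Connectome,
    pairs: np.ndarray,
    voxel_sets: list[np.ndarray] | None = None,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Inter-region distances for (i, j) pairs: median intervoxel distance if
    voxel sets are available, else centroid euclidean distance."""
    if voxel_sets is not None:
        return np.array(
            [median_intervoxel_distance(voxel_sets[i], voxel_sets[j]) for i, j in pairs]
        )
    xyz = c.coords if coords is None else coords
    return np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)


def fit_length_model(
    c: Connectome,
    voxel_sets: list[np.ndarray] | None = None,
) -> tuple[float, float]:
    """OLS of fiber length on inter-region distance over existing edges.

    Returns (intercept, slope) of y = w0 + w1 x.
    """
    iu, ju = np.nonzero(np.triu(c.edge_mask, k=1))
    if len(iu) < 2:
        raise NullModelError("need at least 2 existing edges to fit the length model")
    pairs = np.column_stack([iu, ju])
    x = _edge_distances(c, pairs, voxel_sets)
    y = c.lengths[iu, ju]
    if np.ptp(x) == 0:
        raise NullModelError("degenerate fit: all inter-region distances are equal")
    res = linregress(x, y)
    return float(res.intercept), float(res.slope)


def interpolate_lengths(
    c: Connectome,
    new_edges: np.ndarray,
    voxel_sets: list[np.ndarray] | None = None,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted fiber lengths for absent edges, clamped to >= 1 mm."""
    new_edges = np.atleast_2d(np.asarray(new_edges, dtype=int))
    w0, w1 = fit_length_model(c, voxel_sets)
    d = _edge_distances(c, new_edges, voxel_sets, coords)
    return np.maximum(w0 + w1 * d, 1.0)


def rewire_degree_preserving(
    c: Connectome,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
    voxel_sets: list[np.ndarray] | None = None,
    max_connect_retries: int = 20,
) -> Connectome:
    """Maslov-Sneppen rewiring: swap edge pairs, preserving degree sequence
    and density; weights travel with the swapped edges.  Lengths of edges not
    present in the original network are imputed from the fitted
    distance-length regression.  Disconnected outcomes are resampled.
    """
    if not c.is_connected():
        raise NullModelError("rewiring requires a connected network")
    rng = np.random.default_rng(rng)
    w0, w1 = fit_length_model(c, voxel_sets)
    n = c.n_regions
    orig_mask = c.edge_mask

    for _ in range(max_connect_retries):
        W = c.weights.copy()
        iu, ju = np.nonzero(np.triu(W, k=1))
        edges = list(zip(iu.tolist(), ju.tolist()))
        n_edges = len(edges)
        attempts = n_swaps_per_edge * n_edges
        for _ in range(attempts):
            e1, e2 = rng.integers(0, n_edges, size=2)
            if e1 == e2:
                continue
            a, b = edges[e1]
            cc, d = edges[e2]
            if rng.random() < 0.5:
                cc, d = d, cc
            # propose (a, d) and (cc, b)
            if len({a, b, cc, d}) < 4:
                continue
            if W[a, d] > 0 or W[cc, b] > 0:
                continue
            wab, wcd = W[a, b], W[cc, d]
            W[a, b] = W[b, a] = 0.0
            W[cc, d] = W[d, cc] = 0.0
            W[a, d] = W[d, a] = wab
            W[cc, b] = W[b, cc] = wcd
            edges[e1] = tuple(sorted((a, d)))
            edges[e2] = tuple(sorted((cc, b)))
        n_comp, _ = connected_components(W > 0, directed=False)
        if n_comp == 1:
            break
    else:
        raise NullModelError(
            f"could not retain connectivity in {max_connect_retries} rewiring attempts"
        )

    mask = W > 0
    L = np.where(mask & orig_mask, c.lengths, 0.0)
    new_i, new_j = np.nonzero(np.triu(mask & ~orig_mask, k=1))
    if len(new_i):
        pred = interpolate_lengths(c, np.column_stack([new_i, new_j]), voxel_sets)
        L[new_i, new_j] = pred
        L[new_j, new_i] = pred
    return c.with_(weights=W, lengths=L)


def spatial_null(
    c: Connectome,
    rng: np.random.Generator | int | None = None,
    mode: str = "regress",
    voxel_sets: list[np.ndarray] | None = None,
    perm: np.ndarray | None = None,
) -> Connectome:
    """Permute node positions while keeping every connection profile.

    ``mode='regress'`` (default) recomputes every edge length from the
    permuted geometry through the distance-length regression fitted on the
    original network; ``mode='carry'`` leaves the length matrix attached to
    the node pairs (lengths travel with the nodes).  ``perm`` overrides the
    random position assignment (region i moves to ``coords[perm[i]]``).
    """
    if mode not in ("regress", "carry"):
        raise NullModelError("mode must be 'regress' or 'carry'")
    if perm is None:
        rng = np.random.default_rng(rng)
        perm = rng.permutation(c.n_regions)
    else:
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(c.n_regions)):
            raise NullModelError("perm must be a permutation of the region indices")
    coords = c.coords[perm]  # region sizes and rates stay put: only geometry moves
    if mode == "carry":
        return c.with_(coords=coords)
    w0, w1 = fit_length_model(c, voxel_sets)
    iu, ju = np.nonzero(np.triu(c.edge_mask, k=1))
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    L = np.zeros_like(c.lengths)
    pred = np.maximum(w0 + w1 * d, 1.0)
    L[iu, ju] = pred
    L[ju, iu] = pred
    return c.with_(coords=coords, lengths=L)


def shuffle_profile(z: np.ndarray, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniform random permutation of a regional expression vector."""
    rng = np.random.default_rng(rng)
    z = np.asarray(z, dtype=float)
    return z[rng.permutation(len(z))]


def uniform_profile(z: np.ndarray) -> np.ndarray:
    """Constant vector at the mean expression score (downstream rate =
    transform(mean) everywhere)."""
    z = np.asarray(z, dtype=float)
    return np.full_like(z, z.mean())


def null_fc(
    series_or_fc: np.ndarray,
    rng: np.random.Generator | int | None = None,
    mode: str | None = None,
) -> np.ndarray:
    """Null functional connectivity.

    With regional time series (T x n, ``mode='series'``): randomly reassign
    the series to regions, recompute the Pearson correlation matrix and zero
    negatives.  With an FC matrix (n x n, ``mode='matrix'``): apply one
    symmetric row/column permutation.  Mode is inferred from squareness when
    not given.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(series_or_fc, dtype=float)
    if a.ndim != 2:
        raise NullModelError("expected a 2D array")
    if mode is None:
        mode = "matrix" if a.shape[0] == a.shape[1] else "series"
    if mode == "series":
        if a.shape[0] < 2:
            raise NullModelError("need at least 2 time points")
        perm = rng.permutation(a.shape[1])
        fc = np.corrcoef(a[:, perm], rowvar=False)
        np.fill_diagonal(fc, 1.0)
        return np.clip(fc, 0.0, None)
    perm = rng.permutation(a.shape[0])
    return a[np.ix_(perm, perm)]


def make_ensemble(
    kind: str,
    n_realizations: int,
    rng_seed: int,
    c: Connectome | None = None,
    z: np.ndarray | None = None,
    fc_input: np.ndarray | None = None,
    **kwargs,
) -> NullEnsemble:
    """Generate a reproducible ensemble of null substrates or profiles."""
    rng = np.random.default_rng(rng_seed)
    gens = {
        "rewired": lambda: rewire_degree_preserving(c, rng=rng, **kwargs),
        "spatial": lambda: spatial_null(c, rng=rng, **kwargs),
        "gene_shuffle": lambda: shuffle_profile(z, rng=rng),
        "gene_uniform": lambda: uniform_profile(z),
        "fc_null": lambda: null_fc(fc_input, rng=rng, **kwargs),
    }
    if kind not in gens:
        raise NullModelError(f"unknown null kind {kind!r}; choose from {sorted(gens)}")
    if kind in ("rewired", "spatial") and c is None:
        raise NullModelError(f"{kind} null needs a Connectome")
    if kind in ("gene_shuffle", "gene_uniform") and z is None:
        raise NullModelError(f"{kind} null needs an expression vector")
    if kind == "fc_null" and fc_input is None:
        raise NullModelError("fc_null needs time series or an FC matrix")
    reals = [gens[kind]() for _ in range(n_realizations)]
    return NullEnsemble(kind, reals, rng_seed, n_realizations)
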