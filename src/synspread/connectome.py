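"""Structural network substrate: consensus construction, validation, metrics.

The spreading model runs on a weighted, undirected structural connectome.
Each region carries a size (voxel count) and a 3D position; each edge carries
a connection weight (fiber-tract density, arbitrary units) and a mean fiber
length in millimetres.  The length enters the dynamics through the per-unit-time
edge-exit probability 1/l_ij, so lengths are clamped to >= 1 to keep that a
valid probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist


class ConnectomeError(ValueError):
    """Raised when a network violates the substrate invariants."""


@dataclass
class Connectome:
    """Weighted symmetric structural network with geometry.

    Parameters
    ----------
    region_names
        Region identifiers, length ``n_regions``.
    weights
        ``(n, n)`` nonnegative symmetric matrix of connection weights
        (fiber-tract density); zero diagonal.
    lengths
        ``(n, n)`` matrix of mean fiber lengths (mm), defined (>= 1) wherever
        ``weights > 0``.
    sizes
        Per-region voxel counts ``S_i`` (positive integers).
    coords
        ``(n, 3)`` region centroid coordinates (mm).
    """

    region_names: list[str]
    weights: np.ndarray
    lengths: np.ndarray
    sizes: np.ndarray
    coords: np.ndarray
    allow_isolated: bool = False  # toy/consensus networks may leave regions edgeless

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.sizes = np.asarray(self.sizes)
        self.coords = np.asarray(self.coords, dtype=float)
        self.region_names = list(self.region_names)
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean ``(n, n)`` mask of positive-weight edges."""
        return self.weights > 0

    def validate(self) -> None:
        n = self.n_regions
        w, l = self.weights, self.lengths
        if w.shape != (n, n) or l.shape != (n, n):
            raise ConnectomeError(
                f"weights/lengths must be ({n}, {n}); got {w.shape} and {l.shape}"
            )
        if self.coords.shape != (n, 3):
            raise ConnectomeError(f"coords must be ({n}, 3); got {self.coords.shape}")
        if self.sizes.shape != (n,):
            raise ConnectomeError(f"sizes must be ({n},); got {self.sizes.shape}")
        if not np.isfinite(w).all():
            raise ConnectomeError("weights contain non-finite entries")
        if (w < 0).any():
            raise ConnectomeError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ConnectomeError("weights must be symmetric")
        if np.diag(w).any():
            raise ConnectomeError("weights must have a zero diagonal")
        mask = w > 0
        if not np.allclose(np.where(mask, l, 0.0), np.where(mask, l.T, 0.0)):
            raise ConnectomeError("lengths must be symmetric on the edge set")
        if (l[mask] < 1).any():
            raise ConnectomeError("lengths must be >= 1 mm wherever weights > 0")
        if (self.sizes < 1).any():
            raise ConnectomeError("region sizes must be >= 1 voxel")
        if n > 1 and not self.allow_isolated and (~mask.any(axis=1)).any():
            isolated = [self.region_names[i] for i in np.flatnonzero(~mask.any(axis=1))]
            raise ConnectomeError(f"regions without any edge: {isolated}")

    def is_connected(self) -> bool:
        if self.n_regions == 1:
            return True
        n_comp, _ = connected_components(self.edge_mask, directed=False)
        return n_comp == 1

    def index_of(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise KeyError(f"unknown region: {region!r}") from None

    def with_(self, **changes) -> "Connectome":
        """Return a copy with fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass
class SubjectStack:
    """Per-subject connectivity and streamline-length matrices."""

    matrices: list[np.ndarray]
    lengths: list[np.ndarray]
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ConnectomeError("subject stack is empty")
        if len(self.matrices) != len(self.lengths):
            raise ConnectomeError("matrices and lengths must pair up per subject")
        shape = np.asarray(self.matrices[0]).shape
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        self.lengths = [np.asarray(m, dtype=float) for m in self.lengths]
        for m in self.matrices + self.lengths:
            if m.shape != shape:
                raise ConnectomeError("all subject matrices must share one shape")
        if any((m < 0).any() for m in self.matrices):
            raise ConnectomeError("subject connectivity entries must be >= 0")
        if not self.region_names:
            self.region_names = [f"region_{i}" for i in range(shape[0])]

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)


def binary_density(weights: np.ndarray) -> float:
    """Fraction of possible undirected edges that are present.

    Counts nonzero off-diagonal upper-triangle entries over n(n-1)/2.
    """
    w = np.asarray(weights)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"expected a square matrix, got shape {w.shape}")
    n = w.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(w[iu]) / (n * (n - 1) / 2))


def build_consensus(
    stack: SubjectStack,
    target_density: float,
    *,
    sizes: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    weight_mode: str = "all",
    length_mode: str = "present",
) -> Connectome:
    """Group-consensus network from a stack of per-subject matrices.

    Edges are ranked by how many subjects possess them (ties broken by mean
    weight, then lexicographic index) and the top edges are kept so the binary
    density matches ``target_density`` within one edge.  Kept weights are
    averaged over all subjects by default (``weight_mode='all'``; zeros counted
    for subjects lacking the edge) or over possessing subjects only
    (``'present'``).  Lengths average over possessing subjects by default.

    ``sizes``/``coords`` default to unit sizes and zero coordinates, which is
    sufficient when only topology is needed.
    """
    if not 0 < target_density <= 1:
        raise ConnectomeError("target_density must be in (0, 1]")
    if weight_mode not in ("all", "present") or length_mode not in ("all", "present"):
        raise ConnectomeError("weight_mode/length_mode must be 'all' or 'present'")
    n = stack.matrices[0].shape[0]
    W = np.stack(stack.matrices)  # (s, n, n)
    L = np.stack(stack.lengths)
    present = W > 0
    counts = present.sum(axis=0)
    counts = np.maximum(counts, counts.T)  # occurrence of undirected edge
    mean_all = W.mean(axis=0)
    mean_all = (mean_all + mean_all.T) / 2

    iu, ju = np.triu_indices(n, k=1)
    candidate = counts[iu, ju] > 0
    n_possible = len(iu)
    n_target = int(round(target_density * n_possible))
    n_available = int(candidate.sum())
    if n_target > n_available:
        raise ConnectomeError(
            f"target density {target_density:.3f} not achievable: only "
            f"{n_available} edges occur in any subject "
            f"(max achievable density {n_available / n_possible:.3f})"
        )
    # rank: occurrence desc, mean weight desc, then (i, j) lexicographic
    order = np.lexsort((ju, iu, -mean_all[iu, ju], -counts[iu, ju]))
    keep = order[:n_target]

    weights = np.zeros((n, n))
    lengths = np.zeros((n, n))
    with np.errstate(invalid="ignore"):
        w_present = np.where(present.any(axis=0), W.sum(axis=0) / np.maximum(present.sum(axis=0), 1), 0.0)
        l_present = np.where(present.any(axis=0), (L * present).sum(axis=0) / np.maximum(present.sum(axis=0), 1), 0.0)
    w_src = mean_all if weight_mode == "all" else np.maximum(w_present, w_present.T)
    l_all = L.mean(axis=0)
    l_src = (l_all + l_all.T) / 2 if length_mode == "all" else np.maximum(l_present, l_present.T)
    ki, kj = iu[keep], ju[keep]
    weights[ki, kj] = w_src[ki, kj]
    weights[kj, ki] = w_src[ki, kj]
    lengths[ki, kj] = np.maximum(l_src[ki, kj], 1.0)  # clamp degenerate short edges
    lengths[kj, ki] = lengths[ki, kj]
    np.fill_diagonal(weights, 0.0)

    return Connectome(
        region_names=stack.region_names,
        weights=weights,
        lengths=lengths,
        sizes=np.ones(n, dtype=int) if sizes is None else np.asarray(sizes),
        coords=np.zeros((n, 3)) if coords is None else np.asarray(coords, dtype=float),
        allow_isolated=True,  # very sparse targets can leave regions edgeless
    )


def centrality_metrics(c: Connectome) -> pd.DataFrame:
    """Degree, strength, and eigenvector centrality per region.

    Eigenvector centrality is the principal eigenvector of the weight matrix
    (unit norm, nonnegative); it is only well defined on a connected network.
    """
    if not c.is_connected():
        raise ConnectomeError("eigenvector centrality is ill-defined on a disconnected network")
    w = c.weights
    degree = c.edge_mask.sum(axis=1)
    strength = w.sum(axis=1)
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)  # Perron vector of a connected nonnegative matrix
    v = v / np.linalg.norm(v)
    return pd.DataFrame(
        {"degree": degree, "strength": strength, "eigenvector": v},
        index=pd.Index(c.region_names, name="region"),
    )


def median_intervoxel_distance(voxels_a: np.ndarray, voxels_b: np.ndarray) -> float:
    """Median euclidean distance over all cross pairs of two voxel sets (mm)."""
    a = np.atleast_2d(np.asarray(voxels_a, dtype=float))
    b = np.atleast_2d(np.asarray(voxels_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ConnectomeError("voxel sets must be nonempty")
    return float(np.median(cdist(a, b)))


def warn_if_sparse(c: Connectome, min_density: float = 0.05) -> None:
    if binary_density(c.weights) < min_density:
        warnings.warn("connectome is very sparse; dynamics may be slow to mix", stacklevel=2)
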