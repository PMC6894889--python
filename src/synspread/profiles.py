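"""Per-region gene expression -> synthesis and clearance rates.

Regional SNCA expression sets the alpha-synuclein synthesis rate alpha_i and
regional GBA expression (the lysosomal clearance enzyme) sets the clearance
rate beta_i.  Expression z-scores are mapped into (0, 1) by a strictly
increasing transform, the standard normal CDF by default; alternatives
(logistic, scaled arctan) preserve the rank order of rates, which is what the
dynamics are sensitive to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

# Registry of monotone maps R -> (0, 1) usable as rate transforms.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "normal_cdf": lambda z: ndtr(np.asarray(z, dtype=float)),
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float))),
    "arctan": lambda z: 0.5 + np.arctan(np.asarray(z, dtype=float)) / np.pi,
}


class ExpressionError(ValueError):
    """Raised on malformed expression input."""


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize across regions (sample SD by default)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ExpressionError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def rates_from_zscores(z: np.ndarray, transform: str | Callable = "normal_cdf") -> np.ndarray:
    """Map per-region z-scores to rates in (0, 1) via a monotone transform."""
    f = TRANSFORMS[transform] if isinstance(transform, str) else transform
    rates = np.asarray(f(np.asarray(z, dtype=float)), dtype=float)
    if not ((rates > 0) & (rates < 1)).all():
        raise ExpressionError("transform must return values strictly inside (0, 1)")
    return rates


@dataclass
class RegionalProfiles:
    """Per-region expression z-scores and the derived kinetic rates.

    ``snca_z`` drives synthesis, ``gba_z`` drives clearance; both mapped
    through ``transform`` into (0, 1).
    """

    region_names: list[str]
    snca_z: np.ndarray
    gba_z: np.ndarray
    transform: str = "normal_cdf"
    _rates: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.snca_z = np.asarray(self.snca_z, dtype=float)
        self.gba_z = np.asarray(self.gba_z, dtype=float)
        n = len(self.region_names)
        if self.snca_z.shape != (n,) or self.gba_z.shape != (n,):
            raise ExpressionError("z-score vectors must match region count")
        if not (np.isfinite(self.snca_z).all() and np.isfinite(self.gba_z).all()):
            raise ExpressionError("z-scores must be finite")

    @property
    def synthesis_rate(self) -> np.ndarray:
        """alpha_i in (0, 1): new-agent probability per voxel per unit time."""
        return rates_from_zscores(self.snca_z, self.transform)

    @property
    def clearance_rate(self) -> np.ndarray:
        """beta_i in (0, 1): degradation probability per agent per unit time."""
        return rates_from_zscores(self.gba_z, self.transform)

    def with_transform(self, transform: str) -> "RegionalProfiles":
        return RegionalProfiles(self.region_names, self.snca_z, self.gba_z, transform)


def aggregate_expression(
    samples: pd.DataFrame,
    probe_to_gene: dict[str, str],
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate (region, probe, value) samples into per-gene regional z-scores.

    Per probe: samples falling in a region are averaged, and the regional means
    are standardized across regions.  Per gene: its probe maps are averaged and
    standardized across regions again.  Standardization uses the sample SD.

    Returns a DataFrame indexed by region with one column per gene.
    """
    required = {"region", "probe", "value"}
    if not required.issubset(samples.columns):
        raise ExpressionError(f"samples table needs columns {sorted(required)}")
    samples = samples.copy()
    samples["probe"] = samples["probe"].astype(str)
    probe_to_gene = {str(k): v for k, v in probe_to_gene.items()}
    unknown = set(samples["probe"]) - set(probe_to_gene)
    if unknown:
        raise ExpressionError(f"probes without a gene assignment: {sorted(unknown)}")
    if regions is None:
        regions = sorted(samples["region"].unique())
    means = samples.pivot_table(index="region", columns="probe", values="value", aggfunc="mean")
    means = means.reindex(regions)
    if means.isna().any().any():
        missing = [
            f"{r}/{p}"
            for p in means.columns
            for r in means.index[means[p].isna()]
        ]
        raise ExpressionError(f"regions with no sample for a probe: {missing}")
    probe_z = means.apply(zscore, axis=0, result_type="broadcast")
    genes = {}
    for gene in sorted(set(probe_to_gene.values())):
        cols = [p for p in probe_z.columns if probe_to_gene[p] == gene]
        if not cols:
            continue
        genes[gene] = zscore(probe_z[cols].mean(axis=1).to_numpy())
    return pd.DataFrame(genes, index=pd.Index(regions, name="region"))


def filter_incoherent_probes(probe_maps: pd.DataFrame, min_corr: float) -> list[str]:
    """Greedily drop probes whose mean correlation with the rest is too low.

    While the lowest mean pairwise Pearson correlation falls below
    ``min_corr``, the offending probe is removed; never drops below one probe.
    Returns the retained probe names.
    """
    probes = [str(p) for p in probe_maps.columns]
    if len(probes) < 2:
        warnings.warn("single probe: nothing to filter", stacklevel=2)
        return probes
    data = probe_maps.to_numpy(dtype=float)
    keep = list(range(data.shape[1]))
    while len(keep) > 1:
        corr = np.corrcoef(data[:, keep], rowvar=False)
        mean_corr = (corr.sum(axis=0) - 1.0) / (len(keep) - 1)
        worst = int(np.argmin(mean_corr))
        if mean_corr[worst] >= min_corr:
            break
        keep.pop(worst)
    return [probes[i] for i in keep]
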