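"""Plain-text I/O: TSV matrices and tables, JSON run manifests.

The canonical on-disk dialect is tab-separated with region names as the first
row and column (matrices) or a ``region`` column (tables); ``.csv`` files are
accepted on input.  Every writer/reader pair round-trips exactly at float
precision ``%.17g``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .connectome import Connectome
from .dynamics import Trajectory
from .evaluation import AtrophyMap
from .profiles import RegionalProfiles

logger = logging.getLogger("synspread")


class BundleError(ValueError):
    pass


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def save_matrix(path, matrix: np.ndarray, names: list[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=names, columns=names)
    df.to_csv(path, sep=_sep(Path(path)), float_format="%.17g", index_label="region")


def load_matrix(path, symmetric: bool = True) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=_sep(Path(path)), index_col=0, float_precision="round_trip")
    names = [str(x) for x in df.index]
    if names != [str(x) for x in df.columns]:
        raise BundleError(f"{path}: row and column region names differ")
    a = df.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise BundleError(f"{path}: matrix contains NaN entries")
    if symmetric and not np.allclose(a, a.T):
        raise BundleError(f"{path}: matrix is not symmetric")
    return names, a


def save_regions(path, c: Connectome) -> None:
    pd.DataFrame(
        {
            "name": c.region_names,
            "size_voxels": c.sizes,
            "x": c.coords[:, 0],
            "y": c.coords[:, 1],
            "z": c.coords[:, 2],
        }
    ).to_csv(path, sep=_sep(Path(path)), index=False, float_format="%.17g")


def load_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(Path(path)), float_precision="round_trip")
    required = {"name", "size_voxels", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise BundleError(f"{path}: region table needs columns {sorted(required)}")
    df["name"] = df["name"].astype(str)
    return df


def save_connectome(outdir, c: Connectome, prefix: str = "") -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": outdir / f"{prefix}weights.tsv",
        "lengths": outdir / f"{prefix}lengths.tsv",
        "regions": outdir / f"{prefix}regions.tsv",
    }
    save_matrix(paths["weights"], c.weights, c.region_names)
    save_matrix(paths["lengths"], c.lengths, c.region_names)
    save_regions(paths["regions"], c)
    return {k: str(v) for k, v in paths.items()}


def load_connectome(weights_path, lengths_path, regions_path) -> Connectome:
    names, w = load_matrix(weights_path)
    names_l, l = load_matrix(lengths_path)
    if names_l != names:
        raise BundleError("weights and lengths matrices name different regions")
    reg = load_regions(regions_path)
    if list(reg["name"]) != names:
        diff = sorted(set(reg["name"]).symmetric_difference(names))
        raise BundleError(f"region table does not match matrices; differing: {diff}")
    return Connectome(
        names, w, l, reg["size_voxels"].to_numpy(int), reg[["x", "y", "z"]].to_numpy(float)
    )


def save_profiles(path, p: RegionalProfiles) -> None:
    pd.DataFrame(
        {"region": p.region_names, "snca_z": p.snca_z, "gba_z": p.gba_z}
    ).to_csv(path, sep=_sep(Path(path)), index=False, float_format="%.17g")


def load_profiles(path, transform: str = "normal_cdf") -> RegionalProfiles:
    df = pd.read_csv(path, sep=_sep(Path(path)), float_precision="round_trip")
    required = {"region", "snca_z", "gba_z"}
    if not required.issubset(df.columns):
        raise BundleError(f"{path}: profiles table needs columns {sorted(required)}")
    return RegionalProfiles(
        [str(x) for x in df["region"]],
        df["snca_z"].to_numpy(float),
        df["gba_z"].to_numpy(float),
        transform,
    )


def save_atrophy(path, a: AtrophyMap) -> None:
    pd.DataFrame({"region": a.region_names, "atrophy": a.values}).to_csv(
        path, sep=_sep(Path(path)), index=False, float_format="%.17g"
    )


def load_atrophy(path, excluded_regions: Optional[set[str]] = None) -> AtrophyMap:
    df = pd.read_csv(path, sep=_sep(Path(path)), float_precision="round_trip")
    if not {"region", "atrophy"}.issubset(df.columns):
        raise BundleError(f"{path}: atrophy table needs columns region, atrophy")
    return AtrophyMap(
        [str(x) for x in df["region"]],
        df["atrophy"].to_numpy(float),
        excluded_regions or set(),
    )


def load_fc(path, region_names: Optional[list[str]] = None) -> np.ndarray:
    """FC matrix; negative entries are zeroed on load (with a logged count)."""
    names, fc = load_matrix(path)
    if region_names is not None and names != list(region_names):
        raise BundleError(f"{path}: FC regions do not match the connectome")
    n_neg = int((fc < 0).sum())
    if n_neg:
        logger.info("FC: zeroed %d negative entries on load", n_neg)
        fc = np.clip(fc, 0.0, None)
    return fc


def save_trajectory(outdir, traj: Trajectory, prefix: str = "") -> dict[str, str]:
    """Wide-format TSV per quantity (time x region) plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("normal", traj.N),
        ("misfolded", traj.M),
        ("density", traj.density),
        ("atrophy", traj.atrophy),
    ):
        p = outdir / f"{prefix}{name}.tsv"
        pd.DataFrame(arr, index=pd.Index(traj.times, name="time"), columns=traj.region_names).to_csv(
            p, sep="\t", float_format="%.17g"
        )
        paths[name] = str(p)
    mpath = outdir / f"{prefix}trajectory_meta.json"
    mpath.write_text(json.dumps(traj.meta, indent=2, default=str))
    paths["meta"] = str(mpath)
    return paths


def load_trajectory(outdir, prefix: str = "") -> Trajectory:
    outdir = Path(outdir)
    frames = {}
    for name in ("normal", "misfolded", "density", "atrophy"):
        frames[name] = pd.read_csv(outdir / f"{prefix}{name}.tsv", sep="\t", index_col=0, float_precision="round_trip")
    meta_path = outdir / f"{prefix}trajectory_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ref = frames["normal"]
    return Trajectory(
        times=ref.index.to_numpy(int),
        N=frames["normal"].to_numpy(float),
        M=frames["misfolded"].to_numpy(float),
        density=frames["density"].to_numpy(float),
        atrophy=frames["atrophy"].to_numpy(float),
        region_names=[str(x) for x in ref.columns],
        meta=meta,
    )


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, params: dict, inputs: dict[str, str], seeds: dict) -> None:
    """JSON run manifest: enough to bit-reproduce the run."""
    manifest = {
        "tool": "synspread",
        "version": _version(),
        "command": command,
        "params": params,
        "inputs": {k: {"path": str(v), "sha256": file_hash(v)} for k, v in inputs.items() if v},
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("synspread")
    except Exception:  # pragma: no cover
        return "unknown"


def load_bundle(config: dict) -> tuple[Connectome, RegionalProfiles, Optional[np.ndarray], Optional[AtrophyMap]]:
    """Load and cross-validate a full input bundle.

    ``config`` keys: weights, lengths, regions, profiles (paths; required),
    fc, atrophy (optional).  All files must name the same regions in the same
    order; FC negatives are zeroed on load.
    """
    for key in ("weights", "lengths", "regions", "profiles"):
        if key not in config:
            raise BundleError(f"bundle config is missing {key!r}")
        if not Path(config[key]).exists():
            raise BundleError(f"{key} file not found: {config[key]}")
    c = load_connectome(config["weights"], config["lengths"], config["regions"])
    profiles = load_profiles(config["profiles"], config.get("transform", "normal_cdf"))
    if list(profiles.region_names) != list(c.region_names):
        diff = sorted(set(profiles.region_names).symmetric_difference(c.region_names))
        raise BundleError(f"profiles regions do not match the connectome; differing: {diff}")
    fc = None
    if config.get("fc"):
        fc = load_fc(config["fc"], c.region_names)
    atrophy = None
    if config.get("atrophy"):
        atrophy = load_atrophy(config["atrophy"])
        if list(atrophy.region_names) != list(c.region_names):
            diff = sorted(set(atrophy.region_names).symmetric_difference(c.region_names))
            raise BundleError(f"atrophy regions do not match the connectome; differing: {diff}")
    return c, profiles, fc, atrophy
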