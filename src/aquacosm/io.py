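"""Result serialization: tidy CSV tables, selection JSON, run manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .assessment import SelectionResult
from .config import RunConfig, config_hash

ENDPOINT_COLUMNS = ["group", "temperature", "aro_level", "biomass", "basis"]
CORRELATION_COLUMNS = ["scenario", "group", "temperature", "r", "p", "tier"]


def _package_version() -> str:
    try:
        return version("aquacosm")
    except PackageNotFoundError:
        return "unknown"


def write_results(
    tables: dict[str, pd.DataFrame | SelectionResult | dict],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write named results under a directory and a run manifest besides.

    DataFrames go to ``<name>.csv`` with a stable column order; selection
    results and plain dicts go to ``<name>.json``. The manifest records the
    config hash, seed, package version and files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            df = obj
            for preferred in (ENDPOINT_COLUMNS, CORRELATION_COLUMNS):
                if set(preferred) <= set(df.columns):
                    rest = [c for c in df.columns if c not in preferred]
                    df = df[preferred + rest]
                    break
            df.to_csv(path, index=False)
        elif isinstance(obj, SelectionResult):
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(asdict(obj), indent=2))
        elif isinstance(obj, dict):
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=str))
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
        written[name] = path

    manifest = {
        "package_version": _package_version(),
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
        "written": {k: str(v.name) for k, v in written.items()},
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    return written


def read_endpoints(path: str | Path) -> pd.DataFrame:
    """Read an endpoint CSV back with canonical dtypes."""
    df = pd.read_csv(path)
    df["temperature"] = df["temperature"].astype(float)
    df["aro_level"] = df["aro_level"].astype(int)
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation CSV (group, temperature, aro_level, replicate,
    biomass) with canonical dtypes."""
    df = pd.read_csv(path)
    df["temperature"] = df["temperature"].astype(float)
    df["aro_level"] = df["aro_level"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df
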