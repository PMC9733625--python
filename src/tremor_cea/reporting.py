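"""Output writers: machine CSVs, a pretty console report, run manifests.

Machine CSVs carry full precision with dot decimals and no thousands
separators regardless of locale (pandas' default C-locale formatting);
currency rounding to the nearest pound and QALY rounding to two decimals
happen only in the human-readable report.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import StrategyResult
from .parameters import StrategyName

__all__ = [
    "write_csv",
    "write_traces",
    "write_manifest",
    "pretty_results",
    "config_hash",
]


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_traces(results: dict[StrategyName, StrategyResult], outdir) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    for name, res in results.items():
        df = res.trace.to_frame()
        df["discounted_cost"] = res.per_cycle_costs
        df["discounted_qaly"] = res.per_cycle_qalys
        paths.append(write_csv(df, outdir / f"trace_{name.value}.csv"))
    return paths


def config_hash(config_path) -> str:
    return hashlib.sha256(Path(config_path).read_bytes()).hexdigest()


def write_manifest(
    outdir, *, config_path=None, seed: int | None = None,
    scenario: dict | None = None, outputs: list[Path] = (),
) -> Path:
    """Write the run manifest: config hash, seed, version, timestamp, outputs.

    Re-running with the same config, seed and package version reproduces
    the numeric outputs byte-for-byte; the timestamp is informational only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "tremor-cea",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_path": str(config_path) if config_path else None,
        "config_sha256": config_hash(config_path) if config_path else None,
        "seed": seed,
        "scenario": scenario,
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def pretty_results(table: pd.DataFrame) -> str:
    """Human-readable base-case table (GBP to the pound, QALYs to 2 dp)."""
    df = table.copy()
    for col in ("cost", "delta_cost"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:,.0f}")
    for col in ("qaly", "delta_qaly"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    df.columns = ["Strategy", "Cost (£)", "Δ Cost (£)", "QALY", "Δ QALY", "ICER (£/QALY)"]
    return df.to_string(index=False)
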