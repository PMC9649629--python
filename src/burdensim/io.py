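"""Result serialization: tidy CSVs, JSON summaries, run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

from . import __version__
from .batch import StochasticResult
from .metrics import SummaryRow
from .params import Scenario, scenario_to_config
from .trajectory import Trajectory

__all__ = ["write_trajectory", "write_result", "write_summary", "write_manifest",
           "read_manifest"]


def write_trajectory(traj: Trajectory, out_dir: str | Path,
                     stem: str = "trajectory") -> list[Path]:
    """Tidy CSVs: (time, [batch,] class, abundance) and the production series."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / f"{stem}.csv", out / f"{stem}_production.csv"]
    traj.to_frame().to_csv(paths[0], index=False)
    traj.production_frame().to_csv(paths[1], index=False)
    return paths


def write_result(result: StochasticResult, out_dir: str | Path,
                 stem: str = "replicate") -> list[Path]:
    paths = write_trajectory(result.trajectory, out_dir, stem=stem)
    endpoint_path = Path(out_dir) / f"{stem}_batches.csv"
    result.batch_endpoints.to_csv(endpoint_path, index=False)
    return paths + [endpoint_path]


def write_summary(row: SummaryRow, scenario: Scenario, path: str | Path,
                  seeds: list[int] | None = None) -> Path:
    payload = {
        "summary": dataclasses.asdict(row),
        "seeds": seeds or [],
        "scenario": scenario_to_config(scenario),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


def write_manifest(out_dir: str | Path, scenario: Scenario, engine: str,
                   seeds: list[int], outputs: list[Path]) -> Path:
    """Manifest sufficient to re-run the scenario bit-identically."""
    out = Path(out_dir)
    manifest = {
        "scenario": scenario_to_config(scenario),
        "scenario_id": scenario.scenario_id,
        "engine": engine,
        "seeds": seeds,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(p.relative_to(out)) if p.is_relative_to(out) else str(p)
                    for p in outputs],
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
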