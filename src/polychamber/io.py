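"""Plain-text input/output: field snapshots, tidy tables, run manifests.

All artifacts are CSV or JSON.  Field snapshots are one CSV matrix per
field per time point with a JSON sidecar carrying the lattice spec,
parameters and time stamp.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lattice import FIELD_NAMES, FieldSet, LatticeSpec
from .simulate import ChamberResult, SimConfig, SweepResult


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: Union[str, Path], payload) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True)
                    + "\n")
    return path


def write_snapshot(outdir: Union[str, Path], fields: FieldSet, time: float,
                   config: Optional[SimConfig] = None,
                   tag: str = "snapshot") -> List[Path]:
    """One CSV matrix per field plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"{tag}_t{time:08.3f}h"
    written = []
    for name in FIELD_NAMES:
        p = outdir / f"{stamp}_{name}.csv"
        np.savetxt(p, fields.get(name), delimiter=",", fmt="%.10g")
        written.append(p)
    sidecar = {
        "time_h": time,
        "fields": {n: str((outdir / f'{stamp}_{n}.csv').name)
                   for n in FIELD_NAMES},
        "lattice": fields.spec,
    }
    if config is not None:
        sidecar["config"] = config
    written.append(write_json(outdir / f"{stamp}.json", sidecar))
    return written


def write_chamber_result(outdir: Union[str, Path],
                         result: ChamberResult) -> List[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for t, snap in sorted(result.snapshots.items()):
        written += write_snapshot(outdir, snap, t, config=result.config)
    written += write_snapshot(outdir, result.fields, result.config.duration,
                              config=result.config, tag="final")
    depoly = pd.DataFrame({"time_h": result.times,
                           "depolymerized_mass": result.depolymerized})
    p = outdir / "depolymerization.csv"
    depoly.to_csv(p, index=False)
    written.append(p)
    growth = pd.DataFrame({
        "cell": np.arange(result.population.n_cells),
        "row": result.population.rows,
        "col": result.population.cols,
        "biomass": result.population.B,
        "mu_final": result.growth.mu_last,
        "mu_time_avg": result.growth.mu_time_avg,
        "uptake_cum": result.growth.uptake_cum,
    })
    p = outdir / "cells.csv"
    growth.to_csv(p, index=False)
    written.append(p)
    summary = {
        "mean_mu": result.mean_growth_rate(),
        "depolymerization_rate": result.depolymerization_rate,
        "total_depolymerized": result.total_depolymerized,
        "boundary_exchange": result.boundary_exchange,
        "n_cells": result.population.n_cells,
        "config": result.config,
    }
    written.append(write_json(outdir / "summary.json", summary))
    return written


def write_sweep_result(outdir: Union[str, Path], sweep: SweepResult,
                       name: str = "sweep") -> List[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / f"{name}.csv"
    sweep.table.to_csv(p, index=False)
    meta = write_json(outdir / f"{name}.json",
                      {"axes": {k: v for k, v in sweep.axes.items()}})
    return [p, meta]


class RunManifest:
    """Run provenance: written before any output, finalized on completion
    with the list of every file produced."""

    def __init__(self, path: Union[str, Path], subcommand: str,
                 seed: Optional[int] = None,
                 config_path: Optional[str] = None):
        import polychamber
        self.path = Path(path)
        self.record = {
            "subcommand": subcommand,
            "seed": seed,
            "config_path": config_path,
            "version": polychamber.__version__,
            "numpy_version": np.__version__,
            "started_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "outputs": [],
            "completed": False,
        }
        write_json(self.path, self.record)

    def add(self, paths: Sequence[Union[str, Path]]) -> None:
        self.record["outputs"].extend(str(p) for p in paths)

    def finalize(self) -> None:
        self.record["completed"] = True
        self.record["finished_utc"] = _dt.datetime.now(
            _dt.timezone.utc).isoformat()
        write_json(self.path, self.record)
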