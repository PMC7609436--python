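"""Reading and writing: configs (YAML/JSON), TIFF snapshots, CSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cpm.types import AdhesionMatrix, CellType, LatticeState, ModelParams, PotentialField
from .scenarios import (
    IngressionSchedule,
    ScenarioConfig,
    TissueLayout,
    Trajectory,
    default_layout,
)

__all__ = [
    "load_config",
    "dump_config",
    "config_to_objects",
    "write_trajectory",
    "write_label_tiff",
    "read_label_tiff",
]


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) simulation config document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(doc: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def config_to_objects(
    doc: dict,
) -> tuple[ScenarioConfig, AdhesionMatrix, ModelParams, TissueLayout, PotentialField]:
    """Build the runnable parameter bundle from a config document."""
    sc = doc["scenario"]
    ing = sc.get("ingression", {})
    config = ScenarioConfig(
        name=sc["name"],
        ppl_mobility_multiplier=sc.get("ppl_mobility_multiplier", 1.0),
        ppl_adhesion_multiplier=sc.get("ppl_adhesion_multiplier", 1.0),
        stop_threshold_um=sc.get("stop_threshold_um", 400.0),
        max_mcs=sc.get("max_mcs", 3000),
        save_interval=sc.get("save_interval", 100),
        schedule=IngressionSchedule(
            interval=ing.get("interval", 15),
            batch=ing.get("batch", 4),
            enabled=ing.get("enabled", True),
        ),
    )
    p = doc["params"]
    mu = {
        CellType[name.upper()]: float(v) for name, v in p.get("mu_by_type", {}).items()
    }
    kwargs = dict(
        lambda_V=p["lambda_V"],
        lambda_S=p["lambda_S"],
        lambda_M=p["lambda_M"],
        T=p["T"],
        neighbourhood=p.get("neighbourhood", "moore"),
        seed=p.get("seed", 0),
    )
    if mu:
        kwargs["mu_by_type"] = mu
    params = ModelParams(**kwargs)
    J = AdhesionMatrix(np.asarray(doc["adhesion"]["J"], float))
    layout = default_layout(doc.get("lattice", {}).get("scale", "desk"))
    pot = doc.get("potential", {})
    field = PotentialField(
        slope=pot.get("slope", 1.0),
        anterior_favourable=pot.get("anterior_favourable", True),
    )
    return config, J, params, layout, field


def write_label_tiff(path: str | Path, pages: list[np.ndarray]) -> None:
    """Write integer label images as a multi-page TIFF."""
    tifffile.imwrite(
        str(path), np.stack(pages).astype(np.int32), photometric="minisblack"
    )


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> dict:
    """Write a run: TIFF snapshot stack, CSV trace, JSON manifest + cell table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_label_tiff(out / "snapshots.tif", [s for _, s in traj.snapshots])
    traj.trace.to_csv(out / "trace.csv", index=False)
    state = traj.final_state
    cell_table = [
        {
            "id": rec.id,
            "type": rec.type.name,
            "V": rec.V,
            "V0": rec.V0,
            "S": rec.S,
            "S0": rec.S0,
            "removed": rec.removed,
        }
        for rec in state.cells.values()
    ]
    manifest = {
        "scenario": traj.config.name,
        "termination": traj.termination,
        "mcs": traj.mcs,
        "snapshot_mcs": [m for m, _ in traj.snapshots],
        "site_size_um": state.site_size,
        "cells": cell_table,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
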