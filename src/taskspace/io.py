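"""Plain-text readers/writers for the pipeline's tables and artifacts.

Cohort and state-space tables are TSV; gradient bases and map sets are
delimited matrices (one vertices-by-subjects matrix per condition) plus a
JSON manifest recording condition, file name and subject order; effect
specifications are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import EffectSpec, GradientBasis, MapSet

__all__ = [
    "write_cohort", "read_cohort",
    "write_state_space", "read_state_space",
    "write_gradients", "read_gradients",
    "write_mapset", "read_mapset",
    "write_effects", "read_effects",
    "write_json", "read_json",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str})
    required = {"subject_id", "family_id", "age", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    return df


def write_state_space(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_state_space(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str})
    required = {"subject_id", "condition", "dimension", "location"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"state-space table lacks columns {sorted(missing)}")
    return df


def write_gradients(basis: GradientBasis, path) -> None:
    pd.DataFrame(basis.values, columns=list(basis.dim_names)).to_csv(
        path, sep="\t", index=False
    )


def read_gradients(path) -> GradientBasis:
    df = pd.read_csv(path, sep="\t")
    return GradientBasis(values=df.to_numpy(dtype=float), dim_names=tuple(df.columns))


def write_mapset(maps: MapSet, directory) -> None:
    """One matrix TSV per condition plus manifest.json (subject order)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_vertices": maps.n_vertices,
        "subjects": list(maps.subjects),
        "conditions": [],
    }
    for c in maps.conditions:
        fname = f"maps_{c}.tsv"
        np.savetxt(directory / fname, maps.data[c], delimiter="\t", fmt="%.6g")
        manifest["conditions"].append({"condition": c, "file": fname})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_mapset(directory) -> MapSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    data = {}
    for entry in manifest["conditions"]:
        m = np.loadtxt(directory / entry["file"], delimiter="\t", ndmin=2)
        data[entry["condition"]] = m
    return MapSet(
        subjects=tuple(manifest["subjects"]),
        conditions=tuple(e["condition"] for e in manifest["conditions"]),
        data=data,
        n_vertices=int(manifest["n_vertices"]),
    )


def write_effects(effects: EffectSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(effects.to_dict(), sort_keys=False))


def read_effects(path) -> EffectSpec:
    return EffectSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
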