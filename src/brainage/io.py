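"""Plain-text serialization: TSV tables, whitespace matrices, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulationConfig


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_parcellation(parcellation: pd.DataFrame, path) -> None:
    parcellation.to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.8g")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path)


def write_edge_order(edges: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(edges, dtype=int), fmt="%d", delimiter="\t")


def read_edge_order(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter="\t").reshape(-1, 2)


def write_roi_set(roi_ids, path) -> None:
    Path(path).write_text("\n".join(str(int(r)) for r in roi_ids) + "\n")


def read_roi_set(path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.asarray([int(t) for t in text], dtype=int)


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("group_proportions", "age_range", "age_skewnorm"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def write_fc_run(fc_set, out_dir, cohort=None) -> Path:
    """Write per-participant square matrices + manifest + edge sidecar."""
    from .connectivity import matrix_from_vector

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_ids = np.unique(fc_set.edges)
    rows = []
    for i, pid in enumerate(fc_set.participant_ids):
        path = out / f"{pid}_fc.txt"
        write_matrix(matrix_from_vector(fc_set.X[i], roi_ids), path)
        rows.append({"participant": pid, "path": path.name})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_edge_order(fc_set.edges, out / "edge_order.tsv")
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
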