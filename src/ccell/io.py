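"""Plain-text file formats and run configuration plumbing.

Everything is tab-separated UTF-8 with a header row: labelled matrices
(design, transition), long-format observations (perturbation, time,
measurement_id, value), long-format initial concentrations and edge lists.
Configurations round-trip through YAML or JSON and every run log records
the config hash and seed so runs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .pipeline import RunConfig
from .sparse_bayes import BCSConfig

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_observations_tsv",
    "read_observations_tsv",
    "write_initials_tsv",
    "read_initials_tsv",
    "write_edges_tsv",
    "read_edges_tsv",
    "load_run_config",
    "dump_run_config",
    "config_hash",
]


def write_matrix_tsv(
    matrix: np.ndarray,
    path: str | Path,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
    index_name: str = "id",
) -> None:
    matrix = np.asarray(matrix)
    rows = row_labels or [f"r{i}" for i in range(matrix.shape[0])]
    cols = col_labels or [f"c{j}" for j in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=rows, columns=cols).to_csv(
        path, sep="\t", index_label=index_name
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled matrix; malformed rows raise with their line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    rows, labels = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != width:
            raise ValueError(
                f"{path}: line {lineno}: expected {width} fields, "
                f"got {len(fields)}"
            )
        labels.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return np.array(rows, dtype=float), labels, header[1:]


def write_observations_tsv(
    observations: np.ndarray,
    path: str | Path,
    measurement_ids: list[str] | None = None,
) -> None:
    """Long-format per-perturbation time series (P, T, M)."""
    obs = np.asarray(observations, dtype=float)
    p, t, m = obs.shape
    ids = measurement_ids or [f"m{i}" for i in range(m)]
    pi, ti, mi = np.meshgrid(range(p), range(t), range(m), indexing="ij")
    pd.DataFrame(
        {
            "perturbation": pi.ravel(),
            "time": ti.ravel(),
            "measurement_id": np.array(ids)[mi.ravel()],
            "value": obs.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read long-format observations back into a dense (P, T, M) array.

    Duplicate (perturbation, time, measurement) keys and missing
    combinations are hard errors.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"perturbation", "time", "measurement_id", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    key = ["perturbation", "time", "measurement_id"]
    dup = frame.duplicated(subset=key)
    if dup.any():
        first = frame.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate observation key {first}")
    ids = list(dict.fromkeys(frame["measurement_id"].astype(str)))
    perts = sorted(frame["perturbation"].unique())
    times = sorted(frame["time"].unique())
    expected = len(perts) * len(times) * len(ids)
    if len(frame) != expected:
        raise ValueError(
            f"{path}: incomplete grid: {len(frame)} rows, expected {expected} "
            "(every perturbation x time x measurement combination)"
        )
    pivot = frame.pivot_table(
        index=["perturbation", "time"],
        columns="measurement_id",
        values="value",
        sort=False,
    ).reindex(columns=ids)
    obs = pivot.to_numpy().reshape(len(perts), len(times), len(ids))
    return obs, ids


def write_initials_tsv(
    initials: np.ndarray, path: str | Path, species_ids: list[str] | None = None
) -> None:
    x0 = np.atleast_2d(np.asarray(initials, dtype=float))
    p, n = x0.shape
    ids = species_ids or [f"s{j}" for j in range(n)]
    pi, si = np.meshgrid(range(p), range(n), indexing="ij")
    pd.DataFrame(
        {
            "perturbation": pi.ravel(),
            "species": np.array(ids)[si.ravel()],
            "value": x0.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_initials_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    ids = list(dict.fromkeys(frame["species"].astype(str)))
    perts = sorted(frame["perturbation"].unique())
    pivot = frame.pivot_table(
        index="perturbation", columns="species", values="value", sort=False
    ).reindex(index=perts, columns=ids)
    return pivot.to_numpy(), ids


def write_edges_tsv(
    edges: list[tuple],
    path: str | Path,
    columns: tuple[str, ...] = ("source", "target", "weight"),
) -> None:
    pd.DataFrame(edges, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# configuration


def _config_to_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    alpha = d["bcs"]["alpha_init"]
    if isinstance(alpha, np.ndarray):
        d["bcs"]["alpha_init"] = alpha.tolist()
    return d


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = _config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    )
    bcs = BCSConfig(**data.pop("bcs", {}))
    return RunConfig(bcs=bcs, **data)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
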