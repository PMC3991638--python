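"""Combined-measurement (pooled assay) design matrices.

A combined measurement exploits antibody cross-reactivity: one
immunoprecipitation readout reports a weighted sum of several species'
concentrations.  The M x N design matrix Phi collects these pooling
patterns; here it is built as a regular low-density parity-check (LDPC)
style binary matrix: every species (column) appears in exactly
``column_weight`` measurements and the measurements (rows) carry loads that
differ by at most one.  Construction is greedy load balancing with seeded
random tie-breaking, which keeps the column weights exact for any feasible
(M, N, w) rather than only when Gallager's band sizes divide evenly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementDesign",
    "generate_ldpc_design",
    "simulate_measurements",
    "write_design",
    "read_design",
]


@dataclass
class MeasurementDesign:
    """An M x N combined-measurement matrix with its construction metadata."""

    matrix: np.ndarray
    construction: dict
    species_ids: list[str]
    measurement_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m, n = self.matrix.shape
        if len(self.species_ids) != n or len(self.measurement_ids) != m:
            raise ValueError("label counts do not match matrix shape")
        if m and not self.matrix.any(axis=1).all():
            raise ValueError("design has an all-zero row")
        if n and not self.matrix.any(axis=0).all():
            raise ValueError("design has an all-zero column")

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]


def generate_ldpc_design(
    n_measurements: int,
    n_species: int,
    column_weight: int = 3,
    seed: int = 0,
) -> MeasurementDesign:
    """Regular LDPC-style binary pooling design, deterministic given seed.

    Every column receives exactly ``column_weight`` ones placed on the
    currently least-loaded rows (seeded random tie-break), so row weights
    never differ by more than one and no row is left empty whenever
    ``n_species * column_weight >= n_measurements``.
    """
    if column_weight < 1:
        raise ValueError("column_weight must be >= 1")
    if column_weight > n_measurements:
        raise ValueError(
            f"column_weight {column_weight} exceeds the number of "
            f"measurements {n_measurements}; feasible range is "
            f"1..{n_measurements}"
        )
    if n_species * column_weight < n_measurements:
        raise ValueError(
            "infeasible: fewer ones than rows "
            f"({n_species} x {column_weight} < {n_measurements}); increase "
            "column_weight to at least "
            f"{int(np.ceil(n_measurements / n_species))}"
        )
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n_measurements, n_species))
    loads = np.zeros(n_measurements, dtype=int)
    for j in range(n_species):
        order = np.lexsort((rng.random(n_measurements), loads))
        rows = order[:column_weight]
        matrix[rows, j] = 1.0
        loads[rows] += 1
    return MeasurementDesign(
        matrix=matrix,
        construction={
            "type": "ldpc_regular",
            "column_weight": int(column_weight),
            "row_weight": [int(loads.min()), int(loads.max())],
            "seed": int(seed),
        },
        species_ids=[f"s{j}" for j in range(n_species)],
        measurement_ids=[f"m{i}" for i in range(n_measurements)],
    )


def simulate_measurements(
    design: MeasurementDesign,
    concentrations: np.ndarray,
    noise_std: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Noisy combined measurements ``Phi x + N(0, noise_std^2 I)``.

    ``noise_std = 0`` returns the exact products.  Either a seed or an
    existing generator may be supplied; the generator takes precedence.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    x = np.asarray(concentrations, dtype=float).ravel()
    if x.shape[0] != design.n_species:
        raise ValueError("concentration vector length does not match design")
    clean = design.matrix @ x
    if noise_std == 0:
        return clean
    if rng is None:
        rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, noise_std, size=clean.shape)


# --------------------------------------------------------------------------
# on-disk form: TSV matrix plus a JSON sidecar with the construction


def write_design(design: MeasurementDesign, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        design.matrix, index=design.measurement_ids, columns=design.species_ids
    )
    frame.to_csv(path, sep="\t", index_label="measurement_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(design.construction, indent=1) + "\n")


def read_design(path: str | Path) -> MeasurementDesign:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    construction = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return MeasurementDesign(
        matrix=frame.to_numpy(dtype=float),
        construction=construction,
        species_ids=[str(c) for c in frame.columns],
        measurement_ids=[str(i) for i in frame.index],
    )
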