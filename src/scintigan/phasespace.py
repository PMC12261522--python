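"""Phase-space tables: schema, emission grids, normalization and file I/O.

A phase-space table has exactly nine columns in fixed order:

    X, Y          photon position on the photodetector face (mm)
    dX, dY, dZ    unit direction components (dZ < 0 toward the detector)
    EKine         photon kinetic energy (eV)
    emX, emY, emZ emission coordinates (mm) — the GAN condition labels

Normalization is a per-column z-score; the means and standard
deviations computed on the training table are persisted and are the
only statistics used to denormalize generated output.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import PHASESPACE_COLUMNS, CrystalGeometry, EmissionSpectrum, simulate_point

__all__ = [
    "PHASESPACE_COLUMNS",
    "FEATURE_COLUMNS",
    "CONDITION_COLUMNS",
    "NormalizationStats",
    "SchemaError",
    "emission_grid",
    "build_training_dataset",
    "compute_stats",
    "normalize",
    "denormalize",
    "write_table",
    "read_table",
    "table_hash",
]

#: the six features the GAN generates
FEATURE_COLUMNS = ("X", "Y", "dX", "dY", "dZ", "EKine")
#: the three condition labels (classX, classY, classZ)
CONDITION_COLUMNS = ("emX", "emY", "emZ")


class SchemaError(ValueError):
    """A table does not carry the expected phase-space columns."""


def _check_schema(table: pd.DataFrame, required=PHASESPACE_COLUMNS) -> None:
    missing = [c for c in required if c not in table.columns]
    extra = [c for c in table.columns if c not in required]
    if missing or extra:
        raise SchemaError(
            f"phase-space schema mismatch: missing columns {missing}, extra columns {extra}"
        )


# ---------------------------------------------------------------------------
# emission grid
# ---------------------------------------------------------------------------


def emission_grid(geometry=None, depths=(1.0, 5.0, 9.0), inset=0.01):
    """Emission points covering one octant of the cross-section at several depths.

    The cross-section lattice is the 10-point triangular octant
    ``{(x, y): x, y in {0, hw/3, 2hw/3, hw - inset}, y <= x}`` which for
    the default 3 x 3 mm face is {0, 0.5, 1.0, 1.49} mm; boundary points
    are inset so every emission point is strictly inside the crystal.
    With the default three depths this yields 30 points, including the
    reference point (0.5, 0.5, 1.0).
    """
    geometry = CrystalGeometry() if geometry is None else geometry
    depths = list(depths)
    for z in depths:
        if not 0.0 < z < geometry.length_z:
            raise ValueError(f"depth {z} mm lies outside the crystal (0, {geometry.length_z})")
    hw = geometry.half_width_x
    levels = [0.0, hw / 3.0, 2.0 * hw / 3.0, hw - inset]
    points = []
    for z in depths:
        for x in levels:
            for y in levels:
                if y <= x:
                    points.append((x, y, z))
    return np.array(points, dtype=float)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def build_training_dataset(grid, n_per_point, geometry=None, spectrum=None, seed=None):
    """Simulate every grid point until exactly ``n_per_point`` detected rows.

    Each emission point is re-simulated in batches until ``n_per_point``
    photons have been detected, then truncated, so every point
    contributes the same number of rows (the convention behind a
    30 x 30 000 = 900k-row training set).
    """
    if n_per_point <= 0:
        raise ValueError("n_per_point must be positive")
    geometry = CrystalGeometry() if geometry is None else geometry
    spectrum = EmissionSpectrum() if spectrum is None else spectrum
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    chunks = []
    for point, ss in zip(grid, seeds):
        rng = np.random.default_rng(ss)
        collected = []
        n_detected = 0
        # first batch sized on a nominal ~60% collection efficiency
        batch = max(int(n_per_point / 0.6), 1000)
        while n_detected < n_per_point:
            part = simulate_point(point, batch, geometry, spectrum, rng=rng)
            collected.append(part)
            n_detected += len(part)
            batch = max(int((n_per_point - n_detected) / 0.5), 1000)
        chunk = pd.concat(collected, ignore_index=True).iloc[:n_per_point]
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationStats:
    """Per-column mean and standard deviation of a training table.

    Standard deviations use the population convention (divide by N).
    ``dataset_hash`` ties the statistics to the table they were computed
    on so a checkpoint can assert it is denormalizing with the right
    scale.
    """

    columns: tuple
    mean: np.ndarray
    std: np.ndarray
    dataset_hash: str = ""
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if not (len(self.columns) == self.mean.size == self.std.size):
            raise ValueError("columns, mean and std must have equal length")
        if np.any(self.std <= 0):
            bad = [c for c, s in zip(self.columns, self.std) if s <= 0]
            raise ValueError(f"standard deviation must be strictly positive; offending columns: {bad}")

    def subset(self, columns):
        idx = [self.columns.index(c) for c in columns]
        return NormalizationStats(
            columns=tuple(columns),
            mean=self.mean[idx],
            std=self.std[idx],
            dataset_hash=self.dataset_hash,
            created=self.created,
        )

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "dataset_hash": self.dataset_hash,
            "created": self.created,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            columns=tuple(d["columns"]),
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            dataset_hash=d.get("dataset_hash", ""),
            created=d.get("created", ""),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "NormalizationStats":
        return cls.from_dict(json.loads(Path(path).read_text()))


def table_hash(table: pd.DataFrame) -> str:
    """Stable content hash of a table (column names + float64 bytes)."""
    h = hashlib.sha256()
    h.update(",".join(table.columns).encode())
    h.update(np.ascontiguousarray(table.to_numpy(dtype=np.float64)).tobytes())
    return h.hexdigest()[:16]


def compute_stats(table: pd.DataFrame) -> NormalizationStats:
    """Per-column mean and population standard deviation of *table*."""
    if len(table) == 0:
        raise ValueError("cannot compute statistics of an empty table")
    values = table.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)  # population convention (ddof=0)
    constant = [c for c, s in zip(table.columns, std) if s == 0.0]
    if constant:
        raise ValueError(
            f"constant column(s) {constant} have zero standard deviation; "
            "normalization would be ill-defined"
        )
    return NormalizationStats(
        columns=tuple(table.columns), mean=mean, std=std, dataset_hash=table_hash(table)
    )


def normalize(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """z-score every column of *table* using *stats*."""
    missing = [c for c in table.columns if c not in stats.columns]
    if missing:
        raise KeyError(f"no normalization statistics for column(s): {missing}")
    out = table.copy()
    for c in table.columns:
        i = stats.columns.index(c)
        out[c] = (table[c].to_numpy(dtype=float) - stats.mean[i]) / stats.std[i]
    return out


def denormalize(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Invert :func:`normalize`; may cover only a subset of stats columns."""
    missing = [c for c in table.columns if c not in stats.columns]
    if missing:
        raise KeyError(f"no normalization statistics for column(s): {missing}")
    out = table.copy()
    for c in table.columns:
        i = stats.columns.index(c)
        out[c] = table[c].to_numpy(dtype=float) * stats.std[i] + stats.mean[i]
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path, format=None) -> None:
    """Write a phase-space table as CSV or Parquet (inferred from suffix)."""
    _check_schema(table)
    path = Path(path)
    fmt = format or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "parquet":
        table.to_parquet(path, index=False)
    elif fmt == "csv":
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'parquet'")


def read_table(path) -> pd.DataFrame:
    """Read a phase-space table written by :func:`write_table`."""
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    _check_schema(table)
    return table[list(PHASESPACE_COLUMNS)]
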