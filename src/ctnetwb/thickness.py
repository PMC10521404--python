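"""Parcel tables and per-subject vertex cortical-thickness data.

The network pipeline works on a documented TSV interchange format rather
than FreeSurfer-native surface files: one parcel table
(``parcel_name, hemisphere, network, vertex_count``) defines the canonical
node order, and one thickness table per subject
(``parcel_name, vertex_index, thickness_mm``) carries vertex-wise cortical
thickness in millimetres. Conversion from surface data happens upstream.

A parcel table for the 32 Yeo-7 parcels retained after the <50-vertex
exclusion ships with the package (:func:`default_parcel_table`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTable",
    "SubjectThickness",
    "read_parcel_table",
    "default_parcel_table",
    "filter_parcels",
    "read_subject_thickness",
    "write_subject_thickness",
    "mean_cortical_thickness",
]

_PARCEL_COLUMNS = ["parcel_name", "hemisphere", "network", "vertex_count"]


@dataclass(frozen=True)
class ParcelTable:
    """Atlas parcels with vertex counts; row order is the canonical node order."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _PARCEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"parcel table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("parcel table is empty")
        dup = df["parcel_name"][df["parcel_name"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate parcel names: {sorted(set(dup))}")
        counts = df["vertex_count"]
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, counts.astype(int)):
                raise ValueError("vertex_count must be integer")
        if (counts < 1).any():
            bad = df.loc[counts < 1, "parcel_name"].tolist()
            raise ValueError(f"non-positive vertex counts for: {bad}")

    @property
    def names(self) -> list[str]:
        return self.frame["parcel_name"].tolist()

    @property
    def n_parcels(self) -> int:
        return len(self.frame)

    @property
    def vertex_counts(self) -> dict[str, int]:
        return dict(
            zip(self.frame["parcel_name"], self.frame["vertex_count"].astype(int))
        )

    @property
    def total_vertices(self) -> int:
        return int(self.frame["vertex_count"].sum())


@dataclass
class SubjectThickness:
    """Per-parcel vectors of vertex thickness values (mm) for one subject."""

    subject_id: str
    values: dict[str, np.ndarray] = field(repr=False)

    def validate(self, table: ParcelTable) -> "SubjectThickness":
        counts = table.vertex_counts
        for name, expected in counts.items():
            if name not in self.values:
                raise ValueError(
                    f"subject {self.subject_id}: missing parcel {name!r}"
                )
            vec = np.asarray(self.values[name], dtype=float)
            if vec.shape != (expected,):
                raise ValueError(
                    f"subject {self.subject_id}: parcel {name!r} has "
                    f"{vec.size} vertices, expected {expected}"
                )
            if not np.all(np.isfinite(vec)) or np.any(vec <= 0):
                raise ValueError(
                    f"subject {self.subject_id}: parcel {name!r} contains "
                    "non-finite or non-positive thickness values"
                )
        extra = set(self.values) - set(counts)
        if extra:
            raise ValueError(
                f"subject {self.subject_id}: unknown parcels {sorted(extra)}"
            )
        return self


def read_parcel_table(path) -> ParcelTable:
    """Read and validate a parcel table TSV."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"parcel table {path} is empty") from exc
    df = df.reset_index(drop=True)
    table = ParcelTable(df)
    # normalise dtype once validated
    df["vertex_count"] = df["vertex_count"].astype(int)
    return table


def default_parcel_table() -> ParcelTable:
    """The 32 retained Yeo-7 parcels bundled with the package."""
    ref = importlib.resources.files("ctnetwb.data").joinpath("parcels_32.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_parcel_table(path)


def filter_parcels(table: ParcelTable, min_vertices: int = 50) -> ParcelTable:
    """Drop parcels with fewer than ``min_vertices`` vertices (order kept).

    Parcels with exactly ``min_vertices`` vertices survive: the exclusion is
    strictly-less-than, so the smallest retained parcel may sit exactly on
    the threshold.
    """
    kept = table.frame[table.frame["vertex_count"] >= min_vertices]
    if len(kept) == 0:
        raise ValueError(
            f"no parcels with >= {min_vertices} vertices; no network possible"
        )
    return ParcelTable(kept.reset_index(drop=True))


def read_subject_thickness(path, table: ParcelTable, subject_id: str | None = None) -> SubjectThickness:
    """Read one subject's thickness TSV and validate against ``table``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"parcel_name", "vertex_index", "thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"thickness file {path} missing columns: {sorted(missing)}")
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    values = {}
    for name, grp in df.groupby("parcel_name", sort=False):
        grp = grp.sort_values("vertex_index")
        idx = grp["vertex_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"parcel {name!r}: vertex_index must be 0..n-1 without gaps"
            )
        values[str(name)] = grp["thickness_mm"].to_numpy(dtype=float)
    return SubjectThickness(subject_id, values).validate(table)


def write_subject_thickness(subject: SubjectThickness, path) -> None:
    """Write one subject's thickness vectors in the interchange TSV format."""
    rows = []
    for name, vec in subject.values.items():
        rows.append(
            pd.DataFrame(
                {
                    "parcel_name": name,
                    "vertex_index": np.arange(len(vec)),
                    "thickness_mm": np.asarray(vec, dtype=float),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def mean_cortical_thickness(
    subject: SubjectThickness, weighting: str = "vertex"
) -> float:
    """Mean cortical thickness over all reserved parcels, in mm.

    ``weighting="vertex"`` (default) pools every vertex, so large parcels
    contribute proportionally to their area; ``weighting="parcel"`` averages
    the per-parcel means instead.
    """
    if weighting == "vertex":
        pooled = np.concatenate([np.asarray(v, float) for v in subject.values.values()])
        return float(pooled.mean())
    if weighting == "parcel":
        means = [float(np.mean(v)) for v in subject.values.values()]
        return float(np.mean(means))
    raise ValueError(f"unknown weighting {weighting!r}")
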