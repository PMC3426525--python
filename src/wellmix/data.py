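"""Field/well data model and table I/O.

An HCS plate experiment yields one row per microscope *field*: a total
cell count plus the proportions of cells assigned to each cellular
phenotype (S, G2, M, apoptotic).  Fields are grouped into *wells* (the
experimental unit) by a well identifier, and wells carry a condition
label (e.g. the siRNA used).  Proportions are not forced to sum to one:
cellular phenotypes are not mutually exclusive.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DESCRIPTORS",
    "PROPORTION_EPS",
    "FieldRecord",
    "WellData",
    "Dataset",
    "ScalingParams",
    "SchemaError",
    "ValidationError",
    "read_field_table",
    "write_field_table",
    "dataset_from_frame",
    "derive_g0g1",
    "scale_descriptors",
    "apply_scaling",
]

#: Canonical descriptor order: one count followed by phase proportions.
DEFAULT_DESCRIPTORS = ("cell_count", "prop_S", "prop_G2", "prop_M", "prop_apoptotic")

#: Proportions are clipped into [eps, 1-eps] on load so beta densities stay finite.
PROPORTION_EPS = 1e-6

#: Pseudo-value replacing a raw zero cell count (gamma support is x > 0).
ZERO_COUNT_REPLACEMENT = 0.5


class SchemaError(ValueError):
    """A required column is missing from the field table."""


class ValidationError(ValueError):
    """A row of the field table holds an invalid value."""


@dataclasses.dataclass
class FieldRecord:
    """One microscope field: descriptor vector plus well/condition identity."""

    condition: str
    well_id: str
    field_index: int
    cell_count: float
    proportions: np.ndarray  # in descriptor order, count excluded
    proportion_names: tuple[str, ...] = DEFAULT_DESCRIPTORS[1:]

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.cell_count <= 0:
            raise ValidationError(
                f"cell_count must be positive after preprocessing, got {self.cell_count}"
            )
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValidationError("proportions must lie in [0, 1]")

    @property
    def descriptor_vector(self) -> np.ndarray:
        """(cell_count, proportions...) as a length-D vector."""
        return np.concatenate(([self.cell_count], self.proportions))


@dataclasses.dataclass
class WellData:
    """All fields recorded in one well (K fields; K=4 on the plates modelled here)."""

    well_id: str
    condition: str
    fields: list[FieldRecord]

    def __post_init__(self) -> None:
        if len(self.fields) < 1:
            raise ValidationError(f"well {self.well_id!r} has no fields")
        for f in self.fields:
            if f.well_id != self.well_id:
                raise ValidationError(
                    f"field with well_id {f.well_id!r} placed in well {self.well_id!r}"
                )

    @property
    def K(self) -> int:
        return len(self.fields)

    def field_matrix(self) -> np.ndarray:
        """K x D matrix of descriptor vectors, ordered by field_index."""
        return np.vstack([f.descriptor_vector for f in self.fields])


@dataclasses.dataclass
class Dataset:
    """Wells of grouped fields -- the unit the well-level likelihood is defined over."""

    wells: list[WellData]
    descriptor_names: tuple[str, ...] = DEFAULT_DESCRIPTORS

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            key = (w.condition, w.well_id)
            if key in seen:
                raise ValidationError(f"duplicate well_id {w.well_id!r} in condition {w.condition!r}")
            seen.add(key)

    @property
    def D(self) -> int:
        return len(self.descriptor_names)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def n_fields(self) -> int:
        return sum(w.K for w in self.wells)

    def field_matrix(self) -> np.ndarray:
        """All fields stacked, n_fields x D, wells in order."""
        return np.vstack([w.field_matrix() for w in self.wells])

    def field_well_index(self) -> np.ndarray:
        """For each stacked field row, the index of its well."""
        return np.repeat(np.arange(self.n_wells), [w.K for w in self.wells])

    def subset(self, well_indices: Sequence[int]) -> "Dataset":
        return Dataset([self.wells[i] for i in well_indices], self.descriptor_names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for f in w.fields:
                row = {"condition": w.condition, "well_id": w.well_id, "field_index": f.field_index}
                row.update(zip(self.descriptor_names, f.descriptor_vector))
                rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class ScalingParams:
    """Per-descriptor center/scale used by :func:`scale_descriptors`."""

    descriptor_names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray


def read_field_table(
    path,
    schema: Mapping[str, str] | None = None,
    descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> Dataset:
    """Read a field-level CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with one header row; comma separated, ``.`` decimal.
    schema
        Optional mapping from canonical column names (``condition``,
        ``well_id``, ``field_index`` and each descriptor) to the names
        used in the file.
    descriptor_names
        Descriptor order; the first entry is the count descriptor.

    Preprocessing applied on load: proportions are clipped to
    ``[1e-6, 1 - 1e-6]`` and zero counts replaced by 0.5 so the
    gamma/beta class-conditional densities are finite.  A proportion
    outside [0, 1] by more than 1e-6 is a validation error.
    """
    frame = pd.read_csv(path)
    schema = dict(schema or {})
    required = ["condition", "well_id", "field_index", *descriptor_names]
    colmap = {name: schema.get(name, name) for name in required}
    for canonical, col in colmap.items():
        if col not in frame.columns:
            raise SchemaError(f"field table is missing column {col!r} (for {canonical!r})")
    renamed = frame.rename(columns={v: k for k, v in colmap.items()})
    return dataset_from_frame(renamed, descriptor_names=descriptor_names)


def dataset_from_frame(
    frame: pd.DataFrame,
    descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> Dataset:
    """Build a Dataset from a canonical-column DataFrame (see read_field_table)."""
    descriptor_names = tuple(descriptor_names)
    count_col = descriptor_names[0]
    prop_cols = list(descriptor_names[1:])

    counts = pd.to_numeric(frame[count_col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(counts) | (counts < 0))
    if bad.size:
        raise ValidationError(
            f"row {bad[0]}: {count_col} is non-numeric or negative ({frame[count_col].iloc[bad[0]]!r})"
        )
    n_zero = int(np.sum(counts == 0))
    counts = np.where(counts == 0, ZERO_COUNT_REPLACEMENT, counts)

    props = np.empty((len(frame), len(prop_cols)))
    for j, col in enumerate(prop_cols):
        vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValidationError(f"row {bad[0]}: {col} is non-numeric")
        out = np.flatnonzero((vals < -1e-6) | (vals > 1 + 1e-6))
        if out.size:
            raise ValidationError(
                f"row {out[0]}: {col} = {vals[out[0]]} outside [0, 1]"
            )
        props[:, j] = np.clip(vals, PROPORTION_EPS, 1 - PROPORTION_EPS)

    if n_zero:
        import logging

        logging.getLogger(__name__).info(
            "replaced %d zero cell counts by %.1f", n_zero, ZERO_COUNT_REPLACEMENT
        )

    wells: list[WellData] = []
    # groupby(sort=False) keeps first-appearance order; rows inside a well
    # are ordered by field_index regardless of file order.
    work = frame[["condition", "well_id", "field_index"]].copy()
    work["cleaned_count"] = counts
    for j, col in enumerate(prop_cols):
        work[f"cleaned_p{j}"] = props[:, j]
    for (condition, well_id), grp in work.groupby(["condition", "well_id"], sort=False):
        grp = grp.sort_values("field_index", kind="stable")
        fields = [
            FieldRecord(
                condition=str(condition),
                well_id=str(well_id),
                field_index=int(r.field_index),
                cell_count=float(r.cleaned_count),
                proportions=np.array([getattr(r, f"cleaned_p{j}") for j in range(len(prop_cols))]),
                proportion_names=tuple(prop_cols),
            )
            for r in grp.itertuples()
        ]
        wells.append(WellData(str(well_id), str(condition), fields))
    wells.sort(key=lambda w: (w.condition, w.well_id))
    return Dataset(wells, descriptor_names)


def write_field_table(dataset: Dataset, path) -> None:
    """Write the standard field-table CSV (same dialect the reader accepts)."""
    dataset.to_frame().to_csv(path, index=False)


def derive_g0g1(record: FieldRecord) -> float:
    """Proportion of cells in G0/G1, deduced as 1 - (S + G2 + M), clipped to [0, 1].

    G0/G1 is a derived reporting quantity (descriptor-association tables),
    never one of the model's D descriptors.  The apoptotic proportion does
    not enter: phases, not viability, partition the cycle here.
    """
    names = record.proportion_names
    idx = {n: i for i, n in enumerate(names)}
    total = sum(record.proportions[idx[n]] for n in ("prop_S", "prop_G2", "prop_M"))
    return float(np.clip(1.0 - total, 0.0, 1.0))


def scale_descriptors(dataset: Dataset) -> tuple[Dataset, ScalingParams]:
    """Center each descriptor to mean 0 and unit sd across all fields.

    Returns the scaled copy together with the scaling parameters so the
    same transform can be reapplied to new data.  Raises on a descriptor
    with zero variance.
    """
    X = dataset.field_matrix()
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 fields to scale")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(std < 1e-15)
    if zero.size:
        raise ValidationError(
            f"descriptor {dataset.descriptor_names[zero[0]]!r} has zero variance"
        )
    params = ScalingParams(dataset.descriptor_names, mean, std)
    return apply_scaling(dataset, params), params


def apply_scaling(dataset: Dataset, params: ScalingParams) -> Dataset:
    """Apply previously computed scaling parameters to a dataset.

    The scaled copy is used only for dispersion analysis and k-means
    initialization; scaled proportions leave [0, 1], so FieldRecord
    validation is bypassed on purpose.
    """
    if tuple(params.descriptor_names) != dataset.descriptor_names:
        raise ValidationError("scaling parameters were computed for different descriptors")
    wells = []
    for w in dataset.wells:
        fields = []
        for f in w.fields:
            vec = (f.descriptor_vector - params.mean) / params.std
            rec = object.__new__(FieldRecord)
            rec.condition = f.condition
            rec.well_id = f.well_id
            rec.field_index = f.field_index
            rec.cell_count = float(vec[0])
            rec.proportions = vec[1:].copy()
            rec.proportion_names = f.proportion_names
            fields.append(rec)
        wells.append(WellData.__new__(WellData))
        wells[-1].well_id = w.well_id
        wells[-1].condition = w.condition
        wells[-1].fields = fields
    out = Dataset.__new__(Dataset)
    out.wells = wells
    out.descriptor_names = dataset.descriptor_names
    return out
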