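"""Core domain model for arrayed 384-well imaging screens.

Single-cell data are kept as plain :class:`pandas.DataFrame` tables with a
documented column schema (one row per segmented cell); this module provides
the well/plate addressing types, the screen design (plate layout) container,
plate-layout construction with pseudo-randomized control placement, CSV
readers/writers, and per-well aggregation.

Column naming convention for intensity features is
``<channel>_<statistic>_<compartment>``, e.g. ``EU_sum_nuclear``.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24
WELLS_PER_PLATE = N_ROWS * N_COLS
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: Metadata columns present in every single-cell table.
META_COLUMNS = ["plate", "row", "col", "well_name", "site", "cell_id"]

#: Upstream segmentation / image-classifier flags consumed by clean-up.
FLAG_COLUMNS = ["is_border", "is_mitotic_or_apoptotic", "is_missegmented"]

#: Morphology features (pixel units).
MORPHOLOGY_COLUMNS = ["nuclear_area", "cell_area", "nucleolar_area", "equivalent_diameter"]

#: Intensity features per channel (arbitrary fluorescence units).
CHANNEL_FEATURES: dict[str, list[str]] = {
    "DAPI": ["DAPI_mean_nuclear", "DAPI_sum_nuclear", "DAPI_sum_cell", "DAPI_texture"],
    "EU": ["EU_mean_nuclear", "EU_sum_nuclear", "EU_sum_nucleolar", "EU_sum_nucleoplasmic"],
    "PCNA": ["PCNA_mean_nuclear", "PCNA_sum_nuclear", "PCNA_texture"],
    "SE": ["SE_mean_nuclear", "SE_sum_nuclear", "SE_sum_cell"],
}

#: Texture features are unitless scalars, not intensities; excluded from
#: intensity normalization steps.
TEXTURE_COLUMNS = ["DAPI_texture", "PCNA_texture"]


def intensity_columns(channels: Iterable[str] = ("DAPI", "EU", "PCNA", "SE")) -> list[str]:
    """All intensity feature columns for the given channels (textures excluded)."""
    cols: list[str] = []
    for ch in channels:
        cols.extend(c for c in CHANNEL_FEATURES[ch] if c not in TEXTURE_COLUMNS)
    return cols


REQUIRED_CELL_COLUMNS = (
    META_COLUMNS
    + FLAG_COLUMNS
    + ["nuclear_area", "cell_area"]
    + intensity_columns(("DAPI", "EU", "PCNA", "SE"))
)


class SchemaError(ValueError):
    """A table is missing required columns."""


class LayoutError(ValueError):
    """A plate-layout configuration is infeasible."""


class ControlRole(str, enum.Enum):
    """Role of a well in the screen design.

    ``scrambled`` is the non-targeting negative control and the reference
    population for all normalization and phenotype baselines.  ``kif11`` is
    the transfection control (knockdown kills cells), ``pim2`` a targeting
    control without an EU phenotype, ``slc25a3`` the positive control with
    increased EU incorporation, ``mock`` transfection reagent without siRNA.
    """

    SCRAMBLED = "scrambled"
    KIF11 = "kif11"
    PIM2 = "pim2"
    SLC25A3 = "slc25a3"
    MOCK = "mock"
    PERTURBATION = "perturbation"


CONTROL_GENE_SYMBOLS = {
    ControlRole.SCRAMBLED: "scrambled",
    ControlRole.KIF11: "KIF11",
    ControlRole.PIM2: "PIM2",
    ControlRole.SLC25A3: "SLC25A3",
    ControlRole.MOCK: "mock",
}


@dataclasses.dataclass(frozen=True, order=True)
class WellAddress:
    """1-based (plate, row, column) address of a 384-well plate well."""

    plate: int
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.plate < 1:
            raise ValueError(f"plate id must be >= 1, got {self.plate}")
        if not 1 <= self.row <= N_ROWS:
            raise ValueError(f"row must be in 1..{N_ROWS}, got {self.row}")
        if not 1 <= self.col <= N_COLS:
            raise ValueError(f"column must be in 1..{N_COLS}, got {self.col}")

    @property
    def well_name(self) -> str:
        return f"{ROW_LETTERS[self.row - 1]}{self.col:02d}"

    @classmethod
    def from_name(cls, plate: int, name: str) -> "WellAddress":
        name = name.strip().upper()
        row = ROW_LETTERS.index(name[0]) + 1
        col = int(name[1:])
        return cls(plate=plate, row=row, col=col)


def well_name(row: int | np.ndarray, col: int | np.ndarray) -> np.ndarray | str:
    """Vectorized (row, col) -> well name, e.g. (2, 3) -> ``"B03"``."""
    if np.isscalar(row):
        return WellAddress(1, int(row), int(col)).well_name
    letters = np.array(list(ROW_LETTERS))
    return np.char.add(
        letters[np.asarray(row) - 1],
        np.char.zfill(np.asarray(col).astype(str), 2),
    )


@dataclasses.dataclass
class LayoutConfig:
    """Per-plate control-well counts.

    Defaults follow the primary-screen plate design: 22 scrambled negative
    controls, 6 KIF11 transfection controls, 8 PIM2 no-phenotype controls,
    8 SLC25A3 positive controls, plus a small number of mock wells.
    """

    scrambled: int = 22
    kif11: int = 6
    pim2: int = 8
    slc25a3: int = 8
    mock: int = 3

    def counts(self) -> dict[ControlRole, int]:
        return {
            ControlRole.SCRAMBLED: self.scrambled,
            ControlRole.KIF11: self.kif11,
            ControlRole.PIM2: self.pim2,
            ControlRole.SLC25A3: self.slc25a3,
            ControlRole.MOCK: self.mock,
        }

    @property
    def n_controls(self) -> int:
        return sum(self.counts().values())


class ScreenDesign:
    """Plate/well -> gene, siRNA, control-role mapping with QC annotations.

    Thin wrapper around a DataFrame with columns
    ``plate,row,col,well_name,gene_symbol,sirna_ids,control_role,qc_annotation``.
    """

    COLUMNS = ["plate", "row", "col", "well_name", "gene_symbol", "sirna_ids",
               "control_role", "qc_annotation"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        dup = table.duplicated(subset=["plate", "row", "col"])
        if dup.any():
            raise ValueError("duplicate well entries in design table")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def plates(self) -> list[int]:
        return sorted(self.table["plate"].unique())

    def role_counts(self, plate: int) -> dict[str, int]:
        sub = self.table[self.table["plate"] == plate]
        return sub["control_role"].value_counts().to_dict()

    def wells_with_role(self, role: ControlRole | str, plate: int | None = None) -> pd.DataFrame:
        role = ControlRole(role).value
        sub = self.table[self.table["control_role"] == role]
        if plate is not None:
            sub = sub[sub["plate"] == plate]
        return sub

    def annotate(self, cells: pd.DataFrame) -> pd.DataFrame:
        """Join gene symbol and control role onto a single-cell table."""
        ann = self.table[["plate", "row", "col", "gene_symbol", "control_role"]]
        return cells.merge(ann, on=["plate", "row", "col"], how="left", validate="m:1")

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["well"] = out["well_name"]
        out[["plate", "well", "gene_symbol", "sirna_ids", "control_role",
             "qc_annotation", "row", "col", "well_name"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScreenDesign":
        raw = pd.read_csv(path, dtype={"qc_annotation": "string",
                                       "sirna_ids": "string"})
        required = ["plate", "well", "gene_symbol", "sirna_ids", "control_role"]
        missing = [c for c in required if c not in raw.columns]
        if missing:
            raise SchemaError(f"library file missing columns: {missing}")
        if "row" not in raw.columns or "col" not in raw.columns:
            raw["row"] = raw["well"].str[0].map({l: i + 1 for i, l in enumerate(ROW_LETTERS)})
            raw["col"] = raw["well"].str[1:].astype(int)
        if "well_name" not in raw.columns:
            raw["well_name"] = raw["well"]
        if "qc_annotation" not in raw.columns:
            raw["qc_annotation"] = ""
        raw["qc_annotation"] = raw["qc_annotation"].fillna("").astype(str)
        raw["sirna_ids"] = raw["sirna_ids"].fillna("").astype(str)
        return cls(raw[cls.COLUMNS])


def make_plate_layout(
    n_plates: int,
    layout: LayoutConfig | None = None,
    seed: int = 0,
    gene_prefix: str = "GENE",
) -> ScreenDesign:
    """Build a screen design with pseudo-randomized control placement.

    Controls are placed at positions drawn independently per plate from a
    generator seeded with ``seed``; identical seeds reproduce identical
    layouts.  Non-control wells receive synthetic gene identifiers, one gene
    per well, numbered consecutively across plates.

    Raises
    ------
    LayoutError
        If the configured control counts exceed the 384 wells of a plate.
    """
    layout = layout or LayoutConfig()
    counts = layout.counts()
    if layout.n_controls > WELLS_PER_PLATE:
        raise LayoutError(
            f"control counts sum to {layout.n_controls} > {WELLS_PER_PLATE} wells per plate"
        )
    rng = np.random.default_rng(seed)
    rows = []
    gene_counter = 0
    for plate in range(1, n_plates + 1):
        positions = [(r, c) for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1)]
        order = rng.permutation(len(positions))
        idx = 0
        roles: dict[tuple[int, int], ControlRole] = {}
        for role, n in counts.items():
            for _ in range(n):
                roles[positions[order[idx]]] = role
                idx += 1
        for r, c in positions:
            role = roles.get((r, c), ControlRole.PERTURBATION)
            if role is ControlRole.PERTURBATION:
                gene_counter += 1
                gene = f"{gene_prefix}{gene_counter:05d}"
                sirnas = ";".join(f"s{gene_counter:05d}{k}" for k in "abc")
            else:
                gene = CONTROL_GENE_SYMBOLS[role]
                sirnas = "" if role is ControlRole.MOCK else f"ctrl_{role.value}"
            rows.append(
                (plate, r, c, WellAddress(plate, r, c).well_name, gene, sirnas,
                 role.value, "")
            )
    table = pd.DataFrame(rows, columns=ScreenDesign.COLUMNS)
    return ScreenDesign(table)


# ---------------------------------------------------------------------------
# Single-cell table I/O


def save_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a single-cell table as UTF-8 CSV with a header row.

    Missing numeric values are written as empty fields.  Floats use the
    shortest round-tripping representation, so write -> read is the identity
    up to float tolerance.
    """
    cells.to_csv(path, index=False)


def load_cell_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a single-cell CSV, validating the schema.

    Parameters
    ----------
    path:
        CSV file with one row per cell and a mandatory header.
    required:
        Columns that must be present; defaults to :data:`REQUIRED_CELL_COLUMNS`
        (EdU columns are optional and only present on EdU plates).

    Unknown columns are preserved as passthrough.  Rows with unparseable
    numeric fields are reported with their file line numbers via a warning
    (values become missing).
    """
    required = list(required) if required is not None else list(REQUIRED_CELL_COLUMNS)
    cells = pd.read_csv(path)
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    numeric = [c for c in required if c not in ("well_name",)]
    bad_lines: set[int] = set()
    for col in numeric:
        if cells[col].dtype == object:
            coerced = pd.to_numeric(cells[col], errors="coerce")
            newly_bad = coerced.isna() & cells[col].notna()
            # +2: header line plus 1-based numbering
            bad_lines.update((np.flatnonzero(newly_bad.to_numpy()) + 2).tolist())
            cells[col] = coerced
    if bad_lines:
        warnings.warn(
            f"{path}: malformed numeric values on lines {sorted(bad_lines)}",
            stacklevel=2,
        )
    for col in FLAG_COLUMNS:
        if col in cells.columns:
            cells[col] = cells[col].astype(bool)
    return cells


# ---------------------------------------------------------------------------
# Well aggregation


PHASES = ["G1", "S", "G2"]


def aggregate_wells(
    cells: pd.DataFrame,
    phenotype_cols: Sequence[str] = ("residual_mean_eu", "residual_sum_eu"),
    median_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate a single-cell table to one summary row per (plate, well).

    Produces cell counts, the mean of each per-cell phenotype column present
    (``mean_<col>``), cell-cycle phase fractions when a ``phase`` column is
    present, and per-well medians of intensity columns.  Wells whose cells
    were all filtered upstream simply do not appear (they carry no rows);
    callers that need explicit zero-count rows can reindex on the design.
    """
    keys = ["plate", "row", "col"]
    g = cells.groupby(keys, sort=True)
    out = g.size().rename("n_cells").reset_index()
    for col in phenotype_cols:
        if col in cells.columns:
            m = g[col].mean().rename(f"mean_{col}").reset_index(drop=True)
            out[f"mean_{col}"] = m
    if "phase" in cells.columns:
        frac = (
            cells.pivot_table(index=keys, columns="phase", values="cell_id",
                              aggfunc="count", fill_value=0)
            .reindex(columns=PHASES, fill_value=0)
        )
        frac = frac.div(frac.sum(axis=1), axis=0)
        frac.columns = [f"frac_{p}" for p in PHASES]
        out = out.merge(frac.reset_index(), on=keys, how="left")
    if median_cols is None:
        median_cols = [c for c in intensity_columns() if c in cells.columns]
    for col in median_cols:
        out[f"median_{col}"] = g[col].median().to_numpy()
    out["well_name"] = well_name(out["row"].to_numpy(), out["col"].to_numpy())
    if "gene_symbol" in cells.columns:
        gene = g[["gene_symbol"]].first().reset_index(drop=True)
        out["gene_symbol"] = gene["gene_symbol"]
    if "control_role" in cells.columns:
        out["control_role"] = g[["control_role"]].first().reset_index(drop=True)["control_role"]
    return out
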