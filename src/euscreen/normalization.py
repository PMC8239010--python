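"""Staining-bias normalization.

Four stages, mirroring the analysis order of an arrayed imaging screen:

1. background subtraction with a channel-specific constant;
2. additive row/column staining-bias correction,
   ``I_corrected = I_raw + 2*I_p - I_{p,r} - I_{p,c}``
   with I_p, I_{p,r}, I_{p,c} the medians over all cells of plate p, row r
   and column c (DAPI/PCNA/SE only in primary-screen mode; the EU channel is
   deliberately left uncorrected, and secondary-screen mode corrects
   nothing);
3. plate-wise multiplicative median rescaling to equalize scrambled-control
   medians across plates, with outlier control wells excluded from factor
   estimation by a 1.5*IQR boxplot rule;
4. z-standardization of nucleolar features against each plate's scrambled
   control cells (plate-dependent nucleolar staining bias is not removed by
   median rescaling alone).

All corrected intensities may legitimately be negative; nothing here clips.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_model import ControlRole, ScreenDesign, intensity_columns

#: Channels that receive the additive row/column correction in the primary
#: screen.  EU is excluded: correcting it increases replicate variability
#: because true perturbation effects dominate its row/column structure.
PRIMARY_ROWCOL_CHANNELS = ("DAPI", "PCNA", "SE")

#: Nucleolar features standardized to plate controls.
NUCLEOLAR_FEATURES = ("EU_sum_nucleolar", "EU_sum_nucleoplasmic", "nucleolar_area")


class NormalizationError(ValueError):
    pass


@dataclasses.dataclass
class NormalizationContext:
    """Fitted normalization statistics, persistable as CSV for audit."""

    plate_medians: pd.DataFrame | None = None      # plate, feature, median
    row_medians: pd.DataFrame | None = None        # plate, row, feature, median
    col_medians: pd.DataFrame | None = None        # plate, col, feature, median
    rescale_factors: pd.DataFrame | None = None    # plate, feature, factor
    nucleolar_stats: pd.DataFrame | None = None    # plate, feature, mean, sd
    rowcol_channels: tuple[str, ...] = PRIMARY_ROWCOL_CHANNELS

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("plate_medians", "row_medians", "col_medians",
                     "rescale_factors", "nucleolar_stats"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(directory / f"context_{name}.csv", index=False)


def subtract_background(
    cells: pd.DataFrame,
    constants: Mapping[str, float],
    channels: Iterable[str] = ("DAPI", "EU", "PCNA", "SE"),
) -> pd.DataFrame:
    """Subtract a channel-specific constant from every intensity feature.

    ``constants`` maps channel name to the background value; a missing
    channel is a configuration error.  Results may go negative.
    """
    channels = list(channels)
    missing = [ch for ch in channels if ch not in constants]
    if missing:
        raise NormalizationError(f"no background constant for channels: {missing}")
    out = cells.copy()
    for ch in channels:
        for col in intensity_columns((ch,)):
            if col in out.columns:
                out[col] = out[col] - constants[ch]
    return out


def rowcol_correct(
    cells: pd.DataFrame,
    features: Sequence[str] | None = None,
    context: NormalizationContext | None = None,
) -> tuple[pd.DataFrame, NormalizationContext]:
    """Remove additive row/column staining biases per plate.

    For each feature, each cell's value becomes
    ``raw + 2*I_p - I_{p,r} - I_{p,c}`` where the three terms are medians
    of that feature over all cells of the cell's plate, row and column.
    A purely additive row+column bias on a full grid is removed exactly.
    """
    if features is None:
        features = [c for c in intensity_columns(PRIMARY_ROWCOL_CHANNELS)
                    if c in cells.columns]
    context = context or NormalizationContext()
    out = cells.copy()
    p = out.groupby("plate")[list(features)].transform("median")
    pr = out.groupby(["plate", "row"])[list(features)].transform("median")
    pc = out.groupby(["plate", "col"])[list(features)].transform("median")
    for f in features:
        out[f] = out[f] + 2.0 * p[f] - pr[f] - pc[f]
    context.plate_medians = (cells.groupby("plate")[list(features)].median()
                             .reset_index().melt("plate", var_name="feature",
                                                 value_name="median"))
    context.row_medians = (cells.groupby(["plate", "row"])[list(features)].median()
                           .reset_index().melt(["plate", "row"], var_name="feature",
                                               value_name="median"))
    context.col_medians = (cells.groupby(["plate", "col"])[list(features)].median()
                           .reset_index().melt(["plate", "col"], var_name="feature",
                                               value_name="median"))
    return out, context


def _control_mask(cells: pd.DataFrame, design: ScreenDesign) -> pd.Series:
    ctrl = design.wells_with_role(ControlRole.SCRAMBLED)[["plate", "row", "col"]]
    key = pd.MultiIndex.from_frame(cells[["plate", "row", "col"]])
    return pd.Series(key.isin(pd.MultiIndex.from_frame(ctrl)), index=cells.index)


def plate_rescale(
    cells: pd.DataFrame,
    design: ScreenDesign,
    features: Sequence[str] | None = None,
    iqr_k: float = 1.5,
    context: NormalizationContext | None = None,
) -> tuple[pd.DataFrame, NormalizationContext]:
    """Equalize plate-wise scrambled-control medians by multiplicative rescaling.

    Per feature and plate the control median is computed over all cells in
    scrambled wells, after dropping outlier control wells whose well median
    falls outside ``[Q1 - iqr_k*IQR, Q3 + iqr_k*IQR]`` of that plate's
    control-well medians (outliers are excluded from factor estimation only,
    their cells are still rescaled).  Every value on the plate is multiplied
    by ``target / plate control median`` with the target the median of the
    plate control medians, so control medians match across plates exactly.
    """
    if features is None:
        features = [c for c in intensity_columns() if c in cells.columns]
    context = context or NormalizationContext()
    is_ctrl = _control_mask(cells, design)
    out = cells.copy()
    factor_rows = []
    for f in features:
        plate_medians: dict[int, float] = {}
        for plate, sub in cells[is_ctrl].groupby("plate"):
            wm = sub.groupby(["row", "col"])[f].median()
            if len(wm) < 3:
                raise NormalizationError(
                    f"plate {plate}: fewer than 3 scrambled control wells")
            q1, q3 = wm.quantile([0.25, 0.75])
            iqr = q3 - q1
            keep_wells = wm[(wm >= q1 - iqr_k * iqr) & (wm <= q3 + iqr_k * iqr)].index
            kept = sub.set_index(["row", "col"]).loc[list(keep_wells), f]
            med = float(kept.median())
            if med <= 0:
                raise NormalizationError(
                    f"plate {plate}, feature {f}: control median {med} <= 0; "
                    "cannot rescale multiplicatively")
            plate_medians[plate] = med
        target = float(np.median(list(plate_medians.values())))
        for plate, med in plate_medians.items():
            factor = target / med
            out.loc[out["plate"] == plate, f] *= factor
            factor_rows.append((plate, f, factor))
    context.rescale_factors = pd.DataFrame(
        factor_rows, columns=["plate", "feature", "factor"])
    return out, context


def standardize_nucleolar(
    cells: pd.DataFrame,
    design: ScreenDesign,
    features: Sequence[str] = NUCLEOLAR_FEATURES,
    context: NormalizationContext | None = None,
) -> tuple[pd.DataFrame, NormalizationContext]:
    """z-score nucleolar features against each plate's scrambled control cells.

    ``z = (value - plate control mean) / plate control sd`` for every cell of
    the plate.  A zero control sd makes the feature undefined (missing) on
    that plate, with a warning.
    """
    features = [f for f in features if f in cells.columns]
    context = context or NormalizationContext()
    is_ctrl = _control_mask(cells, design)
    out = cells.copy()
    stat_rows = []
    for plate, sub in cells.groupby("plate"):
        ctrl = sub[is_ctrl.loc[sub.index]]
        if len(ctrl) < 2:
            raise NormalizationError(
                f"plate {plate}: fewer than 2 scrambled control cells")
        for f in features:
            mean = float(ctrl[f].mean())
            sd = float(ctrl[f].std(ddof=1))
            stat_rows.append((plate, f, mean, sd))
            mask = out["plate"] == plate
            if sd == 0:
                warnings.warn(f"plate {plate}, feature {f}: zero control sd; "
                              "feature set to missing on this plate")
                out.loc[mask, f] = np.nan
            else:
                out.loc[mask, f] = (out.loc[mask, f] - mean) / sd
    context.nucleolar_stats = pd.DataFrame(
        stat_rows, columns=["plate", "feature", "mean", "sd"])
    return out, context


def normalize(
    cells: pd.DataFrame,
    design: ScreenDesign,
    mode: str = "primary",
    background: Mapping[str, float] | None = None,
    iqr_k: float = 1.5,
    standardize_nucleolar_features: bool = True,
) -> tuple[pd.DataFrame, NormalizationContext]:
    """Full normalization: background -> row/column -> plate rescale -> nucleolar z.

    ``mode='primary'`` applies the row/column correction to DAPI/PCNA/SE (never
    EU); ``mode='secondary'`` applies it to no channel at all.
    """
    if mode not in ("primary", "secondary"):
        raise ValueError(f"mode must be 'primary' or 'secondary', got {mode!r}")
    background = background or {ch: 0.0 for ch in ("DAPI", "EU", "PCNA", "SE")}
    out = subtract_background(cells, background)
    context = NormalizationContext(
        rowcol_channels=PRIMARY_ROWCOL_CHANNELS if mode == "primary" else ())
    if mode == "primary":
        out, context = rowcol_correct(out, context=context)
    out, context = plate_rescale(out, design, iqr_k=iqr_k, context=context)
    if standardize_nucleolar_features:
        out, context = standardize_nucleolar(out, design, context=context)
    return out, context
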