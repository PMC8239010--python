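"""Single-cell and site-level exclusion rules.

Implements the screen's data clean-up: border cells, cells with substantial
cytoplasmic DAPI (segmentation spill), extreme-DAPI outliers (unsplit
nuclei), upstream missegmentation / mitotic-apoptotic flags, and automated
detection of partially out-of-focus imaging sites.  Each removed cell is
counted exactly once, in the first matching category of a fixed precedence
order, and the accounting is returned as a :class:`CleanupReport`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

#: Category order used to attribute multiply-flagged cells.
PRECEDENCE = (
    "acquisition_errors",
    "border",
    "cytoplasmic_dapi",
    "dapi_outliers",
    "missegmented",
    "mitotic_apoptotic",
    "out_of_focus",
)

_FLAG_FOR_CATEGORY = {
    "acquisition_errors": "is_acquisition_error",
    "border": "flag_border",
    "cytoplasmic_dapi": "flag_cytoplasmic_dapi",
    "dapi_outliers": "flag_dapi_outlier",
    "missegmented": "is_missegmented",
    "mitotic_apoptotic": "is_mitotic_or_apoptotic",
    "out_of_focus": "flag_out_of_focus",
}


class DataIntegrityError(ValueError):
    """Input values violate a physical constraint (e.g. nuclear > cell signal)."""


@dataclasses.dataclass
class CleanupReport:
    """Cells removed per clean-up stage; mirrors the screen's accounting table."""

    total: int
    counts: dict[str, int]
    remaining: int

    def __post_init__(self) -> None:
        assert self.remaining == self.total - sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total)]
        rows += [(k, self.counts.get(k, 0)) for k in PRECEDENCE]
        rows.append(("remaining", self.remaining))
        return pd.DataFrame(rows, columns=["category", "n_cells"])


def flag_border_cells(cells: pd.DataFrame) -> pd.Series:
    """Cells touching an imaging-site border (upstream segmentation flag)."""
    return cells["is_border"].astype(bool).rename("flag_border")


def flag_cytoplasmic_dapi(cells: pd.DataFrame, max_fraction: float = 0.20) -> pd.Series:
    """Cells with more than ``max_fraction`` of their DAPI signal outside the nucleus.

    The boundary is non-inclusive: a cell at exactly the threshold is kept.
    Cells with zero whole-cell DAPI are flagged as invalid.
    """
    sum_cell = cells["DAPI_sum_cell"].to_numpy(float)
    sum_nuc = cells["DAPI_sum_nuclear"].to_numpy(float)
    cyto = sum_cell - sum_nuc
    if np.any(cyto < -1e-9 * np.abs(sum_cell)):
        raise DataIntegrityError("nuclear DAPI exceeds whole-cell DAPI for some cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(sum_cell > 0, cyto / sum_cell, np.inf)
    return pd.Series(frac > max_fraction, index=cells.index, name="flag_cytoplasmic_dapi")


def flag_dapi_outliers(cells: pd.DataFrame, k: float = 4.0) -> pd.Series:
    """Cells whose sum nuclear DAPI exceeds mean + k*sd of their plate.

    The mean and sd are computed per plate over non-border, non-mitotic
    cells (the populations those rules have not already condemned); the
    resulting threshold is applied to every cell of the plate.
    """
    flag = pd.Series(False, index=cells.index, name="flag_dapi_outlier")
    for plate, sub in cells.groupby("plate"):
        scope = sub.loc[~sub["is_border"].astype(bool)
                        & ~sub["is_mitotic_or_apoptotic"].astype(bool),
                        "DAPI_sum_nuclear"]
        if len(scope) < 2:
            warnings.warn(f"plate {plate}: <2 cells in DAPI-outlier scope; no flags")
            continue
        thr = scope.mean() + k * scope.std(ddof=1)
        flag.loc[sub.index] = sub["DAPI_sum_nuclear"] > thr
    return flag


def detect_out_of_focus_sites(
    cells: pd.DataFrame,
    well_range_threshold: float = 1.5,
    mad_factor: float = 3.0,
    deviation_floor: float | None = None,
    channels: tuple[str, str] = ("DAPI_mean_nuclear", "PCNA_mean_nuclear"),
) -> pd.DataFrame:
    """Find partially out-of-focus imaging sites.

    Per well, the mean of single-cell DAPI and PCNA mean intensities is
    computed per site.  A well whose site-mean range (max - min) exceeds
    ``well_range_threshold`` in either channel is 'z-range affected'; within
    such wells, sites deviating from the well's median site value by more
    than ``mad_factor`` times the raw median absolute deviation of the site
    means, in *both* channels, are excluded.  The deviation must also exceed
    ``deviation_floor`` (default: half the well-range threshold) so that
    wells whose site means are all tightly clustered cannot lose a site to a
    vanishing MAD.  Single-site wells are never flagged.

    Returns a DataFrame of excluded ``plate,row,col,site`` rows.
    """
    if deviation_floor is None:
        deviation_floor = well_range_threshold / 2.0
    keys = ["plate", "row", "col"]
    site_means = (cells.groupby(keys + ["site"])[list(channels)]
                  .mean().reset_index())
    out = []
    for well, sm in site_means.groupby(keys):
        if len(sm) < 2:
            continue
        ranges = sm[list(channels)].max() - sm[list(channels)].min()
        if not (ranges > well_range_threshold).any():
            continue
        bad = np.ones(len(sm), bool)
        for ch in channels:
            v = sm[ch].to_numpy()
            med = np.median(v)
            mad = median_abs_deviation(v)
            dev = np.abs(v - med)
            bad &= (dev > mad_factor * mad) & (dev > deviation_floor)
        out.append(sm.loc[bad, keys + ["site"]])
    if not out:
        return pd.DataFrame(columns=keys + ["site"])
    return pd.concat(out, ignore_index=True)


def flag_out_of_focus(cells: pd.DataFrame, oof_sites: pd.DataFrame) -> pd.Series:
    """Boolean per-cell flag from a set of excluded (plate, well, site) rows."""
    keys = ["plate", "row", "col", "site"]
    if len(oof_sites) == 0:
        return pd.Series(False, index=cells.index, name="flag_out_of_focus")
    bad = pd.MultiIndex.from_frame(oof_sites[keys])
    key = pd.MultiIndex.from_frame(cells[keys])
    return pd.Series(key.isin(bad), index=cells.index, name="flag_out_of_focus")


def compute_flags(
    cells: pd.DataFrame,
    max_cytoplasmic_fraction: float = 0.20,
    dapi_outlier_k: float = 4.0,
    well_range_threshold: float = 1.5,
    mad_factor: float = 3.0,
) -> pd.DataFrame:
    """All clean-up flag columns, plus the excluded-site table as ``.attrs``."""
    flags = pd.DataFrame(index=cells.index)
    if "is_acquisition_error" in cells.columns:
        flags["is_acquisition_error"] = cells["is_acquisition_error"].astype(bool)
    flags["flag_border"] = flag_border_cells(cells)
    flags["flag_cytoplasmic_dapi"] = flag_cytoplasmic_dapi(cells, max_cytoplasmic_fraction)
    flags["flag_dapi_outlier"] = flag_dapi_outliers(cells, dapi_outlier_k)
    flags["is_missegmented"] = cells["is_missegmented"].astype(bool)
    flags["is_mitotic_or_apoptotic"] = cells["is_mitotic_or_apoptotic"].astype(bool)
    # site-level detection runs on cells surviving the per-cell rules, so the
    # statistic's scope is stable under re-application of the clean-up
    surviving = ~flags.any(axis=1)
    oof_sites = detect_out_of_focus_sites(
        cells.loc[surviving], well_range_threshold=well_range_threshold,
        mad_factor=mad_factor)
    flags["flag_out_of_focus"] = flag_out_of_focus(cells, oof_sites)
    flags.attrs["oof_sites"] = oof_sites
    return flags


def apply_cleanup(
    cells: pd.DataFrame,
    flags: pd.DataFrame,
) -> tuple[pd.DataFrame, CleanupReport]:
    """Remove all flagged cells; account for each removal exactly once.

    A cell matching several rules is counted under the earliest category in
    :data:`PRECEDENCE`.  Conservation holds by construction:
    ``remaining = total - sum(category counts)``.
    """
    total = len(cells)
    assigned = pd.Series(False, index=cells.index)
    counts: dict[str, int] = {}
    for category in PRECEDENCE:
        col = _FLAG_FOR_CATEGORY[category]
        if col not in flags.columns:
            counts[category] = 0
            continue
        hit = flags[col].astype(bool) & ~assigned
        counts[category] = int(hit.sum())
        assigned |= hit
    kept = cells.loc[~assigned].copy()
    report = CleanupReport(total=total, counts=counts, remaining=len(kept))
    return kept, report


def clean(cells: pd.DataFrame, **kwargs) -> tuple[pd.DataFrame, CleanupReport]:
    """Convenience: compute all flags and apply them in one call."""
    flags = compute_flags(cells, **kwargs)
    return apply_cleanup(cells, flags)
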