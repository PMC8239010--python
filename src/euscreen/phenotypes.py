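"""RNA-production-rate phenotypes.

Two per-cell phenotypes quantify how much a perturbed cell's nascent-RNA
(EU) signal deviates from an unperturbed cell in a comparable state:

* ``residual_mean_eu`` — mean nuclear EU minus the screen-wide scrambled
  control mean for the cell's cycle phase.  Mean nuclear intensity divides
  by nuclear area and therefore accounts for cell size only indirectly,
  through nuclear-size scaling.
* ``residual_sum_eu`` — sum nuclear EU minus the prediction of a linear
  model (cell size, measured as whole-cell sum SE protein stain, plus phase
  indicators) fitted plate-wise to scrambled control cells.  This phenotype
  is directly corrected for cell size, so size-driven and rate-driven
  changes in EU separate.

Well-level phenotypes are the per-well means of these residuals
(``mean_residual_mean_eu``, ``mean_residual_sum_eu``), produced by
:func:`euscreen.screen_model.aggregate_wells`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .screen_model import ControlRole, ScreenDesign

PHASES = ("G1", "S", "G2")


class PhenotypeError(ValueError):
    pass


def _control_cells(cells: pd.DataFrame, design: ScreenDesign) -> pd.DataFrame:
    ctrl = design.wells_with_role(ControlRole.SCRAMBLED)[["plate", "row", "col"]]
    key = pd.MultiIndex.from_frame(cells[["plate", "row", "col"]])
    return cells[key.isin(pd.MultiIndex.from_frame(ctrl))]


def compute_phase_means(cells: pd.DataFrame, design: ScreenDesign) -> dict[str, float]:
    """Screen-wide mean of mean-nuclear EU per phase over pooled scrambled cells."""
    ctrl = _control_cells(cells, design)
    means: dict[str, float] = {}
    for phase in PHASES:
        sub = ctrl.loc[ctrl["phase"] == phase, "EU_mean_nuclear"]
        if len(sub) == 0:
            raise PhenotypeError(f"no scrambled control cells in phase {phase}")
        means[phase] = float(sub.mean())
    return means


def residual_mean_eu(cells: pd.DataFrame, phase_means: Mapping[str, float]) -> pd.Series:
    """Per-cell residual of mean nuclear EU against its phase's control mean.

    Cells without an assigned phase are skipped (missing residual) with a
    warning.
    """
    phase = cells["phase"]
    missing = phase.isna() | ~phase.isin(list(phase_means))
    if missing.any():
        warnings.warn(f"{int(missing.sum())} cells without phase; residual left missing")
    baseline = phase.map(dict(phase_means))
    res = cells["EU_mean_nuclear"] - baseline.astype(float)
    return res.rename("residual_mean_eu")


@dataclasses.dataclass
class SizeModel:
    """Per-plate OLS of sum nuclear EU on cell size and cycle phase.

    Design matrix: intercept + SE_sum_cell + indicator(S) + indicator(G2)
    (G1 is the reference phase).
    """

    coefficients: pd.DataFrame  # plate, term, estimate, stderr
    per_plate: bool = True

    TERMS = ("intercept", "size", "phase_S", "phase_G2")

    def params(self, plate: int) -> np.ndarray:
        sub = self.coefficients[self.coefficients["plate"] == plate]
        if len(sub) == 0:
            raise PhenotypeError(f"no size model fitted for plate {plate}")
        return sub.set_index("term").loc[list(self.TERMS), "estimate"].to_numpy()

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(cells)
        pred = np.empty(len(cells))
        for plate, sub in cells.groupby("plate"):
            beta = self.params(int(plate))
            loc = cells.index.get_indexer(sub.index)
            pred[loc] = X[loc] @ beta
        return pred


def _design_matrix(cells: pd.DataFrame) -> np.ndarray:
    phase = cells["phase"].to_numpy()
    return np.column_stack([
        np.ones(len(cells)),
        cells["SE_sum_cell"].to_numpy(float),
        (phase == "S").astype(float),
        (phase == "G2").astype(float),
    ])


def fit_size_model(
    cells: pd.DataFrame,
    design: ScreenDesign,
    per_plate: bool = True,
    min_control_cells: int = 100,
) -> SizeModel:
    """Fit the control-cell EU ~ size + phase regression.

    ``per_plate=True`` (default) fits one model on each plate's scrambled
    cells; ``False`` fits a single screen-wide model applied to every plate.
    Raises on plates with too few control cells or with fewer than two
    phases represented (rank-deficient design).
    """
    ctrl = _control_cells(cells, design)
    groups = ctrl.groupby("plate") if per_plate else [(None, ctrl)]
    rows = []
    plates = sorted(cells["plate"].unique())
    for plate, sub in groups:
        if len(sub) < min_control_cells:
            raise PhenotypeError(
                f"plate {plate}: {len(sub)} control cells < {min_control_cells}")
        if sub["phase"].nunique() < 2:
            raise PhenotypeError(
                f"plate {plate}: single-phase controls make the design rank-deficient")
        X = _design_matrix(sub)
        fit = sm.OLS(sub["EU_sum_nuclear"].to_numpy(float), X).fit()
        target_plates = [int(plate)] if per_plate else [int(p) for p in plates]
        for p in target_plates:
            for term, est, se in zip(SizeModel.TERMS, fit.params, fit.bse):
                rows.append((p, term, float(est), float(se)))
    return SizeModel(
        coefficients=pd.DataFrame(rows, columns=["plate", "term", "estimate", "stderr"]),
        per_plate=per_plate)


def residual_sum_eu(cells: pd.DataFrame, size_model: SizeModel) -> pd.Series:
    """Per-cell residual of sum nuclear EU against the size+phase prediction."""
    pred = size_model.predict(cells)
    return (cells["EU_sum_nuclear"] - pred).rename("residual_sum_eu")


def compute_phenotypes(
    cells: pd.DataFrame,
    design: ScreenDesign,
    per_plate: bool = True,
) -> pd.DataFrame:
    """Attach both residual phenotype columns to a phase-annotated cell table."""
    out = cells.copy()
    phase_means = compute_phase_means(out, design)
    out["residual_mean_eu"] = residual_mean_eu(out, phase_means)
    model = fit_size_model(out, design, per_plate=per_plate)
    out["residual_sum_eu"] = residual_sum_eu(out, model)
    return out
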