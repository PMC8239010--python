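"""Screen-quality statistics and control-uniformity reporting.

SSMD (strictly standardized mean difference) grades moderate-strength
positive controls; the Z' factor grades strong ones.  Both use the
method-of-moments estimators on well-level values with sample (n-1)
variances.  The uniformity report quantifies well-to-well control
variability per plate (IQR of control-well values normalized by the plate
median) and compares mock/PIM2 controls against scrambled.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .screen_model import ControlRole, ScreenDesign


class QCError(ValueError):
    pass


def ssmd(pos: Sequence[float] | np.ndarray, neg: Sequence[float] | np.ndarray) -> float:
    """Strictly standardized mean difference (mu_p - mu_n)/sqrt(s_p^2 + s_n^2)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if len(pos) < 2 or len(neg) < 2:
        raise QCError("SSMD requires at least 2 values per group")
    vp, vn = pos.var(ddof=1), neg.var(ddof=1)
    if vp == 0 and vn == 0:
        raise QCError("both group variances are zero")
    return float((pos.mean() - neg.mean()) / np.sqrt(vp + vn))


def z_prime(pos: Sequence[float] | np.ndarray, neg: Sequence[float] | np.ndarray) -> float:
    """Z' factor 1 - 3(sd_p + sd_n)/|mu_p - mu_n| (may be negative)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if len(pos) < 2 or len(neg) < 2:
        raise QCError("Z' requires at least 2 values per group")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        raise QCError("Z' undefined for equal group means")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta)


def replicate_correlation(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    value_col: str,
    on: str | Sequence[str] = "gene",
) -> float:
    """Pearson r of a phenotype over conditions shared by two summaries.

    Conditions are matched on ``on``; pairs with a missing value in either
    summary are dropped.  Requires at least 3 shared conditions.
    """
    on = [on] if isinstance(on, str) else list(on)
    merged = summary_a[on + [value_col]].merge(
        summary_b[on + [value_col]], on=on, suffixes=("_a", "_b"))
    merged = merged.dropna(subset=[f"{value_col}_a", f"{value_col}_b"])
    if len(merged) < 3:
        raise QCError(f"only {len(merged)} shared conditions (< 3)")
    r, _ = pearsonr(merged[f"{value_col}_a"], merged[f"{value_col}_b"])
    return float(r)


@dataclasses.dataclass
class QCReport:
    """Per-plate control statistics."""

    uniformity: pd.DataFrame        # plate, feature, normalized IQR of control wells
    cell_counts: pd.DataFrame       # plate, role, median/IQR of cells per well
    control_phenotypes: pd.DataFrame  # plate, role, mean phenotype vs scrambled


def normalized_control_iqr(
    well_summary: pd.DataFrame,
    features: Sequence[str],
    role_col: str = "control_role",
) -> pd.DataFrame:
    """IQR of scrambled-control well values per plate, / the plate median.

    This is the well-to-well staining variability measure that should shrink
    when row/column biases are removed.
    """
    rows = []
    for plate, sub in well_summary.groupby("plate"):
        ctrl = sub[sub[role_col] == ControlRole.SCRAMBLED.value]
        for f in features:
            q1, q3 = ctrl[f].quantile([0.25, 0.75])
            plate_median = sub[f].median()
            norm = (q3 - q1) / plate_median if plate_median != 0 else np.nan
            rows.append((plate, f, float(norm)))
    return pd.DataFrame(rows, columns=["plate", "feature", "normalized_iqr"])


def control_uniformity_report(
    well_summary: pd.DataFrame,
    design: ScreenDesign | None = None,
    features: Sequence[str] | None = None,
    phenotype_col: str = "mean_residual_mean_eu",
    role_col: str = "control_role",
) -> QCReport:
    """Control-uniformity QC on a well-summary table.

    Reports (1) normalized IQR of scrambled-control well medians per
    intensity feature and plate, (2) cell-count summaries for KIF11 vs
    scrambled wells per plate (transfection efficacy), and (3) per-plate
    mean phenotype of each control role relative to scrambled (mock and
    PIM2 should sit at zero).
    """
    if features is None:
        features = [c for c in well_summary.columns if c.startswith("median_")]
    uniformity = normalized_control_iqr(well_summary, features, role_col)

    count_rows = []
    pheno_rows = []
    for plate, sub in well_summary.groupby("plate"):
        scram = sub[sub[role_col] == ControlRole.SCRAMBLED.value]
        for role, grp in sub.groupby(role_col):
            q1, q3 = grp["n_cells"].quantile([0.25, 0.75])
            count_rows.append((plate, role, float(grp["n_cells"].median()),
                               float(q3 - q1), len(grp)))
            if phenotype_col in sub.columns and len(scram):
                delta = grp[phenotype_col].mean() - scram[phenotype_col].mean()
                pheno_rows.append((plate, role, float(grp[phenotype_col].mean()),
                                   float(delta)))
    cell_counts = pd.DataFrame(
        count_rows, columns=["plate", "role", "median_n_cells", "iqr_n_cells", "n_wells"])
    control_phenotypes = pd.DataFrame(
        pheno_rows, columns=["plate", "role", "mean_phenotype", "delta_vs_scrambled"])
    return QCReport(uniformity=uniformity, cell_counts=cell_counts,
                    control_phenotypes=control_phenotypes)
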