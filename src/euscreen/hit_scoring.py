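"""Hit annotation and Bayesian reproducibility scoring.

A condition is a *putative* hit in one screen when its well phenotype falls
below the 1st or above the 99th percentile of the scrambled-control
distribution of that screen, and a *reproducible* hit (class c = -1 down,
+1 up, 0 otherwise) when the directional annotation agrees in both the
primary and the secondary screen.  The posterior probability that a
condition with primary phenotype v is reproducible,

    P(c | v) = P(c) * P(v | c) / P(v),

is estimated with class priors equal to class fractions among conditions
assayed in both screens, Gaussian kernel density estimates for the
class-conditional likelihoods P(v | c), and an evidence term that is either
the prior-weighted mixture of the class KDEs (default; posteriors then sum
to one exactly) or a separate unconditional KDE of v (``evidence=
'empirical'``).  Categorical calls use a posterior cutoff (default 0.85)
and exclude low-viability conditions (< 500 cells).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .screen_model import ControlRole

CLASSES = (-1, 0, 1)
CLASS_NAMES = {-1: "down", 0: "non", 1: "up"}


class HitScoringError(ValueError):
    pass


def percentile_thresholds(
    well_summary: pd.DataFrame,
    value_col: str,
    role_col: str = "control_role",
) -> tuple[float, float]:
    """1st/99th percentiles of scrambled-control well phenotypes.

    Only scrambled wells enter; adding or removing perturbation wells leaves
    the thresholds untouched.  Warns below 100 control wells (the empirical
    1st percentile is poorly determined there).
    """
    ctrl = well_summary.loc[
        well_summary[role_col] == ControlRole.SCRAMBLED.value, value_col].dropna()
    if len(ctrl) == 0:
        raise HitScoringError("no scrambled control wells in summary")
    if len(ctrl) < 100:
        warnings.warn(f"only {len(ctrl)} control wells; percentile thresholds are noisy")
    low, high = np.percentile(ctrl.to_numpy(float), [1.0, 99.0])
    if low == high:
        warnings.warn("degenerate control distribution: low == high threshold")
    return float(low), float(high)


def annotate_putative(values: pd.Series | np.ndarray,
                      thresholds: tuple[float, float]) -> np.ndarray:
    """Directional putative-hit class per condition: v < low -> -1, v > high -> +1.

    Boundaries are inclusive to non-hit (a value exactly at a threshold is 0).
    """
    low, high = thresholds
    v = np.asarray(values, float)
    cls = np.zeros(len(v), dtype=int)
    cls[v < low] = -1
    cls[v > high] = 1
    return cls


def reproducible_class(primary_cls: np.ndarray, secondary_cls: np.ndarray) -> np.ndarray:
    """c = +/-1 iff the putative class is identical and nonzero in both screens."""
    primary_cls = np.asarray(primary_cls, int)
    secondary_cls = np.asarray(secondary_cls, int)
    return np.where((primary_cls == secondary_cls) & (primary_cls != 0),
                    primary_cls, 0)


@dataclasses.dataclass
class HitPosteriorModel:
    """Priors + class-conditional KDEs over the primary phenotype v."""

    priors: dict[int, float]
    kdes: dict[int, gaussian_kde | None]
    evidence: str = "mixture"            # 'mixture' or 'empirical'
    evidence_kde: gaussian_kde | None = None
    cutoff: float = 0.85
    thresholds: tuple[float, float] | None = None

    def likelihood(self, v: np.ndarray, c: int) -> np.ndarray:
        kde = self.kdes[c]
        if kde is None:
            return np.zeros(len(v))
        return kde(v)

    def posterior(self, values: Sequence[float] | np.ndarray) -> pd.DataFrame:
        """P(c | v) for each class, columns ``down``, ``non``, ``up``."""
        v = np.asarray(values, float)
        joint = {c: self.priors[c] * self.likelihood(v, c) for c in CLASSES}
        if self.evidence == "mixture":
            total = sum(joint.values())
            with np.errstate(invalid="ignore", divide="ignore"):
                post = {c: np.where(total > 0, joint[c] / total, 0.0) for c in CLASSES}
        else:
            ev = self.evidence_kde(v)
            with np.errstate(invalid="ignore", divide="ignore"):
                post = {c: np.where(ev > 0, joint[c] / ev, 0.0) for c in CLASSES}
        return pd.DataFrame({CLASS_NAMES[c]: post[c] for c in CLASSES})


def fit_posterior(
    primary_v: Sequence[float] | np.ndarray,
    reproducible_c: Sequence[int] | np.ndarray,
    bw_method: str | float = "silverman",
    evidence: str = "mixture",
    cutoff: float = 0.85,
    thresholds: tuple[float, float] | None = None,
) -> HitPosteriorModel:
    """Fit priors and class-conditional Gaussian KDEs from the two-screen data.

    ``primary_v`` are primary-screen phenotypes of the conditions assayed in
    both screens; ``reproducible_c`` their reproducibility classes.  Classes
    with fewer than two members get no density (their posterior is
    identically zero).
    """
    if evidence not in ("mixture", "empirical"):
        raise ValueError(f"evidence must be 'mixture' or 'empirical', got {evidence!r}")
    v = np.asarray(primary_v, float)
    c = np.asarray(reproducible_c, int)
    if len(v) == 0:
        raise HitScoringError("no conditions to fit the posterior on")
    if len(v) != len(c):
        raise ValueError("primary_v and reproducible_c lengths differ")
    priors: dict[int, float] = {}
    kdes: dict[int, gaussian_kde | None] = {}
    for cls in CLASSES:
        members = v[c == cls]
        priors[cls] = len(members) / len(v)
        if len(members) >= 2 and np.ptp(members) > 0:
            kdes[cls] = gaussian_kde(members, bw_method=bw_method)
        else:
            kdes[cls] = None
    ev_kde = gaussian_kde(v, bw_method=bw_method) if evidence == "empirical" else None
    return HitPosteriorModel(priors=priors, kdes=kdes, evidence=evidence,
                             evidence_kde=ev_kde, cutoff=cutoff,
                             thresholds=thresholds)


def assign_hits(
    model: HitPosteriorModel,
    well_summary: pd.DataFrame,
    value_col: str,
    cutoff: float | None = None,
    min_cells: int = 500,
    role_col: str = "control_role",
    n_cells_col: str = "n_cells",
) -> pd.DataFrame:
    """Categorical hit calls from the posterior model.

    A condition is called ``up`` (``down``) when the matching class
    posterior exceeds the cutoff, ``non`` otherwise.  Controls and
    conditions with fewer than ``min_cells`` cells are marked non-viable /
    excluded and receive no categorical call.
    """
    cutoff = model.cutoff if cutoff is None else cutoff
    out = well_summary.copy()
    post = model.posterior(out[value_col].to_numpy(float))
    out[["p_down", "p_non", "p_up"]] = post[["down", "non", "up"]].to_numpy()
    viable = out[n_cells_col].to_numpy(float) >= min_cells
    is_control = out[role_col].to_numpy() != ControlRole.PERTURBATION.value
    call = np.where(out["p_up"] > cutoff, "up",
                    np.where(out["p_down"] > cutoff, "down", "non"))
    call = pd.array(call, dtype="string")
    call[~viable | is_control] = pd.NA
    out["viable"] = viable
    out["call"] = call
    if model.thresholds is not None:
        out["putative"] = annotate_putative(out[value_col], model.thresholds)
    return out


def score_two_screens(
    primary: pd.DataFrame,
    secondary_reps: Sequence[pd.DataFrame],
    value_col: str = "v",
    gene_col: str = "gene",
    role_col: str = "control_role",
    n_cells_col: str = "n_cells",
    bw_method: str | float = "silverman",
    evidence: str = "mixture",
    cutoff: float = 0.85,
    min_cells: int = 500,
) -> tuple[pd.DataFrame, HitPosteriorModel]:
    """End-to-end hit scoring from primary + secondary well summaries.

    Percentile thresholds are computed per screen from its own scrambled
    controls; the secondary annotation requires the same directional call in
    every replicate.  The posterior is fitted on conditions present in both
    screens and then applied to the primary screen's perturbations.
    """
    thr_primary = percentile_thresholds(primary, value_col, role_col)
    primary_pert = primary[primary[role_col] == ControlRole.PERTURBATION.value].copy()
    primary_pert["putative"] = annotate_putative(primary_pert[value_col], thr_primary)

    sec_cls: list[pd.Series] = []
    for rep in secondary_reps:
        thr = percentile_thresholds(rep, value_col, role_col)
        pert = rep[rep[role_col] == ControlRole.PERTURBATION.value]
        cls = pd.Series(annotate_putative(pert[value_col], thr),
                        index=pert[gene_col].to_numpy())
        sec_cls.append(cls)
    sec = pd.concat(sec_cls, axis=1)
    # all replicates must agree on a nonzero direction
    agree = (sec.nunique(axis=1) == 1) & (sec.iloc[:, 0] != 0)
    secondary_class = pd.Series(np.where(agree, sec.iloc[:, 0], 0), index=sec.index)

    shared = primary_pert[primary_pert[gene_col].isin(secondary_class.index)].copy()
    c = reproducible_class(
        shared["putative"].to_numpy(),
        secondary_class.loc[shared[gene_col]].to_numpy())
    model = fit_posterior(shared[value_col].to_numpy(float), c,
                          bw_method=bw_method, evidence=evidence,
                          cutoff=cutoff, thresholds=thr_primary)
    calls = assign_hits(model, primary_pert, value_col, cutoff=cutoff,
                        min_cells=min_cells, role_col=role_col,
                        n_cells_col=n_cells_col)
    return calls, model
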