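"""Cell-cycle phase assignment.

S phase cannot be read from DNA content alone, so a random-forest classifier
is trained on EdU ground-truth plates (EdU marks active replication; those
plates sacrifice the EU readout) using DAPI and PCNA nuclear intensity and
texture features.  The trained classifier is applied to every screen plate,
and the remaining non-S interphase cells are split into G1 and G2 at the
valley of the (smoothed, log-scale) sum-nuclear-DAPI density between the 2N
and 4N modes, one valley per plate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .screen_model import SchemaError, ScreenDesign

#: Default classifier features: DAPI + PCNA nuclear intensity and texture.
#: EU and EdU features are never allowed (EdU defines the labels; EU is the
#: phenotype being measured).
DEFAULT_CLASSIFIER_FEATURES = (
    "DAPI_mean_nuclear",
    "DAPI_sum_nuclear",
    "DAPI_texture",
    "PCNA_mean_nuclear",
    "PCNA_sum_nuclear",
    "PCNA_texture",
)

_FORBIDDEN_FEATURE_PREFIXES = ("EdU_", "EU_")


class UnimodalDistributionError(ValueError):
    """A bimodal distribution was required but only one mode was found.

    Carries the evaluated density grid for diagnostics (``grid``, ``density``).
    """

    def __init__(self, message: str, grid: np.ndarray | None = None,
                 density: np.ndarray | None = None):
        super().__init__(message)
        self.grid = grid
        self.density = density


def density_valley(values: np.ndarray, n_grid: int = 512,
                   min_prominence: float = 0.01) -> float:
    """Valley of a smoothed 1-D density between its two highest modes.

    A Gaussian KDE with Silverman bandwidth is evaluated on a regular grid;
    local maxima with prominence of at least ``min_prominence`` times the
    density maximum count as modes (smaller wiggles are numerical noise, not
    populations), the two highest are taken, and the minimum of the density
    between them is returned.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 10 or np.ptp(values) == 0:
        raise UnimodalDistributionError("too few distinct values for valley finding")
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), n_grid)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) < 2:
        raise UnimodalDistributionError(
            "distribution is unimodal; select a threshold manually",
            grid=grid, density=dens)
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def edu_ground_truth(
    edu_cells: pd.DataFrame,
    threshold: float | str = "auto",
) -> tuple[pd.Series, float]:
    """Binary S-phase labels from sum nuclear EdU intensity.

    ``threshold='auto'`` places the cut at the valley of the log-intensity
    density between the two largest modes (replication-positive cells form a
    well-separated upper mode); a float applies that manual threshold on the
    raw intensity scale.  Returns (labels, threshold used).
    """
    if "EdU_sum_nuclear" not in edu_cells.columns:
        raise SchemaError("EdU_sum_nuclear column required for ground-truth labelling")
    v = edu_cells["EdU_sum_nuclear"].to_numpy(float)
    if threshold == "auto":
        thr = float(np.exp(density_valley(np.log(np.clip(v, 1e-12, None)))))
    else:
        thr = float(threshold)
    return pd.Series(v > thr, index=edu_cells.index, name="is_s_phase"), thr


@dataclasses.dataclass
class CellCycleModel:
    """Trained S-phase classifier plus per-plate DAPI G1/G2 valleys."""

    classifier: RandomForestClassifier
    features: tuple[str, ...]
    edu_threshold: float
    seed: int
    training_report: pd.DataFrame | None = None
    dapi_valleys: dict[int, float] = dataclasses.field(default_factory=dict)


def _check_features(features: Sequence[str]) -> tuple[str, ...]:
    features = tuple(features)
    if not features:
        raise ValueError("feature list must be nonempty")
    bad = [f for f in features if f.startswith(_FORBIDDEN_FEATURE_PREFIXES)]
    if bad:
        raise ValueError(f"EdU/EU features may not be used by the classifier: {bad}")
    return features


def train_sphase_classifier(
    edu_cells: pd.DataFrame,
    labels: pd.Series,
    features: Sequence[str] = DEFAULT_CLASSIFIER_FEATURES,
    seed: int = 0,
    edu_threshold: float = float("nan"),
    design: ScreenDesign | None = None,
    holdout_fraction: float = 0.25,
    n_estimators: int = 100,
) -> CellCycleModel:
    """Train the random-forest S-phase classifier on EdU-labelled cells.

    A stratified ``holdout_fraction`` of cells is kept out of training and
    used for the accuracy report; when a design is given the report also
    breaks accuracy down by control role (scrambled accuracy is the headline
    quality figure).  Reproducible under ``seed``.
    """
    features = _check_features(features)
    missing = [f for f in features if f not in edu_cells.columns]
    if missing:
        raise SchemaError(f"missing classifier features: {missing}")
    y = labels.loc[edu_cells.index].to_numpy(bool)
    if len(np.unique(y)) < 2:
        raise ValueError("both S and non-S classes required for training")
    X = edu_cells[list(features)].to_numpy(float)
    idx = np.arange(len(y))
    idx_train, idx_test = train_test_split(
        idx, test_size=holdout_fraction, stratify=y, random_state=seed)
    clf = RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced",
        random_state=seed, n_jobs=1)
    clf.fit(X[idx_train], y[idx_train])
    pred = clf.predict(X[idx_test])
    rows = [("overall", float(accuracy_score(y[idx_test], pred)), len(idx_test))]
    if design is not None:
        ann = design.annotate(edu_cells.iloc[idx_test])
        correct = pd.Series(pred == y[idx_test], index=ann.index)
        for role, grp in ann.groupby("control_role"):
            rows.append((role, float(correct.loc[grp.index].mean()), len(grp)))
    report = pd.DataFrame(rows, columns=["group", "accuracy", "n_cells"])
    return CellCycleModel(classifier=clf, features=features,
                          edu_threshold=edu_threshold, seed=seed,
                          training_report=report)


def classify_sphase(model: CellCycleModel, cells: pd.DataFrame) -> pd.Series:
    """Predict the binary S-phase flag for every cell (deterministic)."""
    missing = [f for f in model.features if f not in cells.columns]
    if missing:
        raise SchemaError(f"missing classifier features: {missing}")
    if len(cells) == 0:
        return pd.Series([], dtype=bool, index=cells.index, name="is_s_phase")
    pred = model.classifier.predict(cells[list(model.features)].to_numpy(float))
    return pd.Series(pred.astype(bool), index=cells.index, name="is_s_phase")


def split_g1_g2(
    cells: pd.DataFrame,
    s_flag: pd.Series,
    min_cells: int = 500,
    model: CellCycleModel | None = None,
) -> pd.Series:
    """Assign G1/S/G2 phases; G1 vs G2 by the per-plate DAPI valley.

    For each plate, a valley is located in the smoothed density of
    log sum-nuclear-DAPI over non-S cells; non-S cells at or below the
    valley are G1, above it G2.  The split is monotone in DAPI by
    construction.  Valleys are recorded on ``model`` when given.
    """
    phase = pd.Series(pd.NA, index=cells.index, dtype="object", name="phase")
    phase[s_flag.astype(bool)] = "S"
    for plate, sub in cells.groupby("plate"):
        non_s = sub.loc[~s_flag.loc[sub.index].astype(bool)]
        if len(non_s) < min_cells:
            raise ValueError(
                f"plate {plate}: only {len(non_s)} non-S cells (< {min_cells})")
        logd = np.log(np.clip(non_s["DAPI_sum_nuclear"].to_numpy(float), 1e-12, None))
        try:
            valley = density_valley(logd)
        except UnimodalDistributionError as err:
            raise UnimodalDistributionError(
                f"plate {plate}: non-S DAPI distribution is unimodal; "
                "cannot place a G1/G2 threshold",
                grid=err.grid, density=err.density) from err
        thr = float(np.exp(valley))
        if model is not None:
            model.dapi_valleys[int(plate)] = thr
        g2 = non_s.index[non_s["DAPI_sum_nuclear"].to_numpy(float) > thr]
        phase.loc[non_s.index] = "G1"
        phase.loc[g2] = "G2"
    return phase


def assign_phases(
    model: CellCycleModel,
    cells: pd.DataFrame,
    min_cells: int = 500,
) -> pd.Series:
    """Classifier + valley split in one call; returns the per-cell phase."""
    s_flag = classify_sphase(model, cells)
    return split_g1_g2(cells, s_flag, min_cells=min_cells, model=model)


def cell_cycle_fractions(
    cells: pd.DataFrame,
    by: Sequence[str] = ("plate", "row", "col"),
) -> pd.DataFrame:
    """Phase fractions per group; each group's fractions sum to 1."""
    counts = (cells.pivot_table(index=list(by), columns="phase", values="cell_id",
                                aggfunc="count", fill_value=0)
              .reindex(columns=["G1", "S", "G2"], fill_value=0))
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.columns = [f"frac_{p}" for p in frac.columns]
    return frac.reset_index()
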