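"""End-to-end orchestration: simulate/load -> clean -> normalize -> classify
-> phenotype -> aggregate.

The EdU ground-truth plate is cleaned and normalized together with the
screen plates (the plate-rescaling target is shared) so the classifier sees
features on the same scale during training and application.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import cell_cycle, cleanup, normalization, phenotypes, synthetic
from .screen_model import ScreenDesign, aggregate_wells


@dataclasses.dataclass
class PipelineResult:
    cells: pd.DataFrame                 # cleaned, normalized, phase + phenotype columns
    well_summary: pd.DataFrame
    design: ScreenDesign
    cleanup_report: cleanup.CleanupReport
    cycle_model: cell_cycle.CellCycleModel
    truth: synthetic.GroundTruth | None = None
    edu_truth: synthetic.GroundTruth | None = None


def run_synthetic_screen(
    config: synthetic.SimulationConfig | None = None,
    mode: str = "primary",
) -> PipelineResult:
    """Simulate a screen plus its EdU plate and run the full analysis."""
    config = config or synthetic.SimulationConfig()
    cells, design, truth = synthetic.simulate_screen(config)
    edu_cells, edu_design, edu_truth = synthetic.simulate_edu_plate(config)
    combined_design = ScreenDesign(
        pd.concat([design.table, edu_design.table], ignore_index=True))
    result = run_pipeline(cells, edu_cells, combined_design, mode=mode)
    result.truth = truth
    result.edu_truth = edu_truth
    return result


def run_pipeline(
    cells: pd.DataFrame,
    edu_cells: pd.DataFrame,
    design: ScreenDesign,
    mode: str = "primary",
    seed: int = 0,
    per_plate_size_model: bool = True,
) -> PipelineResult:
    """Analyse screen plates given an EdU ground-truth plate and a design."""
    edu_plates = set(edu_cells["plate"].unique())
    combined = pd.concat([cells, edu_cells], ignore_index=True)

    cleaned, report = cleanup.clean(combined)
    normalized, _ = normalization.normalize(cleaned, design, mode=mode)

    is_edu = normalized["plate"].isin(edu_plates)
    edu_clean = normalized[is_edu]
    screen = normalized[~is_edu].copy()

    labels, thr = cell_cycle.edu_ground_truth(edu_clean)
    model = cell_cycle.train_sphase_classifier(
        edu_clean, labels, seed=seed, edu_threshold=thr, design=design)
    screen["phase"] = cell_cycle.assign_phases(model, screen)

    screen = phenotypes.compute_phenotypes(screen, design,
                                           per_plate=per_plate_size_model)
    screen = design.annotate(screen)
    summary = aggregate_wells(screen)
    return PipelineResult(cells=screen, well_summary=summary, design=design,
                          cleanup_report=report, cycle_model=model)
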