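"""Synthetic single-cell screen generator.

Emulates the statistical structure of a 384-well, image-based EU-incorporation
siRNA screen at the feature-table level (no pixels): G1/S/G2 cell-cycle
structure with 2N -> 4N DNA content, log-normal total-protein (SE) cell-size
distributions, nascent-RNA (EU) signal scaling multiplicatively with cell
size, phase and gene effect, PCNA texture shifted in S phase, EdU
ground-truth plates, plus the technical artefacts the downstream pipeline is
built to remove: additive row/column staining offsets (DAPI/PCNA/SE),
multiplicative per-plate batch factors, out-of-focus imaging sites, and
border / mitotic / missegmented cells.

Every generated nuisance is recorded in a :class:`GroundTruth` object so the
recovery of each pipeline stage can be tested quantitatively.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .screen_model import (
    CHANNEL_FEATURES,
    ControlRole,
    LayoutConfig,
    ScreenDesign,
    make_plate_layout,
    save_cell_table,
    well_name,
)

PHASES = ("G1", "S", "G2")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic screen; defaults are the study conditions.

    Intensity units are arbitrary fluorescence units (a.u.); areas are pixels.
    ``cells_per_well_mean`` is a desk-scale default (the physical screen has
    well over a thousand cells per well); it is the one knob meant to be
    scaled up or down with available compute.
    """

    n_plates: int = 4
    seed: int = 0
    layout: LayoutConfig = dataclasses.field(default_factory=LayoutConfig)

    # cell counts: gamma-Poisson (negative binomial) per well
    cells_per_well_mean: float = 150.0
    cells_per_well_dispersion: float = 20.0  # NB size parameter; larger = tighter
    kif11_count_factor: float = 0.03  # KIF11 knockdown kills cells
    sites_per_well: int = 6

    # cell-cycle structure
    cycle_fractions: tuple[float, float, float] = (0.56, 0.31, 0.13)  # G1, S, G2
    dna_2n: float = 1000.0  # sum nuclear DAPI at 2N DNA content, a.u.
    dna_cv: float = 0.06

    # cell size: log-normal sum SE (total protein ~ volume), grows through the cycle
    se_median_g1: float = 3000.0
    size_phase_factors: tuple[float, float, float] = (1.0, 1.3, 1.6)
    se_sigma_log: float = 0.20

    # nuclear geometry: area ~ size^gamma; gamma = 1 makes mean nuclear EU
    # size-independent (nuclear size scales with cell size)
    area_per_se: float = 0.08
    gamma: float = 1.0
    area_sigma_log: float = 0.08
    cell_area_factor: float = 3.5
    nucleolar_area_fraction: float = 0.15

    # EU signal: sum EU = k * size * phase_factor * gene_effect * plate_factor * noise
    eu_per_se: float = 0.5
    eu_phase_factors: tuple[float, float, float] = (1.0, 1.4, 1.8)
    eu_sigma_log: float = 0.20
    eu_nucleolar_fraction: float = 0.45

    # PCNA: mean nuclear intensity and a variance-like texture scalar,
    # both discriminative for S phase (replication foci)
    pcna_mean: float = 3.0
    pcna_sigma_log: float = 0.20
    pcna_s_factor: float = 1.6
    pcna_texture_s_shift: float = 3.0  # in units of the texture's unit sd
    dapi_texture_s_shift: float = 0.5

    # EdU (ground-truth plates only): bimodal log-normal
    edu_log_mean: float = np.log(50.0)
    edu_log_sigma: float = 0.4
    edu_s_log_shift: float = 2.4  # 6 sigma separation between modes

    # technical effects
    rc_bias_sd: float = 0.03  # additive row/col offsets, fraction of channel mean ref
    plate_factor_sigma: float = 0.05  # per-plate multiplicative log-sd per channel
    oof_site_fraction: float = 0.003
    oof_attenuation: float = 0.5
    border_fraction: float = 0.125
    mitotic_fraction: float = 0.04
    misseg_fraction: float = 0.05
    cyto_dapi_high_fraction: float = 0.0065  # cells with >20% cytoplasmic DAPI
    dapi_doublet_fraction: float = 0.0066  # unsplit doublets -> DAPI outliers
    cyto_frac_typical: float = 0.05

    # perturbation gene-effect mixture on EU production rate
    effect_null_prob: float = 0.70
    effect_up_prob: float = 0.15
    effect_log_mean: float = np.log(1.3)
    effect_log_sd: float = 0.15
    slc25a3_effect: float = 1.3

    # noiseless mode for analytic checks: suppresses all *technical* noise
    # (staining noise, row/column offsets, plate factors, artefact cells and
    # sites) while keeping the biological size distribution (se_sigma_log)
    noiseless: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.cycle_fractions) - 1.0) > 1e-9:
            raise ValueError("cycle_fractions must sum to 1")
        for name in ("cells_per_well_mean", "dna_2n", "se_median_g1",
                     "area_per_se", "eu_per_se", "pcna_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("oof_site_fraction", "border_fraction", "mitotic_fraction",
                     "misseg_fraction", "cyto_dapi_high_fraction",
                     "dapi_doublet_fraction", "effect_null_prob", "effect_up_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_null_prob + self.effect_up_prob > 1.0 + 1e-12:
            raise ValueError("effect mixture probabilities exceed 1")


# reference mean intensity per channel, used to scale row/column offsets
def _channel_refs(config: SimulationConfig) -> dict[str, float]:
    mean_area = config.area_per_se * config.se_median_g1 * 1.25  # rough pop. average
    return {
        "DAPI": config.dna_2n * 1.3 / mean_area,
        "PCNA": config.pcna_mean,
        "SE": config.se_median_g1 * 1.3 / (config.cell_area_factor * mean_area),
    }


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator injected, keyed exactly like the output."""

    cells: pd.DataFrame       # plate,row,col,site,cell_id,true_phase
    well_effects: pd.DataFrame  # plate,row,col,well_name,gene_symbol,control_role,gene_effect
    oof_sites: pd.DataFrame   # plate,row,col,site
    row_offsets: pd.DataFrame  # plate,channel,row,offset
    col_offsets: pd.DataFrame  # plate,channel,col,offset
    plate_factors: pd.DataFrame  # plate,channel,factor

    def write(self, directory: str | Path, prefix: str = "truth_") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("cells", "well_effects", "oof_sites",
                     "row_offsets", "col_offsets", "plate_factors"):
            getattr(self, name).to_csv(directory / f"{prefix}{name}.csv", index=False)


def _noise(rng: np.random.Generator, sigma: float, n: int, noiseless: bool) -> np.ndarray:
    if noiseless or sigma == 0:
        return np.ones(n)
    return rng.lognormal(0.0, sigma, n)


def _sample_gene_effects(design: ScreenDesign, config: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """One multiplicative EU gene effect per well (each well = one condition)."""
    tab = design.table.copy()
    n = len(tab)
    eff = np.ones(n)
    role = tab["control_role"].to_numpy()
    pert = role == ControlRole.PERTURBATION.value
    u = rng.random(n)
    # mixture: point mass at 1, plus log-normal up and down tails
    up = pert & (u >= config.effect_null_prob) & (u < config.effect_null_prob + config.effect_up_prob)
    down = pert & (u >= config.effect_null_prob + config.effect_up_prob)
    mag = np.exp(np.abs(rng.normal(config.effect_log_mean, config.effect_log_sd, n)))
    eff[up] = mag[up]
    eff[down] = 1.0 / mag[down]
    eff[role == ControlRole.SLC25A3.value] = config.slc25a3_effect
    tab["gene_effect"] = eff
    tab["size_effect"] = 1.0
    return tab[["plate", "row", "col", "well_name", "gene_symbol", "control_role",
                "gene_effect", "size_effect"]]


def _simulate_plate_cells(
    plate: int,
    design_rows: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    plate_factors: Mapping[str, float],
    row_offsets: Mapping[str, np.ndarray],
    col_offsets: Mapping[str, np.ndarray],
    with_edu: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one plate; returns (cells, truth_cells, oof_sites)."""
    c = config
    nl = c.noiseless

    # per-well counts
    n_wells = len(design_rows)
    mean = np.full(n_wells, float(c.cells_per_well_mean))
    mean[design_rows["control_role"].to_numpy() == ControlRole.KIF11.value] *= c.kif11_count_factor
    if nl:
        counts = np.maximum(mean.astype(int), 1)
    else:
        lam = rng.gamma(c.cells_per_well_dispersion, mean / c.cells_per_well_dispersion)
        counts = rng.poisson(lam)
    total = int(counts.sum())

    rows = np.repeat(design_rows["row"].to_numpy(), counts)
    cols = np.repeat(design_rows["col"].to_numpy(), counts)
    effect = np.repeat(design_rows["gene_effect"].to_numpy(), counts)
    size_effect = np.repeat(design_rows["size_effect"].to_numpy(), counts)
    site = rng.integers(1, c.sites_per_well + 1, total)
    cell_id = np.concatenate([np.arange(1, k + 1) for k in counts]) if total else np.array([], int)

    # phase
    phase_idx = rng.choice(3, size=total, p=np.asarray(c.cycle_fractions))
    phase = np.array(PHASES)[phase_idx]

    # DNA content (sum nuclear DAPI before staining effects)
    dna = np.empty(total)
    g1, s, g2 = (phase_idx == 0), (phase_idx == 1), (phase_idx == 2)
    if nl:
        dna[g1] = c.dna_2n
        dna[g2] = 2 * c.dna_2n
        dna[s] = 1.5 * c.dna_2n
    else:
        dna[g1] = rng.normal(c.dna_2n, c.dna_cv * c.dna_2n, g1.sum())
        dna[g2] = rng.normal(2 * c.dna_2n, c.dna_cv * 2 * c.dna_2n, g2.sum())
        dna[s] = rng.uniform(c.dna_2n, 2 * c.dna_2n, s.sum())
    dna = np.clip(dna, 1e-6, None)
    # unsplit nuclei doublets -> extreme DAPI
    doublet = rng.random(total) < (0 if nl else c.dapi_doublet_fraction)
    dna[doublet] *= 2.5

    # size (true sum SE) and geometry
    size_factor = np.asarray(c.size_phase_factors)[phase_idx]
    # cell-size dispersion is biology, not noise: honored even in noiseless mode
    size = (c.se_median_g1 * size_factor * size_effect
            * _noise(rng, c.se_sigma_log, total, False))
    nuclear_area = c.area_per_se * size**c.gamma * _noise(rng, c.area_sigma_log, total, nl)
    cell_area = c.cell_area_factor * nuclear_area * _noise(rng, c.area_sigma_log, total, nl)
    nucleolar_area = c.nucleolar_area_fraction * nuclear_area * _noise(rng, 0.15, total, nl)
    equivalent_diameter = np.sqrt(4 * cell_area / np.pi)

    # EU
    eu_phase = np.asarray(c.eu_phase_factors)[phase_idx]
    eu_sum = (c.eu_per_se * size * eu_phase * effect
              * plate_factors["EU"] * _noise(rng, c.eu_sigma_log, total, nl))
    nucleolar_frac = np.clip(
        c.eu_nucleolar_fraction * _noise(rng, 0.15, total, nl), 0.0, 0.95)
    eu_nucleolar = eu_sum * nucleolar_frac
    eu_nucleoplasmic = eu_sum - eu_nucleolar

    # PCNA
    pcna_mean_int = (c.pcna_mean * np.where(s, c.pcna_s_factor, 1.0)
                     * plate_factors["PCNA"] * _noise(rng, c.pcna_sigma_log, total, nl))
    pcna_texture = (np.zeros(total) if nl else rng.normal(0, 1, total)) \
        + c.pcna_texture_s_shift * s
    dapi_texture = (np.zeros(total) if nl else rng.normal(0, 1, total)) \
        + c.dapi_texture_s_shift * s

    # DAPI staining with cytoplasmic spill
    dapi_sum = dna * plate_factors["DAPI"] * _noise(rng, 0.03, total, nl)
    cyto = np.clip(c.cyto_frac_typical * _noise(rng, 0.5, total, nl), 0, 0.19)
    hi = rng.random(total) < (0 if nl else c.cyto_dapi_high_fraction)
    cyto[hi] = rng.uniform(0.22, 0.50, hi.sum())
    dapi_sum_cell = dapi_sum / (1 - cyto)

    # SE staining
    se_sum_cell = size * plate_factors["SE"] * _noise(rng, 0.03, total, nl)
    se_sum_nuclear = se_sum_cell * np.clip(
        nuclear_area / cell_area * 1.2 * _noise(rng, 0.05, total, nl), 0, 0.95)

    cells = pd.DataFrame({
        "plate": plate,
        "row": rows,
        "col": cols,
        "site": site,
        "cell_id": cell_id,
        "nuclear_area": nuclear_area,
        "cell_area": cell_area,
        "nucleolar_area": nucleolar_area,
        "equivalent_diameter": equivalent_diameter,
        "DAPI_sum_nuclear": dapi_sum,
        "DAPI_sum_cell": dapi_sum_cell,
        "DAPI_mean_nuclear": dapi_sum / nuclear_area,
        "DAPI_texture": dapi_texture,
        "EU_sum_nuclear": eu_sum,
        "EU_mean_nuclear": eu_sum / nuclear_area,
        "EU_sum_nucleolar": eu_nucleolar,
        "EU_sum_nucleoplasmic": eu_nucleoplasmic,
        "PCNA_mean_nuclear": pcna_mean_int,
        "PCNA_sum_nuclear": pcna_mean_int * nuclear_area,
        "PCNA_texture": pcna_texture,
        "SE_sum_cell": se_sum_cell,
        "SE_sum_nuclear": se_sum_nuclear,
        "SE_mean_nuclear": se_sum_nuclear / nuclear_area,
    })
    if with_edu:
        shift = c.edu_s_log_shift * s
        cells["EdU_sum_nuclear"] = np.exp(
            rng.normal(c.edu_log_mean + shift, 0 if nl else c.edu_log_sigma))

    # additive row/column staining offsets: each feature of a biased channel
    # shifts by a constant per (row, col).  Mean features shift by the offset
    # itself, sum features by offset * typical area, with the same scale for
    # nuclear and whole-cell sums so the cytoplasmic difference is untouched.
    mean_area = c.area_per_se * c.se_median_g1 * 1.25
    for ch in ("DAPI", "PCNA", "SE"):
        off = row_offsets[ch][rows - 1] + col_offsets[ch][cols - 1]
        for feat in CHANNEL_FEATURES[ch]:
            if feat.endswith("texture"):
                continue
            stat = feat.split("_")[1]
            scale = 1.0 if stat == "mean" else mean_area
            cells[feat] = cells[feat] + off * scale

    # out-of-focus sites: multiplicative attenuation of all stains at the site
    site_index = pd.MultiIndex.from_frame(
        design_rows[["row", "col"]].loc[design_rows.index.repeat(c.sites_per_well)]
        .assign(site=np.tile(np.arange(1, c.sites_per_well + 1), n_wells))
    )
    oof_mask_sites = rng.random(len(site_index)) < (0 if nl else c.oof_site_fraction)
    oof_sites = pd.DataFrame(site_index[oof_mask_sites].to_list(),
                             columns=["row", "col", "site"])
    oof_sites.insert(0, "plate", plate)
    if len(oof_sites):
        key = pd.MultiIndex.from_arrays([rows, cols, site])
        cell_oof = key.isin(pd.MultiIndex.from_frame(oof_sites[["row", "col", "site"]]))
        stain_cols = [f for feats in CHANNEL_FEATURES.values() for f in feats
                      if not f.endswith("texture")]
        if with_edu:
            stain_cols = stain_cols + ["EdU_sum_nuclear"]
        cells.loc[cell_oof, stain_cols] *= c.oof_attenuation
    # segmentation / imaging flags
    cells["is_border"] = rng.random(total) < (0 if nl else c.border_fraction)
    cells["is_mitotic_or_apoptotic"] = rng.random(total) < (0 if nl else c.mitotic_fraction)
    cells["is_missegmented"] = (rng.random(total) < (0 if nl else c.misseg_fraction)) | hi | doublet
    cells["well_name"] = well_name(rows, cols)

    truth_cells = pd.DataFrame({
        "plate": plate, "row": rows, "col": cols, "site": site,
        "cell_id": cell_id, "true_phase": phase,
    })
    return cells, truth_cells, oof_sites


def _technical_effects(config: SimulationConfig, plates: list[int],
                       rng: np.random.Generator):
    """Draw plate factors and row/column offsets for every plate."""
    refs = _channel_refs(config)
    pf_rows, ro_rows, co_rows = [], [], []
    pf, ro, co = {}, {}, {}
    for plate in plates:
        pf[plate] = {}
        ro[plate] = {}
        co[plate] = {}
        for ch in ("DAPI", "EU", "PCNA", "SE"):
            f = 1.0 if config.noiseless else float(
                rng.lognormal(0.0, config.plate_factor_sigma))
            pf[plate][ch] = f
            pf_rows.append((plate, ch, f))
        for ch in ("DAPI", "PCNA", "SE"):
            sd = 0.0 if config.noiseless else config.rc_bias_sd * refs[ch]
            r_off = rng.normal(0.0, sd, 16) if sd else np.zeros(16)
            c_off = rng.normal(0.0, sd, 24) if sd else np.zeros(24)
            ro[plate][ch] = r_off
            co[plate][ch] = c_off
            ro_rows += [(plate, ch, i + 1, v) for i, v in enumerate(r_off)]
            co_rows += [(plate, ch, i + 1, v) for i, v in enumerate(c_off)]
        ro[plate]["EU"] = np.zeros(16)
        co[plate]["EU"] = np.zeros(24)
    return (
        pf, ro, co,
        pd.DataFrame(pf_rows, columns=["plate", "channel", "factor"]),
        pd.DataFrame(ro_rows, columns=["plate", "channel", "row", "offset"]),
        pd.DataFrame(co_rows, columns=["plate", "channel", "col", "offset"]),
    )


def simulate_screen(
    config: SimulationConfig | None = None,
    effects_override: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ScreenDesign, GroundTruth]:
    """Simulate a multi-plate screen; returns (cells, design, truth).

    Reproducible: identical config (including seed) yields byte-identical
    tables.  Scrambled, PIM2 and mock wells carry gene effect exactly 1;
    SLC25A3 wells the configured positive effect; KIF11 wells a near-zero
    cell-count model.

    ``effects_override`` may supply per-well ``gene_effect`` (multiplier on
    the EU production rate) and/or ``size_effect`` (multiplier on cell size,
    with EU following proportionally) columns keyed by plate/row/col,
    replacing the sampled mixture for those wells.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    design = make_plate_layout(config.n_plates, config.layout,
                               seed=int(rng.integers(2**31)))
    effects = _sample_gene_effects(design, config, rng)
    if effects_override is not None:
        effects = effects.merge(
            effects_override, on=["plate", "row", "col"], how="left",
            suffixes=("", "_ovr"))
        for col in ("gene_effect", "size_effect"):
            ovr = f"{col}_ovr"
            if ovr in effects.columns:
                effects[col] = effects[ovr].fillna(effects[col])
                effects = effects.drop(columns=[ovr])
    plates = design.plates
    pf, ro, co, pf_df, ro_df, co_df = _technical_effects(config, plates, rng)

    all_cells, all_truth, all_oof = [], [], []
    for plate in plates:
        d = effects[effects["plate"] == plate].reset_index(drop=True)
        cells, truth_cells, oof = _simulate_plate_cells(
            plate, d, config, rng, pf[plate], ro[plate], co[plate], with_edu=False)
        all_cells.append(cells)
        all_truth.append(truth_cells)
        all_oof.append(oof)
    cells = pd.concat(all_cells, ignore_index=True)
    truth = GroundTruth(
        cells=pd.concat(all_truth, ignore_index=True),
        well_effects=effects,
        oof_sites=pd.concat(all_oof, ignore_index=True),
        row_offsets=ro_df,
        col_offsets=co_df,
        plate_factors=pf_df,
    )
    return cells, design, truth


def simulate_edu_plate(
    config: SimulationConfig | None = None,
    plate: int = 99,
) -> tuple[pd.DataFrame, ScreenDesign, GroundTruth]:
    """Simulate one EdU ground-truth plate (EdU channel instead of EU pulse).

    The plate keeps the standard control layout plus perturbation wells, so
    classifier training sees diverse conditions.  S-phase cells occupy the
    upper mode of the bimodal log sum-EdU distribution.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1 if config.seed < 2**31 - 1 else 0)
    layout_design = make_plate_layout(1, config.layout,
                                      seed=int(rng.integers(2**31)))
    tab = layout_design.table.copy()
    tab["plate"] = plate
    tab = tab.drop(columns=["well_name"])
    tab["well_name"] = well_name(tab["row"].to_numpy(), tab["col"].to_numpy())
    design = ScreenDesign(tab[ScreenDesign.COLUMNS])
    effects = _sample_gene_effects(design, config, rng)
    pf, ro, co, pf_df, ro_df, co_df = _technical_effects(config, [plate], rng)
    cells, truth_cells, oof = _simulate_plate_cells(
        plate, effects.reset_index(drop=True), config, rng,
        pf[plate], ro[plate], co[plate], with_edu=True)
    truth = GroundTruth(cells=truth_cells, well_effects=effects, oof_sites=oof,
                        row_offsets=ro_df, col_offsets=co_df, plate_factors=pf_df)
    return cells, design, truth


def simulate_two_screens(
    n_genes: int = 439,
    effect_sd: float = 1.0,
    replicate_noise_sd: float = 0.143,
    screen_noise_sd: float = 0.672,
    n_control_wells: int = 200,
    n_cells_mean: float = 1500.0,
    low_viability_fraction: float = 0.03,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Well-level model of a primary screen plus a duplicated secondary screen.

    Each gene g carries a shared true phenotype ``effect ~ N(0, effect_sd^2)``.
    The primary measurement adds a per-gene between-screen term
    ``N(0, screen_noise_sd^2)`` (the screens were months apart) plus
    well-level noise; each secondary replicate adds independent well-level
    noise ``N(0, replicate_noise_sd^2)``.  With effect_sd 1 the expected
    Pearson correlation between secondary replicates is 1/(1+rep^2) and
    between the primary screen and the secondary replicate mean
    1/sqrt((1+scr^2+rep^2)(1+rep^2/2)); the defaults reproduce the observed
    screen-to-screen reproducibility.

    Returns a dict with keys ``primary``, ``secondary_rep1``,
    ``secondary_rep2`` (gene, v, n_cells, control_role) and ``truth``.
    """
    for nm, v in (("effect_sd", effect_sd), ("replicate_noise_sd", replicate_noise_sd),
                  ("screen_noise_sd", screen_noise_sd)):
        if v < 0:
            raise ValueError(f"{nm} must be >= 0")
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])
    effect = rng.normal(0.0, effect_sd, n_genes)
    primary_v = effect + rng.normal(0.0, screen_noise_sd, n_genes) \
        + rng.normal(0.0, replicate_noise_sd, n_genes)
    rep1_v = effect + rng.normal(0.0, replicate_noise_sd, n_genes)
    rep2_v = effect + rng.normal(0.0, replicate_noise_sd, n_genes)

    def _table(v: np.ndarray) -> pd.DataFrame:
        n_cells = rng.poisson(n_cells_mean, n_genes).astype(float)
        low = rng.random(n_genes) < low_viability_fraction
        n_cells[low] = rng.integers(0, 500, low.sum())
        ctrl_v = rng.normal(0.0, replicate_noise_sd, n_control_wells)
        ctrl = pd.DataFrame({
            "gene": "scrambled", "v": ctrl_v,
            "n_cells": rng.poisson(n_cells_mean, n_control_wells).astype(float),
            "control_role": ControlRole.SCRAMBLED.value,
        })
        pert = pd.DataFrame({
            "gene": genes, "v": v, "n_cells": n_cells,
            "control_role": ControlRole.PERTURBATION.value,
        })
        return pd.concat([pert, ctrl], ignore_index=True)

    return {
        "primary": _table(primary_v),
        "secondary_rep1": _table(rep1_v),
        "secondary_rep2": _table(rep2_v),
        "truth": pd.DataFrame({"gene": genes, "effect": effect}),
    }


def write_screen(directory: str | Path, cells: pd.DataFrame, design: ScreenDesign,
                 truth: GroundTruth | None = None) -> None:
    """Write per-plate cell CSVs, the library CSV and (optionally) truth CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for plate, sub in cells.groupby("plate"):
        save_cell_table(sub, directory / f"plate_{plate:03d}.csv")
    design.to_csv(directory / "library.csv")
    if truth is not None:
        truth.write(directory)
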