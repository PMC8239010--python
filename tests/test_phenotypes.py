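"""Residual EU phenotypes: phase baselines, size regression, discrimination."""

import numpy as np
import pandas as pd
import pytest

from euscreen import phenotypes as ph
from euscreen.phenotypes import (
    PhenotypeError,
    compute_phase_means,
    fit_size_model,
    residual_mean_eu,
    residual_sum_eu,
)
from euscreen.screen_model import LayoutConfig, aggregate_wells, make_plate_layout
from euscreen.synthetic import SimulationConfig, simulate_screen


def _all_scrambled_design(n_plates=1):
    return make_plate_layout(n_plates, LayoutConfig(scrambled=384, kif11=0,
                                                    pim2=0, slc25a3=0, mock=0))


def _cells(plate, rows, cols, phase, eu_mean=None, eu_sum=None, size=None):
    n = len(phase)
    return pd.DataFrame({
        "plate": plate, "row": rows, "col": cols, "site": 1,
        "cell_id": np.arange(n), "phase": phase,
        "EU_mean_nuclear": eu_mean if eu_mean is not None else np.zeros(n),
        "EU_sum_nuclear": eu_sum if eu_sum is not None else np.zeros(n),
        "SE_sum_cell": size if size is not None else np.ones(n),
    })


class TestPhaseMeans:
    def test_hand_computed(self):
        design = _all_scrambled_design()
        cells = _cells(1, 1, 1, ["G1", "G1", "S", "G2"],
                       eu_mean=[10.0, 10.0, 20.0, 30.0])
        means = compute_phase_means(cells, design)
        assert means == {"G1": 10.0, "S": 20.0, "G2": 30.0}

    def test_uniform_values(self):
        design = _all_scrambled_design()
        cells = _cells(1, 1, 1, ["G1", "S", "G2"], eu_mean=[5.0, 5.0, 5.0])
        assert set(compute_phase_means(cells, design).values()) == {5.0}

    def test_pooling_invariant_to_plate_order(self):
        design = _all_scrambled_design(2)
        cells = pd.concat([
            _cells(1, 1, 1, ["G1", "S", "G2"], eu_mean=[1.0, 2.0, 3.0]),
            _cells(2, 1, 1, ["G1", "S", "G2"], eu_mean=[3.0, 4.0, 5.0]),
        ])
        a = compute_phase_means(cells, design)
        b = compute_phase_means(cells.iloc[::-1], design)
        assert a == b

    def test_missing_phase_is_error(self):
        design = _all_scrambled_design()
        cells = _cells(1, 1, 1, ["G1", "G1"], eu_mean=[1.0, 2.0])
        with pytest.raises(PhenotypeError, match="S"):
            compute_phase_means(cells, design)


class TestResidualMeanEU:
    def test_arithmetic(self):
        cells = _cells(1, 1, 1, ["G1"], eu_mean=[12.0])
        res = residual_mean_eu(cells, {"G1": 10.0, "S": 0.0, "G2": 0.0})
        assert res.iloc[0] == 2.0

    def test_control_cell_at_phase_mean_is_zero(self):
        cells = _cells(1, 1, 1, ["S"], eu_mean=[20.0])
        res = residual_mean_eu(cells, {"G1": 10.0, "S": 20.0, "G2": 30.0})
        assert res.iloc[0] == 0.0

    def test_screen_wide_control_mean_is_zero(self, screen):
        cells, design, truth = screen
        m = cells.merge(truth.cells, on=["plate", "row", "col", "site", "cell_id"])
        m["phase"] = m["true_phase"]
        means = compute_phase_means(m, design)
        res = residual_mean_eu(m, means)
        from euscreen.normalization import _control_mask
        ctrl = res[_control_mask(m, design)]
        assert abs(ctrl.mean()) <= 1e-9 * m["EU_mean_nuclear"].abs().mean()

    def test_missing_phase_skipped_with_warning(self):
        cells = _cells(1, 1, 1, ["G1", None], eu_mean=[1.0, 2.0])
        with pytest.warns(UserWarning, match="without phase"):
            res = residual_mean_eu(cells, {"G1": 1.0, "S": 0.0, "G2": 0.0})
        assert res.isna().iloc[1]


class TestSizeModel:
    def test_exact_recovery_on_noiseless_construction(self, rng):
        design = _all_scrambled_design()
        n = 600
        size = rng.uniform(1000, 5000, n)
        phase = rng.choice(["G1", "S", "G2"], n)
        eu = 2.0 * size + 7.0 + 100.0 * (phase == "S") + 250.0 * (phase == "G2")
        cells = _cells(1, rng.integers(1, 17, n), rng.integers(1, 25, n),
                       phase, eu_sum=eu, size=size)
        model = fit_size_model(cells, design, min_control_cells=10)
        beta = model.params(1)
        assert beta == pytest.approx([7.0, 2.0, 100.0, 250.0], abs=1e-6)
        res = residual_sum_eu(cells, model)
        assert np.allclose(res, 0.0, atol=1e-6)

    def test_null_size_coefficient(self, rng):
        design = _all_scrambled_design()
        n = 2000
        size = rng.uniform(1000, 5000, n)
        phase = rng.choice(["G1", "S", "G2"], n)
        eu = 50.0 + 10.0 * (phase == "G2") + rng.normal(0, 5, n)
        cells = _cells(1, rng.integers(1, 17, n), rng.integers(1, 25, n),
                       phase, eu_sum=eu, size=size)
        model = fit_size_model(cells, design, min_control_cells=10)
        coef = model.coefficients.set_index("term")
        slope, se = coef.loc["size", ["estimate", "stderr"]]
        assert abs(slope) < 3 * se

    def test_duplicated_data_identical_fit(self, rng):
        design = _all_scrambled_design()
        n = 200
        size = rng.uniform(1000, 5000, n)
        phase = rng.choice(["G1", "S", "G2"], n)
        eu = size + rng.normal(0, 10, n)
        cells = _cells(1, rng.integers(1, 17, n), rng.integers(1, 25, n),
                       phase, eu_sum=eu, size=size)
        doubled = pd.concat([cells, cells.assign(cell_id=lambda d: d.cell_id + n)],
                            ignore_index=True)
        a = fit_size_model(cells, design, min_control_cells=10)
        b = fit_size_model(doubled, design, min_control_cells=10)
        assert a.params(1) == pytest.approx(b.params(1), rel=1e-9)

    def test_single_phase_rank_deficient(self):
        design = _all_scrambled_design()
        cells = _cells(1, 1, 1, ["G1"] * 20, eu_sum=np.ones(20), size=np.ones(20))
        with pytest.raises(PhenotypeError, match="rank-deficient"):
            fit_size_model(cells, design, min_control_cells=5)

    def test_missing_plate_model_is_error(self, rng):
        design = _all_scrambled_design()
        cells = _cells(1, 1, 1, ["G1", "S", "G2"] * 10,
                       eu_sum=rng.normal(size=30), size=rng.normal(size=30))
        model = fit_size_model(cells, design, min_control_cells=5)
        other = cells.assign(plate=2)
        with pytest.raises(PhenotypeError, match="plate 2"):
            residual_sum_eu(other, model)


@pytest.fixture(scope="module")
def perturbed_screen():
    cfg = SimulationConfig(
        n_plates=1, cells_per_well_mean=80.0, seed=5,
        effect_null_prob=1.0, effect_up_prob=0.0,
        oof_site_fraction=0.0, border_fraction=0.0, mitotic_fraction=0.0,
        misseg_fraction=0.0, cyto_dapi_high_fraction=0.0,
        dapi_doublet_fraction=0.0)
    cells0, _, truth0 = simulate_screen(cfg)
    pert = truth0.well_effects[truth0.well_effects["control_role"]
                               == "perturbation"]
    override = pd.concat([
        pert.iloc[:25][["plate", "row", "col"]].assign(size_effect=1.5),
        pert.iloc[25:50][["plate", "row", "col"]].assign(gene_effect=1.5),
    ])
    cells, design, truth = simulate_screen(cfg, effects_override=override)
    m = cells.merge(truth.cells, on=["plate", "row", "col", "site", "cell_id"])
    m["phase"] = m["true_phase"]
    m = ph.compute_phenotypes(m, design)
    summary = aggregate_wells(design.annotate(m))
    summary = summary.merge(
        truth.well_effects[["plate", "row", "col", "gene_effect", "size_effect"]],
        on=["plate", "row", "col"])
    return summary


class TestDiscrimination:

    def test_size_only_wells_have_small_sum_residual(self, perturbed_screen):
        s = perturbed_screen
        size_only = s[s["size_effect"] == 1.5]["mean_residual_sum_eu"].abs().mean()
        rate_only = s[(s["gene_effect"] == 1.5) & (s["size_effect"] == 1.0)][
            "mean_residual_sum_eu"].abs().mean()
        assert rate_only > 5 * size_only

    def test_size_effect_still_raises_raw_eu(self, perturbed_screen):
        s = perturbed_screen
        size_only = s[s["size_effect"] == 1.5]["median_EU_sum_nuclear"].mean()
        null = s[s["control_role"] == "scrambled"]["median_EU_sum_nuclear"].mean()
        assert size_only > 1.3 * null

    def test_rate_effect_recovered_in_direction(self, perturbed_screen):
        s = perturbed_screen
        rate = s[(s["gene_effect"] == 1.5) & (s["size_effect"] == 1.0)]
        assert (rate["mean_residual_sum_eu"] > 0).all()


def test_phenotypes_invariant_to_row_shuffle(screen):
    cells, design, truth = screen
    m = cells.merge(truth.cells, on=["plate", "row", "col", "site", "cell_id"])
    m["phase"] = m["true_phase"]
    a = ph.compute_phenotypes(m, design)
    b = ph.compute_phenotypes(m.sample(frac=1, random_state=0), design)
    b = b.sort_index()
    pd.testing.assert_series_equal(a["residual_sum_eu"], b["residual_sum_eu"])
    pd.testing.assert_series_equal(a["residual_mean_eu"], b["residual_mean_eu"])
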