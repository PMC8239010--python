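"""Background subtraction, row/column correction, plate rescaling,
nucleolar standardization."""

import numpy as np
import pandas as pd
import pytest

from euscreen import normalization as nz
from euscreen.normalization import (
    NormalizationError,
    PRIMARY_ROWCOL_CHANNELS,
    normalize,
    plate_rescale,
    rowcol_correct,
    standardize_nucleolar,
    subtract_background,
)
from euscreen.screen_model import ScreenDesign, intensity_columns
from euscreen.synthetic import SimulationConfig, simulate_screen

from conftest import make_cells


def _grid_cells(n_rows, n_cols, value_fn, cells_per_well=2):
    rows = []
    cid = 0
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            for _ in range(cells_per_well):
                cid += 1
                rows.append((1, r, c, 1, cid, value_fn(r, c)))
    return pd.DataFrame(rows, columns=["plate", "row", "col", "site", "cell_id",
                                       "DAPI_mean_nuclear"])


class TestBackground:
    def test_zero_constant_identity(self, screen):
        cells, _, _ = screen
        out = subtract_background(cells, {ch: 0.0 for ch in "DAPI EU PCNA SE".split()})
        pd.testing.assert_frame_equal(out, cells)

    def test_subtraction_may_go_negative(self):
        cells = make_cells({"DAPI_mean_nuclear": [110.0, 90.0]})
        out = subtract_background(cells, {"DAPI": 100.0}, channels=["DAPI"])
        assert out["DAPI_mean_nuclear"].tolist() == [10.0, -10.0]

    def test_channels_corrected_independently(self):
        cells = make_cells({"DAPI_mean_nuclear": [100.0], "EU_mean_nuclear": [100.0]})
        out = subtract_background(cells, {"DAPI": 10.0, "EU": 20.0},
                                  channels=["DAPI", "EU"])
        assert out["DAPI_mean_nuclear"].iloc[0] == 90.0
        assert out["EU_mean_nuclear"].iloc[0] == 80.0

    def test_missing_constant_is_config_error(self):
        cells = make_cells({"DAPI_mean_nuclear": [1.0]})
        with pytest.raises(NormalizationError, match="EU"):
            subtract_background(cells, {"DAPI": 0.0}, channels=["DAPI", "EU"])


class TestRowColCorrection:
    def test_uniform_plate_unchanged(self):
        cells = _grid_cells(4, 6, lambda r, c: 100.0)
        out, _ = rowcol_correct(cells, features=["DAPI_mean_nuclear"])
        assert np.allclose(out["DAPI_mean_nuclear"], 100.0)

    def test_additive_bias_removed_exactly_on_odd_grid(self):
        """Brute-force oracle: on a full odd grid, corrected values equal
        2*median(all) - median_col(col offs) - median_row(row offs) - base
        ... i.e. a constant; additive row+column structure vanishes."""
        row_off = {1: 10.0, 2: 0.0, 3: -10.0}
        col_off = {1: 5.0, 2: 0.0, 3: -5.0}
        cells = _grid_cells(3, 3, lambda r, c: 100.0 + row_off[r] + col_off[c])
        out, _ = rowcol_correct(cells, features=["DAPI_mean_nuclear"])
        # independent oracle: recompute the correction from raw medians
        raw = cells["DAPI_mean_nuclear"]
        expected = (raw + 2 * raw.median()
                    - cells.groupby("row")["DAPI_mean_nuclear"].transform("median")
                    - cells.groupby("col")["DAPI_mean_nuclear"].transform("median"))
        assert np.allclose(out["DAPI_mean_nuclear"], expected)
        assert out["DAPI_mean_nuclear"].nunique() == 1  # bias fully removed
        assert out["DAPI_mean_nuclear"].iloc[0] == pytest.approx(100.0)

    @pytest.mark.parametrize("n_rows,n_cols", [(5, 5), (3, 7), (15, 23)])
    def test_odd_grid_exactness_random_offsets(self, n_rows, n_cols, rng):
        row_off = rng.normal(0, 5, n_rows)
        col_off = rng.normal(0, 5, n_cols)
        cells = _grid_cells(n_rows, n_cols,
                            lambda r, c: 50.0 + row_off[r - 1] + col_off[c - 1],
                            cells_per_well=1)
        out, _ = rowcol_correct(cells, features=["DAPI_mean_nuclear"])
        assert np.ptp(out["DAPI_mean_nuclear"].to_numpy()) < 1e-9

    def test_single_elevated_well_preserved(self):
        cells = _grid_cells(5, 5, lambda r, c: 100.0, cells_per_well=3)
        mask = (cells["row"] == 2) & (cells["col"] == 2)
        cells.loc[mask, "DAPI_mean_nuclear"] += 50.0
        out, _ = rowcol_correct(cells, features=["DAPI_mean_nuclear"])
        elev = out.loc[mask, "DAPI_mean_nuclear"].mean()
        rest = out.loc[~mask, "DAPI_mean_nuclear"].mean()
        assert elev - rest == pytest.approx(50.0, abs=1e-9)

    def test_eu_not_in_primary_correction_map(self):
        feats = intensity_columns(PRIMARY_ROWCOL_CHANNELS)
        assert not any(f.startswith("EU_") for f in feats)

    def test_injected_bias_removed_on_generator(self, screen):
        cells, _, truth = screen
        out, _ = rowcol_correct(cells)
        # after correction, well medians no longer track the injected offsets
        plate = 1
        sub = out[out["plate"] == plate]
        ro = truth.row_offsets.query("plate == @plate and channel == 'DAPI'")
        wm = sub.groupby(["row", "col"])["DAPI_mean_nuclear"].median().reset_index()
        wm["injected"] = wm["row"].map(ro.set_index("row")["offset"])
        slope = np.polyfit(wm["injected"], wm["DAPI_mean_nuclear"], 1)[0]
        assert abs(slope) < 0.2


class TestPlateRescale:
    def _two_plate_cells(self, medians, design_seed=0, noise=0.01):
        from euscreen.screen_model import make_plate_layout
        design = make_plate_layout(len(medians), seed=design_seed)
        rows = []
        cid = 0
        rng = np.random.default_rng(0)
        for plate, med in enumerate(medians, 1):
            for _, w in design.table[design.table["plate"] == plate].iterrows():
                for _ in range(5):
                    cid += 1
                    rows.append((plate, w["row"], w["col"], 1, cid,
                                 med * (1 + noise * rng.normal())))
        cells = pd.DataFrame(rows, columns=["plate", "row", "col", "site",
                                            "cell_id", "EU_sum_nuclear"])
        return cells, design

    def test_factor_arithmetic_two_plates(self):
        cells, design = self._two_plate_cells([100.0, 200.0])
        out, ctx = plate_rescale(cells, design, features=["EU_sum_nuclear"])
        factors = ctx.rescale_factors.set_index("plate")["factor"]
        assert factors[1] * 100 == pytest.approx(factors[2] * 200, rel=0.05)
        # plate 2 roughly halved relative to plate 1
        assert factors[2] / factors[1] == pytest.approx(0.5, rel=0.05)

    def test_identical_plates_identity(self):
        # byte-identical plates: rescale factors are exactly 1
        one, design1 = self._two_plate_cells([100.0])
        two = pd.concat([one, one.assign(plate=2)], ignore_index=True)
        from euscreen.screen_model import make_plate_layout
        design = make_plate_layout(2, seed=0)
        # both plates share the same layout as plate 1 of the design? build
        # a design whose plate 2 mirrors plate 1 so control wells coincide
        d = design1.table
        mirrored = pd.concat([d, d.assign(plate=2)], ignore_index=True)
        design = type(design1)(mirrored)
        out, ctx = plate_rescale(two, design, features=["EU_sum_nuclear"])
        assert (ctx.rescale_factors["factor"] == 1.0).all()
        pd.testing.assert_series_equal(out["EU_sum_nuclear"], two["EU_sum_nuclear"])

    def test_outlier_control_well_excluded_from_factor(self):
        cells, design = self._two_plate_cells([100.0, 100.0], noise=0.0)
        ctrl = design.wells_with_role("scrambled", plate=1).iloc[0]
        mask = ((cells["plate"] == 1) & (cells["row"] == ctrl["row"])
                & (cells["col"] == ctrl["col"]))
        spiked = cells.copy()
        spiked.loc[mask, "EU_sum_nuclear"] *= 10
        _, ctx_plain = plate_rescale(cells, design, features=["EU_sum_nuclear"])
        _, ctx_spiked = plate_rescale(spiked, design, features=["EU_sum_nuclear"])
        f_plain = ctx_plain.rescale_factors.set_index("plate")["factor"]
        f_spiked = ctx_spiked.rescale_factors.set_index("plate")["factor"]
        assert f_spiked[1] == pytest.approx(f_plain[1], rel=1e-6)

    def test_control_medians_equalized(self, screen):
        cells, design, _ = screen
        out, _ = plate_rescale(cells, design, features=["EU_sum_nuclear"])
        meds = []
        from euscreen.normalization import _control_mask
        ctrl = out[_control_mask(out, design)]
        for plate, sub in ctrl.groupby("plate"):
            wm = sub.groupby(["row", "col"])["EU_sum_nuclear"].median()
            q1, q3 = wm.quantile([0.25, 0.75])
            iqr = q3 - q1
            keep = wm[(wm >= q1 - 1.5 * iqr) & (wm <= q3 + 1.5 * iqr)].index
            meds.append(sub.set_index(["row", "col"])
                        .loc[list(keep), "EU_sum_nuclear"].median())
        assert np.ptp(meds) <= 1e-9 * abs(meds[0])

    def test_nonpositive_control_median_rejected(self):
        cells, design = self._two_plate_cells([100.0, 100.0])
        cells["EU_sum_nuclear"] -= 200.0
        with pytest.raises(NormalizationError, match="<= 0"):
            plate_rescale(cells, design, features=["EU_sum_nuclear"])


class TestNucleolarStandardization:
    def test_z_score_arithmetic(self):
        from euscreen.screen_model import make_plate_layout, LayoutConfig
        design = make_plate_layout(1, LayoutConfig(scrambled=384, kif11=0, pim2=0,
                                                   slc25a3=0, mock=0))
        rng = np.random.default_rng(0)
        n = 2000
        cells = pd.DataFrame({
            "plate": 1,
            "row": rng.integers(1, 17, n), "col": rng.integers(1, 25, n),
            "site": 1, "cell_id": np.arange(n),
            "EU_sum_nucleolar": rng.normal(5.0, 2.0, n),
        })
        out, ctx = standardize_nucleolar(cells, design,
                                         features=["EU_sum_nucleolar"])
        stats = ctx.nucleolar_stats.iloc[0]
        probe = (9.0 - stats["mean"]) / stats["sd"]
        assert probe == pytest.approx(2.0, abs=0.15)  # controls ~ N(5, 2^2)
        assert out["EU_sum_nucleolar"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["EU_sum_nucleolar"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_plate_bias_removed_on_generator(self, screen):
        cells, design, _ = screen
        out, _ = standardize_nucleolar(cells, design)
        from euscreen.normalization import _control_mask
        ctrl = out[_control_mask(out, design)]
        plate_means = ctrl.groupby("plate")["EU_sum_nucleolar"].mean()
        assert np.allclose(plate_means, 0.0, atol=1e-9)


class TestFullNormalize:
    def test_secondary_mode_skips_rowcol(self, screen):
        cells, design, _ = screen
        prim, _ = normalize(cells, design, mode="primary",
                            standardize_nucleolar_features=False)
        sec, ctx = normalize(cells, design, mode="secondary",
                             standardize_nucleolar_features=False)
        assert ctx.rowcol_channels == ()
        # secondary equals plain rescale: well-median structure of DAPI retained
        resc, _ = plate_rescale(cells, design,
                                features=[c for c in intensity_columns()
                                          if c in cells.columns])
        pd.testing.assert_series_equal(sec["DAPI_mean_nuclear"],
                                       resc["DAPI_mean_nuclear"])
        assert not np.allclose(prim["DAPI_mean_nuclear"], sec["DAPI_mean_nuclear"])

    def test_invalid_mode_rejected(self, screen):
        cells, design, _ = screen
        with pytest.raises(ValueError):
            normalize(cells, design, mode="tertiary")
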