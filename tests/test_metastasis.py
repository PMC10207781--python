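"""Poisson seeding model: probability law, calibration, strategy tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from waitline.kinetics import DAYS_PER_MONTH, GrowthModel, Thresholds, advance_cells, cells_from_diameter
from waitline.metastasis import (
    BEYOND_PALPABILITY,
    MetastasisModel,
    StageBand,
    calibrate_P,
    default_stage_bands,
    pr_met,
    probability_interval,
    read_stage_probabilities,
    stage_probabilities,
    write_stage_probabilities,
)

KINETICS = GrowthModel()
BANDS = default_stage_bands()


def reference_observed(p_star: float) -> dict[str, float]:
    """Observed table generated from a known seeding parameter."""
    model = MetastasisModel(P=p_star)
    return {
        b.label: model.pr_met(cells_from_diameter(b.representative_diameter_mm))
        for b in BANDS
        if b.label in ("T1A", "T1B", "T1C", "T2")
    }


class TestPrMet:
    def test_zero_cells_zero_probability(self):
        assert pr_met(0.0, MetastasisModel(P=1e9)) == 0.0

    def test_half_probability_at_P_ln2_cells(self):
        model = MetastasisModel(P=1e9)
        assert pr_met(1e9 * math.log(2), model) == pytest.approx(0.5)

    def test_mu_ratio_0_2231_gives_20_percent(self):
        # mean 0.2231 seeding events <=> 20% metastasis probability
        model = MetastasisModel(P=1e9)
        assert pr_met(0.2231 * 1e9, model) == pytest.approx(0.20, abs=5e-4)

    @given(st.floats(min_value=0, max_value=1e12), st.floats(min_value=0, max_value=1e12))
    def test_monotone_nondecreasing(self, a, b):
        model = MetastasisModel(P=7e9)
        lo, hi = sorted((a, b))
        assert pr_met(lo, model) <= pr_met(hi, model) <= 1.0

    @given(st.floats(min_value=0, max_value=1e11))
    def test_strictly_below_one_for_finite_cells(self, cells):
        # up to mu ~ 14, where 1 - exp(-mu) is resolvable below 1.0
        assert pr_met(cells, MetastasisModel(P=7e9)) < 1.0

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            pr_met(-1.0, MetastasisModel(P=1e9))


class TestProbabilityInterval:
    @staticmethod
    def wilson_oracle(p, n, z=1.959963984540054):
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return center - half, center + half

    @pytest.mark.parametrize("point, n", [(0.5, 100), (0.03, 242), (0.2, 242), (0.59, 242)])
    def test_matches_closed_form_wilson(self, point, n):
        lo, hi = probability_interval(point, n)
        olo, ohi = self.wilson_oracle(point, n)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)

    def test_half_at_n_100(self):
        lo, hi = probability_interval(0.5, 100)
        assert (lo, hi) == (pytest.approx(0.404, abs=1e-3), pytest.approx(0.596, abs=1e-3))

    def test_zero_point_has_zero_lower_bound(self):
        lo, _ = probability_interval(0.0, 242)
        assert lo == 0.0

    @pytest.mark.parametrize("point", [0.0, 0.03, 0.5, 0.97])
    def test_interval_contains_point_and_shrinks_with_n(self, point):
        lo, hi = probability_interval(point, 100)
        assert lo <= point <= hi
        lo2, hi2 = probability_interval(point, 10000)
        assert hi2 - lo2 < hi - lo or (hi - lo) == 0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            probability_interval(0.5, 0)


class TestCalibration:
    def test_single_pair_closed_form(self):
        bands = [StageBand("T1C", 10, 20)]
        n0 = cells_from_diameter(bands[0].representative_diameter_mm)
        result = calibrate_P({"T1C": 0.5}, bands, KINETICS)
        assert result.model.P == pytest.approx(n0 / math.log(2), rel=1e-12)

    def test_noiseless_recovery_within_one_percent(self):
        p_star = 5e9
        result = calibrate_P(reference_observed(p_star), BANDS, KINETICS)
        assert result.model.P == pytest.approx(p_star, rel=0.01)
        assert result.rmse < 1e-6

    def test_recovery_under_binomial_noise_at_registry_size(self):
        # the generating parameter lies inside the spread of estimates from
        # repeated binomially perturbed observation tables (n = 242)
        p_star, n, rng = 5e9, 242, np.random.default_rng(42)
        clean = reference_observed(p_star)
        estimates = []
        for _ in range(40):
            noisy = {s: rng.binomial(n, p) / n for s, p in clean.items()}
            estimates.append(calibrate_P(noisy, BANDS, KINETICS).model.P)
        lo, hi = np.percentile(estimates, [2.5, 97.5])
        assert lo <= p_star <= hi

    def test_scale_consistency(self):
        # multiplying every cell count by k multiplies the recovered P by k
        observed = reference_observed(5e9)
        base = calibrate_P(observed, BANDS, KINETICS).model.P
        k = 10.0
        denser = GrowthModel(cell_density_per_cm3=KINETICS.cell_density_per_cm3 * k)
        scaled = calibrate_P(observed, BANDS, denser).model.P
        assert scaled == pytest.approx(k * base, rel=1e-6)

    def test_all_degenerate_probabilities_fail(self):
        with pytest.raises(ValueError, match="calibration failure"):
            calibrate_P({"T1A": 0.0, "T1B": 0.0}, BANDS, KINETICS)

    def test_fit_of_reference_column_has_small_residuals(self, scenario_config):
        result = calibrate_P(
            scenario_config.observed_reference, scenario_config.bands, scenario_config.growth
        )
        assert result.rmse < 0.02
        assert all(abs(r) < 0.03 for r in result.residuals.values())


class TestStageProbabilities:
    def table(self, waiting, model, **kw):
        defaults = dict(
            bands=BANDS,
            kinetics=KINETICS,
            reference_waiting_months=32.0,
            thresholds=Thresholds.from_cells(),
        )
        defaults.update(kw)
        return stage_probabilities(waiting, model, **defaults)

    def test_reference_strategy_reproduces_model_column(self):
        model = MetastasisModel(P=7e9)
        table = self.table(32.0, model)
        for _, row in table[table["note"] == ""].iterrows():
            band = next(b for b in BANDS if b.label == row["stage"])
            n = cells_from_diameter(band.representative_diameter_mm)
            assert row["point"] == pytest.approx(model.pr_met(n), rel=1e-12)

    def test_shorter_wait_never_raises_probability(self):
        model = MetastasisModel(P=7e9)
        t16 = self.table(16.0, model).set_index("stage")["point"]
        t22 = self.table(22.0, model).set_index("stage")["point"]
        t32 = self.table(32.0, model).set_index("stage")["point"]
        informative = [s for s in t32.index if not math.isnan(t32[s])]
        assert informative
        for stage in informative:
            assert t16[stage] <= t22[stage] <= t32[stage]

    def test_waiting_time_effect_matches_growth_law(self):
        # analytic oracle: rewind the band's cell count by the waiting-time
        # difference, then apply the Poisson law directly
        model = MetastasisModel(P=7e9)
        wait = 22.0
        table = self.table(wait, model).set_index("stage")
        band = next(b for b in BANDS if b.label == "T1C")
        n_ref = cells_from_diameter(band.representative_diameter_mm)
        n = advance_cells(n_ref, (wait - 32.0) * DAYS_PER_MONTH, KINETICS)
        assert table.loc["T1C", "point"] == pytest.approx(model.pr_met(n), rel=1e-12)

    def test_bands_beyond_palpability_get_sentinel(self):
        table = self.table(32.0, MetastasisModel(P=7e9))
        sentinel = table[table["note"] == BEYOND_PALPABILITY]
        assert set(sentinel["stage"]) == {"T2+", "T3"}
        assert sentinel["point"].isna().all()

    def test_nonpositive_waiting_time_rejected(self):
        with pytest.raises(ValueError):
            self.table(0.0, MetastasisModel(P=7e9))

    def test_csv_round_trip(self, tmp_path):
        table = self.table(22.0, MetastasisModel(P=7e9), strategy_label="22-month")
        path = tmp_path / "probs.csv"
        write_stage_probabilities(table, path)
        back = read_stage_probabilities(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, atol=1e-12)
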