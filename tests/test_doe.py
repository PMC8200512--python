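"""Taguchi L27 construction, response computation, effects and ANOVA."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from beamtune import (
    BeamModelParams,
    build_l27,
    compute_responses,
    design_to_settings,
    effects_and_anova,
    interaction_surface,
    output_factor,
)
from beamtune.doe import (
    HD_FFF_LEVELS,
    HD_LEVELS,
    MILLENNIUM_LEVELS,
    OF_FIELD_SIZES,
)


@pytest.fixture(scope="module")
def design():
    return build_l27()


def planted_responses(design, column, effect=(0.0, 1.0, 2.0), noise_sd=0.05, seed=1):
    """Response = a pure function of one column's level + small iid noise."""
    rng = np.random.default_rng(seed)
    levels = design.array[:, column - 1]
    y = np.array([effect[lv - 1] for lv in levels]) + noise_sd * rng.standard_normal(27)
    return pd.DataFrame({5.0: y}, index=pd.RangeIndex(1, 28, name="trial"))


class TestBuildL27:
    def test_twenty_seven_trials_thirteen_columns(self, design):
        assert design.array.shape == (27, 13)

    def test_level_balance_and_pairwise_orthogonality(self, design):
        for k in range(13):
            assert Counter(design.array[:, k]) == {1: 9, 2: 9, 3: 9}
        for i in range(13):
            for j in range(i + 1, 13):
                pairs = Counter(zip(design.array[:, i], design.array[:, j]))
                assert all(v == 3 for v in pairs.values()) and len(pairs) == 9

    def test_column_budget(self, design):
        used = set(design.factor_columns.values())
        for cols in design.interaction_columns.values():
            used.update(cols)
        assert used | set(design.error_columns) == set(range(1, 14))
        assert not used & set(design.error_columns)

    def test_too_many_factors_rejected(self):
        with pytest.raises(ValueError, match="column budget|at most"):
            build_l27(["a", "b", "c", "d", "e"], interactions=[])

    def test_conflicting_interaction_rejected(self, design):
        # sigma_x * sigma_y needs the columns already spent on dlg * sigma_y
        with pytest.raises(ValueError, match="occupied"):
            build_l27(
                interactions=[("dlg", "sigma_x"), ("dlg", "sigma_y"),
                              ("sigma_x", "dlg")],
            )


class TestDesignToSettings:
    def test_all_level_two_row_maps_to_published_millennium_values(self, design):
        settings = design_to_settings(design, MILLENNIUM_LEVELS)
        rows = design.array
        idx = [
            i for i in range(27)
            if all(rows[i, c - 1] == 2 for c in design.factor_columns.values())
        ]
        assert len(idx) == 1
        p = settings[idx[0]]
        assert (p.sigma_x, p.sigma_y, p.dlg, p.transmission) == (1.3, 1.1, 2.3, 0.018)

    def test_all_level_one_row_maps_to_published_fff_values(self, design):
        settings = design_to_settings(design, HD_FFF_LEVELS)
        first = settings[0]  # trial 1 is the all-ones row by construction
        assert (first.sigma_x, first.sigma_y, first.dlg, first.transmission) == (
            0.0, 0.0, 0.0, 0.008,
        )

    def test_bad_level_index_rejected(self):
        with pytest.raises(ValueError):
            MILLENNIUM_LEVELS.value("dlg", 4)


class TestComputeResponses:
    def test_zero_when_calc_equals_corrected_measured(self, design):
        settings = design_to_settings(design, HD_LEVELS)
        truth = BeamModelParams(sigma_x=0.6, sigma_y=0.6, dlg=1.5, transmission=0.012)
        corr = {"diamond": 1.02, "diode": 1.04}
        measured = {
            det: {fs: output_factor(fs, truth) / c for fs in OF_FIELD_SIZES}
            for det, c in corr.items()
        }
        resp = compute_responses(
            [truth] * 27, measured, lambda p, fs: output_factor(fs, p), corr
        )
        assert np.allclose(resp.to_numpy(), 0.0, atol=1e-12)

    def test_detector_disagreement_averages_to_midpoint(self, design):
        measured = {"a": {10.0: 0.90}, "b": {10.0: 0.92}}
        resp = compute_responses(
            [BeamModelParams()], measured, lambda p, fs: 0.95, {"a": 1.0, "b": 1.0}
        )
        assert resp.loc[1, 10.0] == pytest.approx(100 * (0.95 - 0.91))

    def test_unit_correction_uses_raw_ratio(self):
        measured = {"a": {10.0: 0.9}}
        resp = compute_responses(
            [BeamModelParams()], measured, lambda p, fs: 0.9, {"a": 1.0}
        )
        assert resp.loc[1, 10.0] == pytest.approx(0.0)


class TestEffectsAndAnova:
    def test_planted_main_effect_is_the_only_significant_source(self, design):
        resp = planted_responses(design, design.factor_columns["dlg"])
        effects, anova = effects_and_anova(design, resp, alpha=0.01)
        assert anova.significant_sources(5.0) == ["dlg"]
        assert not anova.degenerate[5.0]

    def test_sum_of_squares_decomposition_is_exact(self, design, rng):
        y = rng.standard_normal(27)
        resp = pd.DataFrame({5.0: y}, index=pd.RangeIndex(1, 28, name="trial"))
        _, anova = effects_and_anova(design, resp)
        t = anova.tables[5.0]
        total = float(np.sum((y - y.mean()) ** 2))
        assert t["ss"].sum() == pytest.approx(total, rel=1e-12)
        assert int(t["df"].sum()) == 26

    def test_constant_responses_nothing_significant(self, design):
        resp = pd.DataFrame({5.0: np.full(27, 3.0)},
                            index=pd.RangeIndex(1, 28, name="trial"))
        effects, anova = effects_and_anova(design, resp)
        assert anova.significant_sources(5.0) == []
        assert np.allclose(effects.amplitudes.to_numpy(), 0.0)

    def test_noise_free_single_column_response_flags_degenerate_error(self, design):
        resp = planted_responses(design, design.factor_columns["dlg"], noise_sd=0.0)
        _, anova = effects_and_anova(design, resp)
        assert anova.degenerate[5.0]
        # ranking falls back to sum of squares: the planted factor leads
        t = anova.tables[5.0].drop(index="error")
        assert t.index[0] == "dlg"
        assert t["ss"].iloc[1:].max() == pytest.approx(0.0, abs=1e-20)

    def test_planted_interaction_cell_recovered(self, design):
        # one deviant (dlg level 1, sigma_x level 3) cell on top of noise
        rng = np.random.default_rng(1)
        la = design.array[:, design.factor_columns["dlg"] - 1]
        lb = design.array[:, design.factor_columns["sigma_x"] - 1]
        y = 0.05 * rng.standard_normal(27)
        y[(la == 1) & (lb == 3)] -= 7.0
        resp = pd.DataFrame({5.0: y}, index=pd.RangeIndex(1, 28, name="trial"))
        _, anova = effects_and_anova(design, resp)
        assert "dlg*sigma_x" in anova.significant_sources(5.0)
        surface = interaction_surface(design, y, ("dlg", "sigma_x"))
        i, j = np.unravel_index(np.argmin(surface), surface.shape)
        assert (i, j) == (0, 2)

    def test_matches_statsmodels_ols_decomposition(self, design, rng):
        # independent oracle: OLS ANOVA with categorical mains + the two
        # assigned interactions must reproduce the column sums of squares
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        y = rng.standard_normal(27)
        resp = pd.DataFrame({5.0: y}, index=pd.RangeIndex(1, 28, name="trial"))
        _, anova = effects_and_anova(design, resp)
        df = pd.DataFrame(
            {
                name: design.array[:, col - 1]
                for name, col in design.factor_columns.items()
            }
        )
        df["y"] = y
        model = smf.ols(
            "y ~ C(sigma_x) + C(sigma_y) + C(dlg) + C(transmission)"
            " + C(dlg):C(sigma_x) + C(dlg):C(sigma_y)",
            data=df,
        ).fit()
        table = sm.stats.anova_lm(model, typ=2)
        ours = anova.tables[5.0]
        assert ours.loc["dlg", "ss"] == pytest.approx(table.loc["C(dlg)", "sum_sq"])
        assert ours.loc["sigma_x", "ss"] == pytest.approx(
            table.loc["C(sigma_x)", "sum_sq"]
        )
        assert ours.loc["dlg*sigma_x", "ss"] == pytest.approx(
            table.loc["C(dlg):C(sigma_x)", "sum_sq"]
        )
        assert ours.loc["error", "ss"] == pytest.approx(
            table.loc["Residual", "sum_sq"]
        )

    def test_engine_monotonic_directions_match_small_field_behaviour(self, design):
        # whenever a main factor is significant, its level-mean trend has the
        # expected direction: the response falls as DLG or T falls and as
        # sigma_x / sigma_y rises
        rng = np.random.default_rng(3)
        settings = design_to_settings(design, HD_LEVELS)
        truth = BeamModelParams(sigma_x=0.6, sigma_y=0.6, dlg=1.2, transmission=0.012)
        measured = {"det": {fs: output_factor(fs, truth) for fs in OF_FIELD_SIZES}}
        resp = compute_responses(
            settings, measured, lambda p, fs: output_factor(fs, p), {"det": 1.0}
        )
        resp = resp + 0.05 * rng.standard_normal(resp.shape)
        effects, anova = effects_and_anova(design, resp)
        increasing = {"dlg": True, "transmission": True,
                      "sigma_x": False, "sigma_y": False}
        # adjacent sigma levels (0 vs 0.6 mm) are nearly degenerate at a
        # 2.5 mm half-field, so the direction check compares the extreme
        # levels of each significant main factor on the smallest field
        checked = 0
        for factor in anova.significant_sources(5.0):
            if factor not in increasing:
                continue
            means = effects.level_means[(factor, 5.0)]
            trend = means[2] - means[0]
            assert trend > 0 if increasing[factor] else trend < 0
            checked += 1
        assert checked >= 2  # the smallest field must flag several main factors

    def test_significant_count_nonincreasing_with_field_size(self, design):
        # engine-generated responses + reproducibility-level noise: sensitivity
        # concentrates in the smallest fields
        rng = np.random.default_rng(2)
        settings = design_to_settings(design, HD_LEVELS)
        truth = BeamModelParams(sigma_x=0.6, sigma_y=0.6, dlg=1.2, transmission=0.012)
        measured = {"det": {fs: output_factor(fs, truth) for fs in OF_FIELD_SIZES}}
        resp = compute_responses(
            settings, measured, lambda p, fs: output_factor(fs, p), {"det": 1.0}
        )
        resp = resp + 0.3 * rng.standard_normal(resp.shape)  # percent-scale noise
        _, anova = effects_and_anova(design, resp)
        counts = [len(anova.significant_sources(fs)) for fs in sorted(anova.tables)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestInteractionSurface:
    def test_additive_response_has_parallel_rows(self, design):
        la = design.array[:, design.factor_columns["dlg"] - 1].astype(float)
        lb = design.array[:, design.factor_columns["sigma_x"] - 1].astype(float)
        y = 2.0 * la - 3.0 * lb
        s = interaction_surface(design, y, ("dlg", "sigma_x"))
        row_profiles = s - s[:, :1]
        assert np.ptp(row_profiles, axis=0).max() < 1e-12

    def test_constant_response_all_cells_equal(self, design):
        s = interaction_surface(design, np.full(27, 1.5), ("dlg", "sigma_y"))
        np.testing.assert_allclose(s, 1.5)

    def test_three_observations_per_cell(self, design):
        la = design.array[:, design.factor_columns["dlg"] - 1]
        lb = design.array[:, design.factor_columns["sigma_x"] - 1]
        counts = Counter(zip(la, lb))
        assert all(v == 3 for v in counts.values())
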