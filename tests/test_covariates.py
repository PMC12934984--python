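import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugcourts import (
    TertileBins,
    build_design,
    fit_principal_index,
    fit_tertiles,
    score_index,
    targeting_index,
)
from drugcourts.covariates import (
    MAIN_EFFECT_NAMES,
    CovariateTransforms,
    fit_transforms,
)

from conftest import manual_panel


class TestTargetingIndex:
    def test_forced_arithmetic(self):
        assert targeting_index(50, 300, 200) == pytest.approx(0.1)

    def test_zero_numerator(self):
        assert targeting_index(0, 10, 10) == 0.0

    def test_zero_denominator_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            out = targeting_index(5, 0, 0)
        assert math.isnan(out)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            targeting_index(-1, 10, 10)

    def test_vectorized(self):
        out = targeting_index([50, 0], [300, 10], [200, 10])
        np.testing.assert_allclose(out, [0.1, 0.0])


class TestTertiles:
    def test_one_through_nine_order_statistic_oracle(self):
        values = np.arange(1.0, 10.0)

        # oracle: empirical-CDF (type-1) quantile is the ceil(p*n)-th order stat
        def type1_quantile(sorted_vals, p):
            n = len(sorted_vals)
            return sorted_vals[max(math.ceil(p * n), 1) - 1]

        bins = fit_tertiles(values)
        assert bins.lower == type1_quantile(np.sort(values), 1 / 3) == 3.0
        assert bins.upper == type1_quantile(np.sort(values), 2 / 3) == 6.0

    def test_all_identical_classified_middle(self):
        bins = fit_tertiles(np.full(10, 0.5))
        assert bins.lower == bins.upper == 0.5
        assert set(bins.classify(np.full(10, 0.5))) == {"middle"}

    def test_boundary_values_go_middle(self):
        bins = TertileBins(lower=0.107, upper=0.217)
        labels = bins.classify([0.106, 0.107, 0.2, 0.217, 0.218])
        assert list(labels) == ["low", "middle", "middle", "middle", "high"]

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="3"):
            fit_tertiles([0.1, 0.2])

    def test_nan_excluded_from_fit(self):
        bins = fit_tertiles([0.1, 0.2, 0.3, np.nan])
        assert np.isfinite(bins.lower)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=3, max_value=80))
    def test_classification_near_thirds_for_distinct_values(self, n):
        n *= 3  # divisible by 3
        values = np.random.default_rng(n).permutation(np.arange(n, dtype=float))
        bins = fit_tertiles(values)
        labels = bins.classify(values)
        counts = {lab: int((labels == lab).sum()) for lab in ("low", "middle", "high")}
        for lab, c in counts.items():
            assert abs(c - n / 3) <= 2, (lab, counts)


class TestPrincipalIndex:
    def _panel_with(self, **columns):
        counties = [f"C{i}" for i in range(40)]
        years = [2017, 2018, 2019]
        deaths = np.zeros((40, 3), dtype=int)
        pop = np.full((40, 3), 10_000)
        return manual_panel(counties, years, deaths, pop, **columns)

    def test_two_perfectly_correlated_variables(self):
        rng = np.random.default_rng(1)
        v = np.repeat(rng.normal(15, 3, 40)[:, None], 3, axis=1)
        panel = self._panel_with(poverty_pct=v, unemployed_pct=2 * v + 1)
        model = fit_principal_index(
            panel, ["poverty_pct", "unemployed_pct"], "poverty_pct"
        )
        # oracle: leading eigenvector of [[1, 1], [1, 1]] is (1, 1)/sqrt(2)
        np.testing.assert_allclose(model.weights, [2**-0.5, 2**-0.5], atol=1e-8)
        assert model.explained_variance_ratio == pytest.approx(1.0)

    def test_anchor_orientation_flips_sign(self):
        rng = np.random.default_rng(2)
        v = np.repeat(rng.normal(15, 3, 40)[:, None], 3, axis=1)
        # anti-correlated pair: unanchored eigenvector sign is arbitrary
        panel = self._panel_with(poverty_pct=v, unemployed_pct=30 - v)
        m_pov = fit_principal_index(panel, ["poverty_pct", "unemployed_pct"], "poverty_pct")
        m_unemp = fit_principal_index(panel, ["poverty_pct", "unemployed_pct"], "unemployed_pct")
        np.testing.assert_allclose(np.abs(m_pov.weights), np.abs(m_unemp.weights), atol=1e-10)
        np.testing.assert_allclose(m_pov.weights, -m_unemp.weights, atol=1e-10)
        assert m_pov.weights[0] > 0 and m_unemp.weights[1] > 0

    def test_three_independent_variables_near_identity(self):
        rng = np.random.default_rng(3)
        cols = {
            "poverty_pct": np.clip(rng.normal(15, 3, (40, 3)), 0, 100),
            "unemployed_pct": np.clip(rng.normal(6, 1, (40, 3)), 0, 100),
            "disabled_pct": np.clip(rng.normal(12, 2, (40, 3)), 0, 100),
        }
        panel = self._panel_with(**cols)
        names = list(cols)
        model = fit_principal_index(panel, names, "poverty_pct")
        # oracle: eigendecomposition of the pooled sample correlation matrix
        frame = panel.data[panel.data.year >= 2018][names].to_numpy()
        z = (frame - frame.mean(0)) / frame.std(0)
        eigvals = np.linalg.eigvalsh(z.T @ z / len(z))
        assert model.explained_variance_ratio == pytest.approx(
            eigvals[-1] / eigvals.sum(), abs=1e-10
        )
        assert abs(model.explained_variance_ratio - 1 / 3) < 0.15

    def test_zero_variance_variable_named(self):
        panel = self._panel_with(poverty_pct=np.full((40, 3), 10.0))
        with pytest.raises(ValueError, match="poverty_pct"):
            fit_principal_index(panel, ["poverty_pct", "unemployed_pct"], "poverty_pct")

    def test_single_variable_rejected(self):
        panel = self._panel_with()
        with pytest.raises(ValueError, match="2 variables"):
            fit_principal_index(panel, ["poverty_pct"], "poverty_pct")


class TestScoreIndex:
    def _fitted(self):
        rng = np.random.default_rng(4)
        counties = [f"C{i}" for i in range(30)]
        v1 = np.clip(rng.normal(15, 3, (30, 4)), 0, 100)
        v2 = np.clip(0.7 * v1 + rng.normal(0, 1, (30, 4)), 0, 100)
        panel = manual_panel(
            counties, [2017, 2018, 2019, 2020],
            np.zeros((30, 4), int), np.full((30, 4), 10_000),
            poverty_pct=v1, unemployed_pct=v2,
        )
        model = fit_principal_index(panel, ["poverty_pct", "unemployed_pct"], "poverty_pct")
        return panel, model

    def test_pooled_mean_scores_zero(self):
        panel, model = self._fitted()
        scores = score_index(model, panel)
        # oracle: direct summation of the projected standardized matrix
        assert scores.to_numpy().sum() == pytest.approx(0.0, abs=1e-9)

    def test_raising_anchor_raises_score(self):
        panel, model = self._fitted()
        bumped_data = panel.data.copy()
        bumped_data.loc[bumped_data.year >= 2018, "poverty_pct"] += 5.0
        bumped = panel.__class__(bumped_data, window=panel.window)
        assert (
            score_index(model, bumped).to_numpy() > score_index(model, panel).to_numpy()
        ).all()

    def test_scores_match_manual_projection(self):
        panel, model = self._fitted()
        frame = panel.data[panel.data.year >= 2018]
        z = (frame[list(model.variable_names)].to_numpy() - model.centers) / model.scales
        manual = z @ model.weights
        np.testing.assert_allclose(
            np.sort(score_index(model, panel).to_numpy()), np.sort(manual), atol=1e-10
        )


class TestBuildDesign:
    def test_model1_has_no_interaction_block(self, small_sim, lattice_graph):
        panel, _ = small_sim
        design = build_design(panel, lattice_graph, include_interactions=False)
        assert design.interactions is None
        assert design.main_effects.shape == (
            panel.n_counties, panel.n_years - 1, len(MAIN_EFFECT_NAMES)
        )

    def test_untreated_interaction_rows_zero(self, small_sim, lattice_graph):
        panel, _ = small_sim
        design = build_design(panel, lattice_graph, include_interactions=True)
        untreated = design.exposure == 0
        assert np.all(design.interactions[untreated] == 0)

    def test_interactions_are_exact_products(self, small_sim, lattice_graph):
        panel, _ = small_sim
        design = build_design(panel, lattice_graph, include_interactions=True)
        np.testing.assert_array_equal(
            design.interactions, design.main_effects * design.exposure[..., None]
        )

    def test_targeting_indicators_mutually_exclusive(self, small_sim, lattice_graph):
        panel, _ = small_sim
        design = build_design(panel, lattice_graph, include_interactions=True)
        low = design.main_effects[..., MAIN_EFFECT_NAMES.index("low_targeting")]
        high = design.main_effects[..., MAIN_EFFECT_NAMES.index("high_targeting")]
        assert np.all(low * high == 0)

    def test_continuous_columns_standardized(self, small_sim, lattice_graph):
        panel, _ = small_sim
        design = build_design(panel, lattice_graph, include_interactions=False)
        for name in ("crime_rate", "poverty_index", "healthcare_index"):
            col = design.main_effects[..., MAIN_EFFECT_NAMES.index(name)].ravel()
            # oracle: direct summation
            assert col.sum() / col.size == pytest.approx(0.0, abs=1e-8)
            assert np.sqrt((col**2).sum() / col.size - (col.mean()) ** 2) == pytest.approx(
                1.0, abs=1e-8
            )

    def test_build_design_is_pure(self, small_sim, lattice_graph):
        panel, _ = small_sim
        transforms = fit_transforms(panel)
        d1 = build_design(panel, lattice_graph, True, transforms=transforms)
        d2 = build_design(panel, lattice_graph, True, transforms=transforms)
        np.testing.assert_array_equal(d1.main_effects, d2.main_effects)
        np.testing.assert_array_equal(d1.exposure, d2.exposure)
        np.testing.assert_array_equal(d1.interactions, d2.interactions)


class TestTransformsSidecar:
    def test_json_round_trip_preserves_scores(self, small_sim, tmp_path):
        panel, _ = small_sim
        transforms = fit_transforms(panel)
        path = tmp_path / "transforms.json"
        transforms.to_json(path)
        loaded = CovariateTransforms.from_json(path)
        assert loaded.tertiles == transforms.tertiles
        np.testing.assert_allclose(
            loaded.poverty_index.weights, transforms.poverty_index.weights
        )
        np.testing.assert_allclose(
            score_index(loaded.healthcare_index, panel).to_numpy(),
            score_index(transforms.healthcare_index, panel).to_numpy(),
            atol=1e-12,
        )
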