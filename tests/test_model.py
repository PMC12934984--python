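import numpy as np
import pytest

from drugcourts import (
    AdjacencyGraph,
    ModelSpec,
    ParameterState,
    PriorConfig,
    icar_log_kernel,
    log_likelihood,
    log_posterior,
    log_prior,
    log_rate,
    log_rate_matrix,
    make_lattice_graph,
)
from drugcourts.covariates import MAIN_EFFECT_NAMES
from scipy import stats

from conftest import manual_design, manual_panel

P = len(MAIN_EFFECT_NAMES)


def make_state(n, beta0=0.0, delta=0.0, gamma=None, phi=None, alpha=None, tau=1.0,
               beta=None, components=None):
    return ParameterState(
        alpha=np.full(n, -9.0) if alpha is None else np.asarray(alpha, float),
        beta0=beta0,
        beta=np.zeros(P) if beta is None else np.asarray(beta, float),
        delta=delta,
        gamma=np.zeros(0) if gamma is None else np.asarray(gamma, float),
        phi=np.zeros(n) if phi is None else np.asarray(phi, float),
        tau=tau,
        components=components,
    )


class TestIcarKernel:
    def test_constant_phi_is_zero(self):
        graph = make_lattice_graph(3, 3)
        assert icar_log_kernel(np.full(9, 2.7), graph, tau=3.0) == 0.0

    def test_two_node_hand_value(self):
        graph = AdjacencyGraph.from_edges([("A", "B")])
        assert icar_log_kernel(np.array([1.0, -1.0]), graph, tau=1.0) == pytest.approx(-2.0)

    def test_matches_dense_quadratic_form_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            graph = make_lattice_graph(1, 5) if rng.uniform() < 0.5 else make_lattice_graph(5, 1)
            # densify with random chords
            extra = [(f"C{i:04d}", f"C{j:04d}") for i in range(5) for j in range(i + 2, 5)
                     if rng.uniform() < 0.4]
            graph = AdjacencyGraph.from_edges(list(graph.edges) + extra, nodes=graph.nodes)
            phi = rng.normal(size=5)
            tau = float(rng.gamma(2.0, 1.0)) + 0.1
            lap = graph.laplacian()
            expected = -0.5 * tau * phi @ lap @ phi
            assert icar_log_kernel(phi, graph, tau) == pytest.approx(expected, abs=1e-10)

    def test_constant_shift_invariance_within_component(self):
        graph = make_lattice_graph(2, 3)
        rng = np.random.default_rng(1)
        phi = rng.normal(size=6)
        a = icar_log_kernel(phi, graph, tau=2.0)
        b = icar_log_kernel(phi + 17.3, graph, tau=2.0)
        assert a == pytest.approx(b, abs=1e-8)

    def test_nonpositive_tau_rejected(self):
        graph = make_lattice_graph(2, 2)
        with pytest.raises(ValueError):
            icar_log_kernel(np.zeros(4), graph, tau=0.0)


class TestLogRate:
    def test_identity_transition(self):
        design = manual_design(["A"], (2018, 2019, 2020), 2017)
        state = make_state(1, alpha=[-8.0])
        for year in (2017, 2018, 2019, 2020):
            assert log_rate(state, design, "A", year) == pytest.approx(-8.0)

    def test_drug_court_rate_ratio_084(self):
        # exposure alone with delta = log(0.84): consecutive-year ratio 0.84
        design = manual_design(["A"], (2018, 2019), 2017, exposure=[[1.0, 1.0]])
        state = make_state(1, delta=np.log(0.84))
        r1 = np.exp(log_rate(state, design, "A", 2018) - log_rate(state, design, "A", 2017))
        r2 = np.exp(log_rate(state, design, "A", 2019) - log_rate(state, design, "A", 2018))
        assert r1 == pytest.approx(0.84)
        assert r2 == pytest.approx(0.84)

    def test_high_targeting_interaction_cancels_benefit(self):
        x = np.zeros((1, 1, P))
        x[0, 0, MAIN_EFFECT_NAMES.index("high_targeting")] = 1.0
        design = manual_design(["A"], (2018,), 2017, main_effects=x,
                               exposure=[[1.0]], interactions=True)
        gamma = np.zeros(P)
        gamma[MAIN_EFFECT_NAMES.index("high_targeting")] = np.log(1.21)
        beta = np.zeros(P)  # isolate the exposure and its interaction
        state = make_state(1, delta=np.log(0.84), gamma=gamma, beta=beta)
        ratio = np.exp(log_rate(state, design, "A", 2018) - log_rate(state, design, "A", 2017))
        assert ratio == pytest.approx(0.84 * 1.21)
        assert ratio == pytest.approx(1.0164)

    def test_recursion_matches_vectorized_matrix(self, small_sim):
        _, truth = small_sim
        design = truth.design
        mat = log_rate_matrix(truth.state, design)
        years = (design.baseline_year,) + design.years
        for i, county in enumerate(design.counties[:5]):
            for j, year in enumerate(years):
                assert log_rate(truth.state, design, county, year) == pytest.approx(
                    mat[i, j], abs=1e-10
                )

    def test_year_outside_window_rejected(self):
        design = manual_design(["A"], (2018,), 2017)
        state = make_state(1)
        with pytest.raises(ValueError):
            log_rate(state, design, "A", 2025)

    def test_beta0_translation_compounds(self):
        design = manual_design(["A", "B"], (2018, 2019, 2020), 2017)
        base = make_state(2, beta0=0.3)
        shifted = make_state(2, beta0=0.3 + 0.1)
        m0 = log_rate_matrix(base, design)
        m1 = log_rate_matrix(shifted, design)
        for t in range(4):
            np.testing.assert_allclose(m1[:, t] - m0[:, t], 0.1 * t, atol=1e-12)

    def test_rates_strictly_positive_finite(self, small_sim):
        _, truth = small_sim
        lam = np.exp(log_rate_matrix(truth.state, truth.design))
        assert np.all(lam > 0) and np.all(np.isfinite(lam))


class TestLogLikelihood:
    def test_zero_count_cell_is_minus_mu(self):
        design = manual_design(["A"], (2018,), 2017)
        panel = manual_panel(["A"], [2017, 2018], np.array([[0, 0]]), np.array([[1000, 1000]]))
        state = make_state(1, alpha=[np.log(5 / 1000)])
        # both cells have mean 5; Poisson logpmf at zero is -mu
        assert log_likelihood(state, panel, design) == pytest.approx(-10.0)

    def test_matches_per_cell_pmf_oracle(self, small_sim):
        panel, truth = small_sim
        ll = log_likelihood(truth.state, panel, truth.design)
        lam = np.exp(log_rate_matrix(truth.state, truth.design))
        expected = 0.0
        for i in range(panel.n_counties):
            for t in range(panel.n_years):
                expected += stats.poisson.logpmf(
                    int(panel.deaths[i, t]), panel.population[i, t] * lam[i, t]
                )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_doubling_population_doubles_zero_cell_contribution(self):
        design = manual_design(["A"], (2018,), 2017)
        small = manual_panel(["A"], [2017, 2018], np.zeros((1, 2), int), np.full((1, 2), 1000))
        big = manual_panel(["A"], [2017, 2018], np.zeros((1, 2), int), np.full((1, 2), 2000))
        state = make_state(1, alpha=[np.log(0.004)])
        assert log_likelihood(state, big, design) == pytest.approx(
            2 * log_likelihood(state, small, design)
        )

    def test_negative_counts_rejected(self, small_sim):
        panel, truth = small_sim
        bad = panel.deaths.copy()
        with pytest.raises(ValueError):
            # bypass panel validation by patching the matrix path
            class Fake:
                deaths = bad * -1 - 1
                population = panel.population
            log_likelihood(truth.state, Fake(), truth.design)


class TestLogPosterior:
    def test_equals_sum_of_components(self, small_sim, lattice_graph):
        panel, truth = small_sim
        rng = np.random.default_rng(7)
        state = truth.state.replace(
            beta0=truth.state.beta0 + rng.normal(0, 0.05),
            phi=truth.state.phi + rng.normal(0, 0.1, panel.n_counties),
        )
        lp = log_posterior(state, panel, truth.design, lattice_graph, truth.spec)
        expected = (
            log_likelihood(state, panel, truth.design)
            + icar_log_kernel(state.phi, lattice_graph, state.tau, order=truth.design.counties)
            + log_prior(state, lattice_graph, truth.spec)
        )
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_prior_neutral_perturbations_track_likelihood(self, small_sim, lattice_graph):
        # states symmetric around the prior centers have equal prior mass,
        # so their posterior difference equals their likelihood difference
        panel, truth = small_sim
        spec = truth.spec
        center = spec.priors.baseline_loc
        s_plus = make_state(panel.n_counties, beta0=0.2, gamma=np.zeros(P),
                            alpha=np.full(panel.n_counties, center + 0.5))
        s_minus = make_state(panel.n_counties, beta0=-0.2, gamma=np.zeros(P),
                             alpha=np.full(panel.n_counties, center - 0.5))
        dp = log_posterior(s_plus, panel, truth.design, lattice_graph, spec) - log_posterior(
            s_minus, panel, truth.design, lattice_graph, spec
        )
        dl = log_likelihood(s_plus, panel, truth.design) - log_likelihood(
            s_minus, panel, truth.design
        )
        assert dp == pytest.approx(dl, abs=1e-8)

    def test_tight_priors_dominate(self, small_sim, lattice_graph):
        panel, truth = small_sim
        tight = ModelSpec(
            include_interactions=True,
            priors=PriorConfig(coef_scale=1e-6, baseline_loc=-9.0, baseline_scale=1e-6),
        )
        at_center = make_state(panel.n_counties, gamma=np.zeros(P))
        away = make_state(panel.n_counties, beta0=0.05, gamma=np.zeros(P))
        assert log_posterior(at_center, panel, truth.design, lattice_graph, tight) > (
            log_posterior(away, panel, truth.design, lattice_graph, tight)
        )


class TestParameterState:
    def test_constructor_centers_phi(self):
        state = make_state(4, phi=np.array([1.0, 2.0, 3.0, 4.0]))
        assert state.phi.sum() == pytest.approx(0.0, abs=1e-12)

    def test_centering_per_component(self):
        comps = np.array([0, 0, 1, 1])
        state = make_state(4, phi=np.array([1.0, 2.0, 10.0, 20.0]), components=comps)
        assert state.phi[:2].sum() == pytest.approx(0.0, abs=1e-12)
        assert state.phi[2:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            make_state(2, tau=-1.0)


class TestModelSpec:
    def test_interaction_names_empty_for_model1(self):
        spec = ModelSpec(include_interactions=False)
        assert spec.interaction_names == ()

    def test_json_round_trip(self, tmp_path):
        spec = ModelSpec(include_interactions=True,
                         priors=PriorConfig(coef_scale=5.0, tau_rate=0.1))
        path = tmp_path / "spec.json"
        spec.to_json(path)
        again = ModelSpec.from_json(path)
        assert again == spec

    def test_bad_prior_scale_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(coef_scale=-1.0)
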