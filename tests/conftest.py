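import numpy as np
import pandas as pd
import pytest

from drugcourts import (
    AdjacencyGraph,
    CountyYearPanel,
    DesignMatrices,
    IndexModel,
    McmcConfig,
    TertileBins,
    TruthConfig,
    fit,
    make_lattice_graph,
    simulate_panel,
)
from drugcourts.covariates import MAIN_EFFECT_NAMES, CovariateTransforms, Standardizer
from drugcourts.inference import PosteriorSamples
from drugcourts.model import ModelSpec


def dummy_transforms() -> CovariateTransforms:
    """Structurally valid transformers for hand-built designs."""
    def index(names, anchor):
        w = np.zeros(len(names))
        w[names.index(anchor)] = 1.0
        return IndexModel(
            variable_names=tuple(names),
            weights=w,
            centers=np.zeros(len(names)),
            scales=np.ones(len(names)),
            orientation_anchor=anchor,
        )

    return CovariateTransforms(
        tertiles=TertileBins(lower=0.1, upper=0.2),
        poverty_index=index(
            ["poverty_pct", "unemployed_pct", "disabled_pct", "food_stamps_pct",
             "no_hs_diploma_pct"], "poverty_pct"),
        healthcare_index=index(["uninsured_pct", "mua", "otp_count"], "uninsured_pct"),
        standardizers={
            k: Standardizer(0.0, 1.0)
            for k in ("crime_rate", "poverty_index", "healthcare_index")
        },
    )


def manual_design(
    counties,
    years,
    baseline_year,
    main_effects=None,
    exposure=None,
    interactions=False,
) -> DesignMatrices:
    n, t = len(counties), len(years)
    p = len(MAIN_EFFECT_NAMES)
    x = np.zeros((n, t, p)) if main_effects is None else np.asarray(main_effects, float)
    d = np.zeros((n, t)) if exposure is None else np.asarray(exposure, float)
    z = x * d[..., None] if interactions else None
    return DesignMatrices(
        counties=tuple(counties),
        years=tuple(years),
        baseline_year=baseline_year,
        main_effect_names=MAIN_EFFECT_NAMES,
        main_effects=x,
        exposure=d,
        interactions=z,
        transforms=dummy_transforms(),
    )


def manual_panel(counties, years, deaths, population, **columns) -> CountyYearPanel:
    """Panel with given deaths/population matrices and benign covariates."""
    deaths = np.asarray(deaths)
    population = np.asarray(population)
    defaults = {
        "drug_court": 0, "possession_arrests": 10, "persons_arrests": 30,
        "property_arrests": 40, "crime_rate": 0.01, "hidta": 0, "democrat_da": 0,
        "urban": 0, "mua": 0, "uninsured_pct": 10.0, "poverty_pct": 15.0,
        "unemployed_pct": 5.0, "disabled_pct": 12.0, "food_stamps_pct": 11.0,
        "public_assistance_pct": 2.0, "no_hs_diploma_pct": 13.0, "otp_count": 1,
    }
    defaults.update(columns)
    rows = []
    for i, county in enumerate(counties):
        for j, year in enumerate(years):
            row = {"county_id": county, "year": year,
                   "deaths": int(deaths[i, j]), "population": int(population[i, j])}
            for k, v in defaults.items():
                row[k] = v[i, j] if isinstance(v, np.ndarray) else v
            rows.append(row)
    return CountyYearPanel(pd.DataFrame(rows), window=(min(years), max(years)))


def degenerate_samples(design, state, n_draws=3) -> PosteriorSamples:
    """All draws pinned at a single parameter state."""
    n = len(design.counties)
    q = len(state.gamma)
    spec = ModelSpec(include_interactions=design.has_interactions)
    shape = (1, n_draws)
    return PosteriorSamples(
        alpha=np.broadcast_to(state.alpha, shape + (n,)).copy(),
        beta0=np.full(shape, state.beta0),
        beta=np.broadcast_to(state.beta, shape + (len(state.beta),)).copy(),
        delta=np.full(shape, state.delta),
        gamma=np.broadcast_to(state.gamma, shape + (q,)).copy(),
        phi=np.broadcast_to(state.phi, shape + (n,)).copy(),
        tau=np.full(shape, state.tau),
        seed=0,
        spec=spec,
        counties=design.counties,
    )


@pytest.fixture(scope="session")
def lattice_graph() -> AdjacencyGraph:
    return make_lattice_graph(4, 5)


@pytest.fixture(scope="session")
def truth_config() -> TruthConfig:
    return TruthConfig(
        grid_shape=(4, 5),
        n_years=5,
        delta=-0.17,
        gamma={"high_targeting": 0.19},
        tau=4.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(truth_config, lattice_graph):
    panel, truth = simulate_panel(truth_config, lattice_graph, return_truth=True)
    return panel, truth


@pytest.fixture(scope="session")
def fitted_small(small_sim, lattice_graph):
    panel, truth = small_sim
    samples = fit(
        panel,
        lattice_graph,
        truth.design,
        truth.spec,
        mcmc=McmcConfig(chains=2, warmup=300, draws=300),
        seed=5,
    )
    return panel, truth, samples
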