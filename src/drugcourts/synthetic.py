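"""Fully synthetic county systems generated from the model itself.

Builds lattice adjacency graphs, draws ICAR spatial effects, generates
correlated covariate panels (so the principal-component indices and the
targeting tertiles are exercised), simulates Poisson death counts through
the autoregressive recursion at known parameter values, and runs
parameter-recovery experiments against the fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import MAIN_EFFECT_NAMES, build_design
from .inference import McmcConfig, PosteriorSamples, fit
from .model import ModelSpec, ParameterState, PriorConfig, log_rate_matrix
from .panel import AdjacencyGraph, CountyYearPanel

__all__ = [
    "TruthConfig",
    "SimulationTruth",
    "RecoveryReport",
    "make_lattice_graph",
    "sample_icar",
    "generate_covariates",
    "simulate_panel",
    "recovery_experiment",
]


@dataclass(frozen=True)
class TruthConfig:
    """True parameter values and generating rules for a synthetic system.

    ``beta`` and ``gamma`` map covariate names to true coefficients;
    unnamed covariates get zero.  A non-empty ``gamma`` selects the
    interaction model.  ``grid_shape`` fixes the lattice, so
    ``n_counties == rows * cols``.
    """

    grid_shape: tuple[int, int] = (10, 10)
    n_years: int = 7
    start_year: int = 2017
    beta0: float = 0.05
    beta: Mapping[str, float] = field(default_factory=dict)
    delta: float = -0.17
    gamma: Mapping[str, float] = field(default_factory=dict)
    tau: float = 4.0
    alpha_loc: float = -9.0
    alpha_scale: float = 0.5
    pop_range: tuple[float, float] = (1e4, 1e6)
    treated_fraction: float = 0.3
    poverty_rho: float = 0.8
    confounded_exposure: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape dimensions must be positive")
        if self.n_years < 2:
            raise ValueError("need at least a baseline and one transition year")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for key in list(self.beta) + list(self.gamma):
            if key not in MAIN_EFFECT_NAMES:
                raise ValueError(f"unknown covariate in truth config: {key}")

    @property
    def n_counties(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def include_interactions(self) -> bool:
        return bool(self.gamma)

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(n, 0.0) for n in MAIN_EFFECT_NAMES])

    def gamma_vector(self) -> np.ndarray:
        if not self.include_interactions:
            return np.zeros(0)
        return np.array([self.gamma.get(n, 0.0) for n in MAIN_EFFECT_NAMES])

    def true_terms(self) -> dict[str, float]:
        """Named true coefficient values keyed by model term."""
        out = {"intercept": self.beta0, "drug_court": self.delta}
        for name, b in zip(MAIN_EFFECT_NAMES, self.beta_vector()):
            out[name] = float(b)
        if self.include_interactions:
            for name, g in zip(MAIN_EFFECT_NAMES, self.gamma_vector()):
                out[f"drug_court:{name}"] = float(g)
        return out


def make_lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency lattice with rows*(cols-1) + cols*(rows-1) edges."""
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")

    def node(r: int, c: int) -> str:
        return f"C{r * cols + c:04d}"

    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((node(r, c), node(r, c + 1)))
            if r + 1 < rows:
                edges.append((node(r, c), node(r + 1, c)))
    nodes = [node(r, c) for r in range(rows) for c in range(cols)]
    return AdjacencyGraph.from_edges(edges, nodes=nodes)


def sample_icar(
    graph: AdjacencyGraph,
    tau: float,
    seed: int | np.random.Generator = 0,
    order: Sequence | None = None,
) -> np.ndarray:
    """Draw spatial effects from the sum-to-zero-constrained ICAR law.

    Uses the eigendecomposition of the graph Laplacian with the zero
    eigenvalue(s) excluded, so each connected component sums to zero
    exactly (up to floating point).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = list(order) if order is not None else list(graph.nodes)
    lap = graph.laplacian(order=order)
    eigvals, eigvecs = np.linalg.eigh(lap)
    keep = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    phi = eigvecs[:, keep] @ (z / np.sqrt(tau * eigvals[keep]))
    return phi


def generate_covariates(config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate a covariate/exposure panel (deaths left at zero).

    County-level structure: a shared deprivation factor drives the five
    poverty-block percentages with pairwise correlation ``poverty_rho``;
    a second factor ties the healthcare variables together; arrest counts
    give a realistic spread of the targeting index; drug-court adoption
    is staggered and monotone.
    """
    n = config.n_counties
    counties = [f"C{i:04d}" for i in range(n)]
    years = config.years
    t = len(years)

    population = np.exp(rng.uniform(np.log(config.pop_range[0]), np.log(config.pop_range[1]), n))
    population = np.round(population).astype(int)

    rho = config.poverty_rho
    f_pov = rng.standard_normal(n)
    pov_means = {"poverty_pct": 16.0, "unemployed_pct": 6.0, "disabled_pct": 14.0,
                 "food_stamps_pct": 13.0, "no_hs_diploma_pct": 12.0}
    pov_sds = {"poverty_pct": 4.0, "unemployed_pct": 1.5, "disabled_pct": 3.0,
               "food_stamps_pct": 4.0, "no_hs_diploma_pct": 3.0}
    pov_county = {}
    for name in pov_means:
        eps = rng.standard_normal(n)
        latent = np.sqrt(rho) * f_pov + np.sqrt(1 - rho) * eps
        pov_county[name] = np.clip(pov_means[name] + pov_sds[name] * latent, 0.0, 100.0)

    f_hc = rng.standard_normal(n)
    uninsured = np.clip(12.0 + 3.0 * (0.8 * f_hc + 0.6 * rng.standard_normal(n)), 0.0, 100.0)
    mua = (f_hc + 0.5 * rng.standard_normal(n) > 0.3).astype(int)
    otp = rng.poisson(np.exp(1.0 - 0.5 * f_hc))
    # tiny systems must still exercise the index PCA: force variation
    if n >= 2 and mua.min() == mua.max():
        mua[int(np.argmax(f_hc))] = 1 - mua[0]
    if n >= 2 and otp.min() == otp.max():
        otp[int(np.argmin(f_hc))] += 1

    hidta = (rng.uniform(size=n) < 0.25).astype(int)
    democrat_da = (rng.uniform(size=n) < 0.4).astype(int)
    urban = (rng.uniform(size=n) < 0.3).astype(int)

    # per-county enforcement profile giving targeting indices spanning the bins
    target_level = np.exp(rng.normal(np.log(0.16), 0.55, n))
    arrest_rate = np.exp(rng.normal(np.log(0.012), 0.3, n))  # person+property per capita

    if config.confounded_exposure:
        logits = -1.0 + 0.8 * f_pov + 0.6 * urban
        prob = 1.0 / (1.0 + np.exp(-logits))
        prob *= config.treated_fraction * n / max(prob.sum(), 1e-9)
        treated = rng.uniform(size=n) < np.clip(prob, 0, 1)
    else:
        n_treated = int(round(config.treated_fraction * n))
        treated = np.zeros(n, dtype=bool)
        treated[rng.choice(n, size=n_treated, replace=False)] = True
    start_years = np.full(n, years[-1] + 1)
    start_years[treated] = rng.integers(years[1], years[-1] + 1, size=int(treated.sum()))

    rows = []
    for i, county in enumerate(counties):
        for year in years:
            persons = rng.poisson(0.45 * arrest_rate[i] * population[i])
            prop = rng.poisson(0.55 * arrest_rate[i] * population[i])
            possession = rng.poisson(target_level[i] * max(persons + prop, 1))
            total_arrests = persons + prop + possession
            rows.append(
                {
                    "county_id": county,
                    "year": year,
                    "deaths": 0,
                    "population": population[i],
                    "drug_court": int(year >= start_years[i]),
                    "possession_arrests": possession,
                    "persons_arrests": persons,
                    "property_arrests": prop,
                    "crime_rate": total_arrests / population[i],
                    "hidta": hidta[i],
                    "democrat_da": democrat_da[i],
                    "urban": urban[i],
                    "mua": mua[i],
                    "uninsured_pct": np.clip(uninsured[i] + rng.normal(0, 0.3), 0, 100),
                    "poverty_pct": np.clip(pov_county["poverty_pct"][i] + rng.normal(0, 0.3), 0, 100),
                    "unemployed_pct": np.clip(pov_county["unemployed_pct"][i] + rng.normal(0, 0.2), 0, 100),
                    "disabled_pct": np.clip(pov_county["disabled_pct"][i] + rng.normal(0, 0.3), 0, 100),
                    "food_stamps_pct": np.clip(pov_county["food_stamps_pct"][i] + rng.normal(0, 0.3), 0, 100),
                    "public_assistance_pct": np.clip(2.0 + 0.8 * f_pov[i] + rng.normal(0, 0.2), 0, 100),
                    "no_hs_diploma_pct": np.clip(pov_county["no_hs_diploma_pct"][i] + rng.normal(0, 0.3), 0, 100),
                    "otp_count": otp[i],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationTruth:
    """The generating state and design of one simulated panel."""

    state: ParameterState
    spec: ModelSpec
    design: object  # DesignMatrices; kept loose to avoid a circular import
    graph: AdjacencyGraph


def simulate_panel(
    config: TruthConfig,
    graph: AdjacencyGraph | None = None,
    return_truth: bool = False,
):
    """Simulate a full county-year panel from known parameters.

    Covariates are generated first, the covariate transformers are fitted
    on them (so design columns match what a refit would use), and counts
    are drawn as Poisson around the recursively propagated rates.  Pure
    function of (config, seed).
    """
    if graph is None:
        graph = make_lattice_graph(*config.grid_shape)
    if graph.n_nodes != config.n_counties:
        raise ValueError("graph size does not match config.n_counties")
    rng = np.random.default_rng(config.seed)
    frame = generate_covariates(config, rng)
    window = (config.start_year, config.years[-1])
    shell = CountyYearPanel(data=frame, window=window)
    spec = ModelSpec(include_interactions=config.include_interactions)
    design = build_design(shell, graph, include_interactions=config.include_interactions)

    alpha = rng.normal(config.alpha_loc, config.alpha_scale, config.n_counties)
    phi = sample_icar(graph, config.tau, rng, order=design.counties)
    state = ParameterState(
        alpha=alpha,
        beta0=config.beta0,
        beta=config.beta_vector(),
        delta=config.delta,
        gamma=config.gamma_vector(),
        phi=phi,
        tau=config.tau,
        components=graph.component_labels(order=design.counties),
    )
    log_lam = log_rate_matrix(state, design)
    mu = shell.population * np.exp(log_lam)
    if not np.all(np.isfinite(mu)) or mu.max() > 1e9:
        raise ValueError("simulated rates overflow; check the truth config")
    deaths = rng.poisson(mu)

    frame = frame.copy()
    order = {c: i for i, c in enumerate(design.counties)}
    year_pos = {y: j for j, y in enumerate(shell.years)}
    frame["deaths"] = [
        int(deaths[order[c], year_pos[y]]) for c, y in zip(frame["county_id"], frame["year"])
    ]
    panel = CountyYearPanel(data=frame, window=window)
    if not return_truth:
        return panel
    return panel, SimulationTruth(state=state, spec=spec, design=design, graph=graph)


@dataclass
class RecoveryReport:
    """Bias / RMSE / CI coverage of the fit pipeline over replicates."""

    table: pd.DataFrame  # index: term; columns: truth, bias, rmse, coverage
    n_replicates: int
    seeds: tuple[int, ...]
    failures: list = field(default_factory=list)

    def coverage(self, term: str) -> float:
        return float(self.table.loc[term, "coverage"])

    def bias(self, term: str) -> float:
        return float(self.table.loc[term, "bias"])


def recovery_experiment(
    config: TruthConfig,
    n_replicates: int,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    terms: Sequence[str] | None = None,
) -> RecoveryReport:
    """Simulate-and-refit replicates at the true model.

    For each replicate: simulate a panel, fit it, and record per-term
    point-estimate error and whether the equal-tailed 95% CI covers the
    truth.  Sampler failures are recorded in ``failures`` rather than
    silently dropped.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    mcmc = mcmc or McmcConfig(chains=2, warmup=500, draws=500)
    truths = TruthConfig.true_terms(config)
    if terms is None:
        terms = [t for t in ("intercept", "drug_court", "drug_court:high_targeting") if t in truths]
    seqs = np.random.SeedSequence(seed).generate_state(2 * n_replicates)

    records: dict[str, list] = {t: [] for t in terms}
    failures = []
    seeds_used = []
    graph = make_lattice_graph(*config.grid_shape)
    for r in range(n_replicates):
        sim_seed = int(seqs[2 * r])
        fit_seed = int(seqs[2 * r + 1])
        seeds_used.append(sim_seed)
        cfg = replace(config, seed=sim_seed)
        try:
            panel, truth = simulate_panel(cfg, graph, return_truth=True)
            samples = fit(panel, graph, truth.design, truth.spec, mcmc=mcmc, seed=fit_seed)
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            failures.append({"replicate": r, "seed": sim_seed, "error": repr(exc)})
            continue
        for term in terms:
            draws = samples.term_draws(term).reshape(-1)
            lo, hi = np.quantile(draws, [0.025, 0.975])
            est = float(np.median(draws))
            records[term].append(
                {"error": est - truths[term], "covered": lo <= truths[term] <= hi}
            )

    rows = []
    for term in terms:
        recs = records[term]
        errs = np.array([x["error"] for x in recs]) if recs else np.array([np.nan])
        cov = np.array([x["covered"] for x in recs]) if recs else np.array([np.nan])
        rows.append(
            {
                "term": term,
                "truth": truths[term],
                "bias": float(errs.mean()),
                "rmse": float(np.sqrt((errs**2).mean())),
                "coverage": float(cov.mean()),
                "n_ok": len(recs),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return RecoveryReport(
        table=table,
        n_replicates=n_replicates,
        seeds=tuple(seeds_used),
        failures=failures,
    )
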