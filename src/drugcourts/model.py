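"""Generative model: Poisson counts with an autoregressive log-rate
recursion, ICAR spatial growth effects, and weakly informative priors.

The per-person death rate evolves multiplicatively: the baseline year has
log-rate ``alpha_i`` per county, and every later year adds a transition
term ``beta0 + x'beta + D*delta + z*gamma + phi_i`` to the previous
year's log rate, so exponentiated coefficients are year-over-year rate
ratios.  Everything here is a pure log-density usable by any sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .covariates import MAIN_EFFECT_NAMES, DesignMatrices
from .panel import AdjacencyGraph, CountyYearPanel

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ParameterState",
    "icar_log_kernel",
    "log_rate",
    "log_rate_matrix",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the independent parameter priors.

    Coefficients (drift, covariates, exposure, interactions) get
    Normal(0, coef_scale^2); baseline log rates get
    Normal(baseline_loc, baseline_scale^2); the ICAR precision gets
    Gamma(tau_shape, rate=tau_rate).
    """

    coef_scale: float = 10.0
    baseline_loc: float = -9.0
    baseline_scale: float = 5.0
    tau_shape: float = 1.0
    tau_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("coef_scale", "baseline_scale", "tau_shape", "tau_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and with what priors.

    The main-effects variant uses only the covariates and the exposure;
    the interaction variant additionally multiplies every covariate by
    the exposure.
    """

    include_interactions: bool = False
    main_effect_names: tuple[str, ...] = MAIN_EFFECT_NAMES
    priors: PriorConfig = field(default_factory=PriorConfig)

    @property
    def interaction_names(self) -> tuple[str, ...]:
        if not self.include_interactions:
            return ()
        return tuple(f"drug_court:{n}" for n in self.main_effect_names)

    @property
    def n_main(self) -> int:
        return len(self.main_effect_names)

    @property
    def n_interactions(self) -> int:
        return len(self.interaction_names)

    def term_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.main_effect_names + ("drug_court",) + self.interaction_names

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": {
                "interactions": self.include_interactions,
                "main_effects": list(self.main_effect_names),
                "priors": {
                    "coef_scale": self.priors.coef_scale,
                    "baseline_loc": self.priors.baseline_loc,
                    "baseline_scale": self.priors.baseline_scale,
                    "tau_shape": self.priors.tau_shape,
                    "tau_rate": self.priors.tau_rate,
                },
            }
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSpec":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)["model"]
        return cls(
            include_interactions=bool(d.get("interactions", False)),
            main_effect_names=tuple(d.get("main_effects", MAIN_EFFECT_NAMES)),
            priors=PriorConfig(**d.get("priors", {})),
        )


@dataclass(frozen=True)
class ParameterState:
    """One realization of all model unknowns.

    The spatial effects ``phi`` are hard-centered to sum to zero within
    each connected component at construction, so the invariant cannot be
    violated through the public constructor.
    """

    alpha: np.ndarray
    beta0: float
    beta: np.ndarray
    delta: float
    gamma: np.ndarray
    phi: np.ndarray
    tau: float
    components: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        phi = np.asarray(self.phi, dtype=float).copy()
        if phi.shape != alpha.shape:
            raise ValueError("phi and alpha must have one entry per county")
        labels = (
            np.zeros(phi.shape[0], dtype=int)
            if self.components is None
            else np.asarray(self.components, dtype=int)
        )
        for k in np.unique(labels):
            mask = labels == k
            phi[mask] -= phi[mask].mean()
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "components", labels)

    @property
    def n_counties(self) -> int:
        return self.alpha.shape[0]

    def replace(self, **kwargs) -> "ParameterState":
        return replace(self, **kwargs)


def icar_log_kernel(phi, graph: AdjacencyGraph, tau: float, order=None) -> float:
    """Pairwise-difference ICAR kernel, up to an additive constant.

    Returns ``-(tau/2) * sum over edges (phi_i - phi_j)^2``, the improper
    Gaussian log-density whose precision is ``tau`` times the graph
    Laplacian.  ``order`` gives the node ordering of ``phi`` (defaults to
    the graph's sorted node order).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    phi = np.asarray(phi, dtype=float)
    order = list(order) if order is not None else list(graph.nodes)
    if phi.shape[0] != len(order):
        raise ValueError("phi must have one entry per graph node")
    idx = {n: i for i, n in enumerate(order)}
    total = 0.0
    for a, b in graph.edges:
        d = phi[idx[a]] - phi[idx[b]]
        total += d * d
    return -0.5 * tau * total


def log_rate_matrix(state: ParameterState, design: DesignMatrices) -> np.ndarray:
    """Log death rate per person, (n_counties, n_years) incl. baseline.

    Column 0 is the baseline year (``alpha``); later columns accumulate
    the transition terms.
    """
    eta = (
        state.beta0
        + design.main_effects @ state.beta
        + design.exposure * state.delta
        + state.phi[:, None]
    )
    if design.interactions is not None:
        if state.gamma.shape[0] != design.interactions.shape[2]:
            raise ValueError("gamma length does not match interaction columns")
        eta = eta + design.interactions @ state.gamma
    elif state.gamma.size:
        raise ValueError("state has interaction coefficients but design has none")
    log_lam = np.empty((state.n_counties, len(design.years) + 1))
    log_lam[:, 0] = state.alpha
    np.cumsum(eta, axis=1, out=eta)
    log_lam[:, 1:] = state.alpha[:, None] + eta
    return log_lam


def log_rate(state: ParameterState, design: DesignMatrices, county, year: int) -> float:
    """Log rate for one county-year, computed by explicit recursion.

    The baseline year returns ``alpha_i``; each transition year adds its
    drift, covariate, exposure, interaction and spatial terms to the
    previous year's log rate.
    """
    if county not in design.counties:
        raise KeyError(county)
    i = design.counties.index(county)
    if year == design.baseline_year:
        return float(state.alpha[i])
    if year not in design.years:
        raise ValueError(f"year {year} outside the modeled window")
    value = log_rate(state, design, county, year - 1)
    t = design.years.index(year)
    value += (
        state.beta0
        + float(design.main_effects[i, t] @ state.beta)
        + float(design.exposure[i, t]) * state.delta
        + float(state.phi[i])
    )
    if design.interactions is not None:
        value += float(design.interactions[i, t] @ state.gamma)
    return value


def log_likelihood(
    state: ParameterState, panel: CountyYearPanel, design: DesignMatrices
) -> float:
    """Poisson log likelihood summed over all county-years.

    The mean for cell (i, t) is population times the recursively defined
    rate ``exp(log_rate)``.
    """
    y = panel.deaths
    if np.isnan(y).any() or (y < 0).any() or (y % 1 != 0).any():
        raise ValueError("death counts must be non-negative integers")
    pop = panel.population
    mu = pop * np.exp(log_rate_matrix(state, design))
    return float(stats.poisson.logpmf(y.astype(int), mu).sum())


def log_prior(state: ParameterState, graph: AdjacencyGraph, spec: ModelSpec, order=None) -> float:
    """Independent prior log-densities for everything except the ICAR kernel.

    Includes the rank/2 * log(tau) normalization of the (improper) ICAR
    density, so that together with :func:`icar_log_kernel` the posterior
    is proper in ``tau``.
    """
    p = spec.priors
    total = float(stats.norm.logpdf(state.alpha, p.baseline_loc, p.baseline_scale).sum())
    coefs = np.concatenate(
        [[state.beta0], state.beta, [state.delta], state.gamma]
    )
    total += float(stats.norm.logpdf(coefs, 0.0, p.coef_scale).sum())
    total += float(stats.gamma.logpdf(state.tau, a=p.tau_shape, scale=1.0 / p.tau_rate))
    rank = graph.n_nodes - len(graph.components())
    total += 0.5 * rank * np.log(state.tau)
    return total


def log_posterior(
    state: ParameterState,
    panel: CountyYearPanel,
    design: DesignMatrices,
    graph: AdjacencyGraph,
    spec: ModelSpec,
) -> float:
    """Unnormalized posterior: likelihood + ICAR kernel + priors."""
    return (
        log_likelihood(state, panel, design)
        + icar_log_kernel(state.phi, graph, state.tau, order=design.counties)
        + log_prior(state, graph, spec, order=design.counties)
    )
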