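"""Posterior inference and summaries.

The model is linear in its parameters once the autoregressive recursion
is unrolled (every log rate is the baseline plus a cumulative sum of
transition terms), so the likelihood is a Poisson GLM with a dense design
built here once.  Sampling uses Hamiltonian Monte Carlo with analytic
gradients for the Gaussian/ICAR block and a conjugate Gibbs update for
the ICAR precision.  Diagnostics are rank-normalized split R-hat and bulk
ESS via arviz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .covariates import DesignMatrices
from .model import ModelSpec, ParameterState
from .panel import AdjacencyGraph, CountyYearPanel

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "SummaryRow",
    "fit",
    "diagnostics",
    "rate_ratio_table",
    "linear_combination",
    "summary_table",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. Defaults: 4 chains, 1000 warmup + 1000 kept."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_leapfrog: int = 24
    target_accept: float = 0.8
    init_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must be positive")


@dataclass
class SummaryRow:
    """One row of a rate-ratio summary table.

    ``estimate`` and the CI bounds are on the rate-ratio scale;
    ``percent_positive`` is the posterior probability that the rate ratio
    exceeds one (equivalently, the coefficient is positive).
    """

    term: str
    estimate: float
    ci_lower: float
    ci_upper: float
    percent_positive: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise ValueError("estimate must lie inside its credible interval")
        if not (0.0 <= self.percent_positive <= 1.0):
            raise ValueError("percent_positive must be in [0, 1]")

    @property
    def excludes_null(self) -> bool:
        """True when the 95% CI excludes a rate ratio of one."""
        return self.ci_upper < 1.0 or self.ci_lower > 1.0


class _LinearizedModel:
    """Dense linear parameterization of the unrolled model.

    Parameter vector: [alpha (n) | beta0 | beta (p) | delta | gamma (q) |
    u (rank)], with the spatial effects represented as ``phi = B @ u`` on
    an orthonormal per-component sum-to-zero basis, so the sum-to-zero
    constraint holds exactly for every draw.
    """

    def __init__(
        self,
        panel: CountyYearPanel,
        graph: AdjacencyGraph,
        design: DesignMatrices,
        spec: ModelSpec,
    ) -> None:
        if tuple(design.counties) != tuple(panel.counties):
            raise ValueError("design and panel county sets differ")
        if spec.include_interactions != design.has_interactions:
            raise ValueError("spec/design disagree about interaction columns")
        n = len(design.counties)
        t_trans = len(design.years)
        t_all = t_trans + 1
        p = design.main_effects.shape[2]
        q = p if design.has_interactions else 0

        labels = graph.component_labels(order=design.counties)
        blocks = []
        for k in np.unique(labels):
            m = int((labels == k).sum())
            blocks.append(linalg.null_space(np.ones((1, m))))
        rank = sum(b.shape[1] for b in blocks)
        basis = np.zeros((n, rank))
        col = 0
        for k, b in zip(np.unique(labels), blocks):
            mask = labels == k
            basis[mask, col : col + b.shape[1]] = b
            col += b.shape[1]

        lap = graph.laplacian(order=design.counties)
        self.icar_quad = basis.T @ lap @ basis  # (rank, rank)
        self.basis = basis
        self.components = labels
        self.rank = rank

        steps = np.arange(t_all, dtype=float)  # transitions accumulated by year t
        cum_x = np.zeros((n, t_all, p))
        cum_x[:, 1:, :] = np.cumsum(design.main_effects, axis=1)
        cum_d = np.zeros((n, t_all))
        cum_d[:, 1:] = np.cumsum(design.exposure, axis=1)

        ncell = n * t_all
        d = n + 1 + p + 1 + q + rank
        a = np.zeros((ncell, d))
        eye = np.repeat(np.eye(n), t_all, axis=0)
        a[:, :n] = eye
        a[:, n] = np.tile(steps, n)
        a[:, n + 1 : n + 1 + p] = cum_x.reshape(ncell, p)
        a[:, n + 1 + p] = cum_d.reshape(ncell)
        off = n + 2 + p
        if q:
            cum_z = np.zeros((n, t_all, q))
            cum_z[:, 1:, :] = np.cumsum(design.interactions, axis=1)
            a[:, off : off + q] = cum_z.reshape(ncell, q)
            off += q
        # phi_i contributes t per year, mapped through the basis
        a[:, off:] = (steps[None, :, None] * basis[:, None, :]).reshape(ncell, rank)

        self.matrix = a
        self.matrix_sq = a * a
        self.n, self.p, self.q, self.t_all = n, p, q, t_all
        self.slices = {
            "alpha": slice(0, n),
            "beta0": slice(n, n + 1),
            "beta": slice(n + 1, n + 1 + p),
            "delta": slice(n + 1 + p, n + 2 + p),
            "gamma": slice(n + 2 + p, n + 2 + p + q),
            "u": slice(n + 2 + p + q, d),
        }
        self.dim = d

        self.y = panel.deaths.reshape(ncell)
        self.log_pop = np.log(panel.population.reshape(ncell))

        pri = spec.priors
        prec = np.zeros(d)
        mean = np.zeros(d)
        prec[self.slices["alpha"]] = 1.0 / pri.baseline_scale**2
        mean[self.slices["alpha"]] = pri.baseline_loc
        for key in ("beta0", "beta", "delta", "gamma"):
            prec[self.slices[key]] = 1.0 / pri.coef_scale**2
        self.prior_prec = prec
        self.prior_mean = mean
        self.tau_shape = pri.tau_shape
        self.tau_rate = pri.tau_rate

    # -- target density ---------------------------------------------------

    def mu(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(self.log_pop + self.matrix @ theta)

    def potential_grad(self, theta: np.ndarray, tau: float):
        """Negative log density (up to constants) and its gradient."""
        eta = self.log_pop + self.matrix @ theta
        mu = np.exp(np.clip(eta, -700, 700))
        u = theta[self.slices["u"]]
        icar_u = tau * (self.icar_quad @ u)
        centered = theta - self.prior_mean
        pot = (
            -(self.y @ eta - mu.sum())
            + 0.5 * centered @ (self.prior_prec * centered)
            + 0.5 * (u @ icar_u)
        )
        grad = -(self.matrix.T @ (self.y - mu)) + self.prior_prec * centered
        grad[self.slices["u"]] += icar_u
        return pot, grad

    def hessian(self, theta: np.ndarray, tau: float) -> np.ndarray:
        """Full negative-log-density Hessian (exact for this GLM)."""
        mu = self.mu(theta)
        h = self.matrix.T @ (self.matrix * mu[:, None])
        h[np.diag_indices_from(h)] += self.prior_prec
        su = self.slices["u"]
        h[su, su] += tau * self.icar_quad
        return h

    def log_lik(self, theta: np.ndarray) -> float:
        eta = self.log_pop + self.matrix @ theta
        mu = np.exp(np.clip(eta, -700, 700))
        return float(self.y @ eta - mu.sum())

    def gibbs_tau(self, theta: np.ndarray, rng: np.random.Generator) -> float:
        u = theta[self.slices["u"]]
        shape = self.tau_shape + 0.5 * self.rank
        rate = self.tau_rate + 0.5 * (u @ (self.icar_quad @ u))
        return float(rng.gamma(shape, 1.0 / rate))

    def initial_theta(self) -> np.ndarray:
        theta = self.prior_mean.copy()
        y0 = self.y.reshape(self.n, self.t_all)[:, 0]
        pop0 = np.exp(self.log_pop.reshape(self.n, self.t_all)[:, 0])
        theta[self.slices["alpha"]] = np.log((y0 + 0.5) / pop0)
        return theta

    def to_state(self, theta: np.ndarray, tau: float) -> ParameterState:
        s = self.slices
        return ParameterState(
            alpha=theta[s["alpha"]],
            beta0=float(theta[s["beta0"]][0]),
            beta=theta[s["beta"]],
            delta=float(theta[s["delta"]][0]),
            gamma=theta[s["gamma"]],
            phi=self.basis @ theta[s["u"]],
            tau=tau,
            components=self.components,
        )


class _Metric:
    """Dense mass matrix M with momentum ~ N(0, M) and kinetic p'M^-1 p/2."""

    def __init__(self, hessian: np.ndarray) -> None:
        # small jitter keeps the factorization stable if the Hessian is
        # near-singular at an odd evaluation point
        jitter = 1e-10 * np.trace(hessian) / hessian.shape[0]
        self.chol = np.linalg.cholesky(
            hessian + jitter * np.eye(hessian.shape[0])
        )

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return self.chol @ rng.standard_normal(self.chol.shape[0])

    def velocity(self, mom: np.ndarray) -> np.ndarray:
        v = linalg.solve_triangular(self.chol, mom, lower=True)
        return linalg.solve_triangular(self.chol.T, v, lower=False)

    def kinetic(self, mom: np.ndarray) -> float:
        v = linalg.solve_triangular(self.chol, mom, lower=True)
        return 0.5 * float(v @ v)


def _find_epsilon(model: _LinearizedModel, theta, tau, metric: _Metric, rng) -> float:
    """Double/halve until the one-step acceptance crosses 0.5."""
    eps = 1.0
    pot, grad = model.potential_grad(theta, tau)
    mom = metric.sample_momentum(rng)
    h0 = pot + metric.kinetic(mom)

    def one_step(eps):
        m = mom - 0.5 * eps * grad
        th = theta + eps * metric.velocity(m)
        p1, g1 = model.potential_grad(th, tau)
        if not (np.isfinite(p1) and np.all(np.isfinite(g1))):
            return np.inf
        m = m - 0.5 * eps * g1
        return p1 + metric.kinetic(m)

    with np.errstate(over="ignore", invalid="ignore"):
        h1 = one_step(eps)
        delta = h0 - h1 if np.isfinite(h1) else -np.inf
        direction = 1 if delta > np.log(0.5) else -1
        for _ in range(50):
            eps *= 2.0**direction
            h1 = one_step(eps)
            delta = h0 - h1 if np.isfinite(h1) else -np.inf
            if (direction == 1 and delta <= np.log(0.5)) or (
                direction == -1 and delta >= np.log(0.5)
            ):
                break
    return min(eps, 2.0)


def _run_chain(model: _LinearizedModel, mcmc: McmcConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    tau = mcmc.init_tau

    # MAP initialization at the starting precision; the penalized Poisson
    # log-density is smooth and concave so L-BFGS is reliable here.
    theta = model.initial_theta()
    res = optimize.minimize(
        lambda th: model.potential_grad(th, tau),
        theta,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    theta = res.x
    metric = _Metric(model.hessian(theta, tau))

    eps = _find_epsilon(model, theta, tau, metric, rng)
    log_eps_bar, h_bar = 0.0, 0.0
    mu_da = np.log(10.0 * eps)
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    n_iter = mcmc.warmup + mcmc.draws
    thetas = np.empty((mcmc.draws, model.dim))
    taus = np.empty(mcmc.draws)
    accepts = np.empty(n_iter)
    divergences = 0

    pot, grad = model.potential_grad(theta, tau)
    su = model.slices["u"]
    for it in range(n_iter):
        tau = model.gibbs_tau(theta, rng)

        # interweaved precision move: hold the whitened effects w = sqrt(tau)*u
        # fixed and propose tau on the log scale, so tau can traverse its
        # posterior even though the HMC metric was built at a fixed tau
        if model.rank:
            log_tau_prop = np.log(tau) + 0.6 * rng.standard_normal()
            tau_prop = float(np.exp(log_tau_prop))
            theta_prop = theta.copy()
            theta_prop[su] = theta[su] * np.sqrt(tau / tau_prop)
            log_ratio = (
                model.log_lik(theta_prop)
                - model.log_lik(theta)
                + model.tau_shape * (log_tau_prop - np.log(tau))
                - model.tau_rate * (tau_prop - tau)
            )
            if np.log(rng.uniform()) < log_ratio:
                tau, theta = tau_prop, theta_prop

        pot, grad = model.potential_grad(theta, tau)

        mom = metric.sample_momentum(rng)
        h0 = pot + metric.kinetic(mom)
        n_steps = int(rng.integers(1, mcmc.max_leapfrog + 1))
        th, g = theta, grad
        with np.errstate(over="ignore", invalid="ignore"):
            m = mom - 0.5 * eps * g
            h1 = np.inf
            for step in range(n_steps):
                if not np.all(np.isfinite(m)):
                    break
                th = th + eps * metric.velocity(m)
                p_new, g = model.potential_grad(th, tau)
                if not np.isfinite(p_new):
                    break
                m = m - (0.5 if step == n_steps - 1 else 1.0) * eps * g
            else:
                h1 = p_new + metric.kinetic(m)
        log_accept = h0 - h1
        if not np.isfinite(log_accept):
            log_accept = -np.inf
            divergences += 1
        accept_prob = min(1.0, np.exp(log_accept))
        if np.log(rng.uniform()) < log_accept:
            theta = th
        accepts[it] = accept_prob

        if it < mcmc.warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (mcmc.target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(it + 1) / gamma_da * h_bar
            w = (it + 1) ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == mcmc.warmup // 2:
                # refresh the metric once the chain has settled
                metric = _Metric(model.hessian(theta, tau))
                eps = float(np.exp(log_eps_bar))
        elif it == mcmc.warmup:
            eps = float(np.exp(log_eps_bar))
        if it == mcmc.warmup - 1:
            eps = float(np.exp(log_eps_bar))
        if it >= mcmc.warmup:
            k = it - mcmc.warmup
            thetas[k] = theta
            taus[k] = tau
    return thetas, taus, accepts, divergences


@dataclass
class PosteriorSamples:
    """MCMC draws with chain/seed metadata.

    Arrays are shaped (chains, draws) with trailing parameter dimensions;
    ``phi`` is already mapped back from the sum-to-zero basis, so every
    draw satisfies the component-wise centering exactly.
    """

    alpha: np.ndarray
    beta0: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    tau: np.ndarray
    seed: int
    spec: ModelSpec
    counties: tuple
    accept_rate: float = float("nan")
    divergences: int = 0
    _diag_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def term_names(self) -> tuple[str, ...]:
        return self.spec.term_names()

    def term_draws(self, term: str) -> np.ndarray:
        """Coefficient draws for a named model term, shape (chains, draws)."""
        if term == "intercept":
            return self.beta0
        if term == "drug_court":
            return self.delta
        if term in self.spec.main_effect_names:
            return self.beta[..., self.spec.main_effect_names.index(term)]
        if term in self.spec.interaction_names:
            return self.gamma[..., self.spec.interaction_names.index(term)]
        raise KeyError(f"unknown model term {term!r}")

    def state_at(self, chain: int, draw: int) -> ParameterState:
        return ParameterState(
            alpha=self.alpha[chain, draw],
            beta0=float(self.beta0[chain, draw]),
            beta=self.beta[chain, draw],
            delta=float(self.delta[chain, draw]),
            gamma=self.gamma[chain, draw],
            phi=self.phi[chain, draw],
            tau=float(self.tau[chain, draw]),
        )

    def to_inference_data(self) -> az.InferenceData:
        data = {
            "alpha": self.alpha,
            "beta0": self.beta0,
            "beta": self.beta,
            "delta": self.delta,
            "phi": self.phi,
            "tau": self.tau,
        }
        if self.gamma.shape[-1]:
            data["gamma"] = self.gamma
        return az.from_dict(posterior=data)

    # -- text round-trip ---------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        c, d = self.n_chains, self.n_draws
        cols["chain"] = np.repeat(np.arange(c), d)
        cols["draw"] = np.tile(np.arange(d), c)
        for i, county in enumerate(self.counties):
            cols[f"alpha[{county}]"] = self.alpha[..., i].reshape(-1)
        cols["beta0"] = self.beta0.reshape(-1)
        for i, name in enumerate(self.spec.main_effect_names):
            cols[f"beta[{name}]"] = self.beta[..., i].reshape(-1)
        cols["delta"] = self.delta.reshape(-1)
        for i, name in enumerate(self.spec.interaction_names):
            cols[f"gamma[{name}]"] = self.gamma[..., i].reshape(-1)
        for i, county in enumerate(self.counties):
            cols[f"phi[{county}]"] = self.phi[..., i].reshape(-1)
        cols["tau"] = self.tau.reshape(-1)
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: ModelSpec, counties: Sequence, seed: int = -1
    ) -> "PosteriorSamples":
        c = int(df["chain"].max()) + 1
        d = int(df["draw"].max()) + 1
        counties = tuple(counties)

        def grab(names):
            return np.stack(
                [df[n].to_numpy().reshape(c, d) for n in names], axis=-1
            ) if names else np.zeros((c, d, 0))

        return cls(
            alpha=grab([f"alpha[{x}]" for x in counties]),
            beta0=df["beta0"].to_numpy().reshape(c, d),
            beta=grab([f"beta[{n}]" for n in spec.main_effect_names]),
            delta=df["delta"].to_numpy().reshape(c, d),
            gamma=grab([f"gamma[{n}]" for n in spec.interaction_names]),
            phi=grab([f"phi[{x}]" for x in counties]),
            tau=df["tau"].to_numpy().reshape(c, d),
            seed=seed,
            spec=spec,
            counties=counties,
        )

    @classmethod
    def load_csv(cls, path, spec: ModelSpec, counties: Sequence) -> "PosteriorSamples":
        return cls.from_dataframe(pd.read_csv(path), spec, counties)


def fit(
    panel: CountyYearPanel,
    graph: AdjacencyGraph,
    design: DesignMatrices,
    spec: ModelSpec,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Sample the posterior by HMC with a Gibbs step for the ICAR precision.

    Deterministic for a fixed (seed, config, data) triple: chains run
    sequentially from seeds spawned off ``seed``.  A chain whose mean
    acceptance rate collapses is reported through ``accept_rate`` and
    ``divergences`` on the returned samples rather than silently dropped.
    """
    mcmc = mcmc or McmcConfig()
    model = _LinearizedModel(panel, graph, design, spec)
    seqs = np.random.SeedSequence(seed).spawn(mcmc.chains)

    c, d = mcmc.chains, mcmc.draws
    thetas = np.empty((c, d, model.dim))
    taus = np.empty((c, d))
    accept = np.empty(c)
    divergences = 0
    for k in range(c):
        th, ta, acc, div = _run_chain(model, mcmc, seqs[k])
        thetas[k], taus[k] = th, ta
        accept[k] = acc[mcmc.warmup :].mean()
        divergences += div

    s = model.slices
    samples = PosteriorSamples(
        alpha=thetas[..., s["alpha"]],
        beta0=thetas[..., s["beta0"]][..., 0],
        beta=thetas[..., s["beta"]],
        delta=thetas[..., s["delta"]][..., 0],
        gamma=thetas[..., s["gamma"]],
        phi=thetas[..., s["u"]] @ model.basis.T,
        tau=taus,
        seed=seed,
        spec=spec,
        counties=tuple(design.counties),
        accept_rate=float(accept.mean()),
        divergences=divergences,
    )
    if samples.accept_rate < 0.5:
        import warnings

        warnings.warn(
            f"mean HMC acceptance rate {samples.accept_rate:.2f} is low; "
            f"{divergences} divergent transitions — inspect diagnostics",
            stacklevel=2,
        )
    return samples


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per scalar parameter.

    Requires at least 2 chains.  Constant (degenerate) chains yield NaN
    diagnostics and a ``degenerate`` flag instead of an error.
    """
    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if "table" in samples._diag_cache:
        return samples._diag_cache["table"]

    scalars: dict[str, np.ndarray] = {"beta0": samples.beta0, "delta": samples.delta, "tau": samples.tau}
    for i, name in enumerate(samples.spec.main_effect_names):
        scalars[f"beta[{name}]"] = samples.beta[..., i]
    for i, name in enumerate(samples.spec.interaction_names):
        scalars[f"gamma[{name}]"] = samples.gamma[..., i]
    for i, county in enumerate(samples.counties):
        scalars[f"alpha[{county}]"] = samples.alpha[..., i]
        scalars[f"phi[{county}]"] = samples.phi[..., i]

    rows = []
    for name, arr in scalars.items():
        degenerate = bool(np.allclose(arr, arr.reshape(-1)[0]))
        if degenerate:
            rhat, ess = float("nan"), float("nan")
        else:
            rhat = float(az.rhat(az.convert_to_dataset({"x": arr}))["x"].values)
            ess = float(az.ess(az.convert_to_dataset({"x": arr}))["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess, "degenerate": degenerate})
    table = pd.DataFrame(rows).set_index("parameter")
    samples._diag_cache["table"] = table
    return table


def _summarize_coef_draws(term: str, draws: np.ndarray, point: str) -> SummaryRow:
    # order-statistic (type-1) quantiles commute exactly with monotone
    # maps, so summarizing on the coefficient scale and exponentiating
    # equals summarizing the exponentiated draws
    flat = draws.reshape(-1)
    if point == "median":
        center = np.quantile(flat, 0.5, method="inverted_cdf")
    else:
        center = flat.mean()
    lo, hi = np.quantile(flat, [0.025, 0.975], method="inverted_cdf")
    return SummaryRow(
        term=term,
        estimate=float(np.exp(center)),
        ci_lower=float(np.exp(lo)),
        ci_upper=float(np.exp(hi)),
        percent_positive=float((flat > 0).mean()),
    )


def rate_ratio_table(
    samples: PosteriorSamples, terms: Sequence[str], point: str = "median"
) -> list[SummaryRow]:
    """Rate-ratio summary rows for the named terms.

    Per term: estimate = exp(posterior median of the coefficient) (or
    mean if ``point='mean'`` — note the mean is not transform-equivariant),
    equal-tailed 95% CI as exp of coefficient quantiles, and the fraction
    of draws with a positive coefficient.
    """
    return [_summarize_coef_draws(t, samples.term_draws(t), point) for t in terms]


def linear_combination(
    samples: PosteriorSamples, weights: Mapping[str, float], point: str = "median"
) -> SummaryRow:
    """Posterior summary of a weighted sum of coefficients.

    Forms sum_k w_k * coef_k per draw and summarizes on the rate-ratio
    scale exactly as :func:`rate_ratio_table` does for single terms.
    """
    combo = np.zeros_like(samples.beta0)
    for term, w in weights.items():
        combo = combo + w * samples.term_draws(term)
    label = " + ".join(f"{w:g}*{t}" for t, w in weights.items()) or "0"
    return _summarize_coef_draws(label, combo, point)


def summary_table(samples: PosteriorSamples, terms: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabular form of :func:`rate_ratio_table` (CSV-friendly)."""
    if terms is None:
        terms = ("drug_court",) + samples.spec.interaction_names
    rows = rate_ratio_table(samples, terms)
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "estimate": [r.estimate for r in rows],
            "ci_lower": [r.ci_lower for r in rows],
            "ci_upper": [r.ci_upper for r in rows],
            "percent_positive": [r.percent_positive for r in rows],
        }
    )
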