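"""Counterfactual scenarios and posterior-predictive aggregation.

A scenario rewrites the exposure (and, where allowed, the targeting
indicators) in the design matrices, the autoregressive recursion is
re-propagated from each county's baseline under every posterior draw,
and changes in death counts/rates versus the observed panel are
aggregated to county and statewide summaries with credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .covariates import DesignMatrices
from .inference import PosteriorSamples
from .panel import CountyYearPanel

__all__ = [
    "Scenario",
    "PosteriorCounts",
    "CounterfactualSummary",
    "no_courts",
    "universal_courts",
    "universal_courts_no_high_targeting",
    "identity_scenario",
    "apply_scenario",
    "posterior_mean_counts",
    "summarize_changes",
]

#: covariates a scenario is allowed to override (plus the exposure)
OVERRIDABLE = frozenset({"low_targeting", "high_targeting"})

CF_MINUS_OBSERVED = "counterfactual_minus_observed"
OBSERVED_MINUS_CF = "observed_minus_counterfactual"

ExposureRule = Callable[[object, int], float]
CovariateRule = Callable[[object, int, str], "float | None"]


@dataclass(frozen=True)
class Scenario:
    """A named rewrite of exposure and targeting covariates.

    ``exposure_override`` is a constant or a ``(county, year) -> value``
    rule; ``None`` leaves the observed exposure in place.
    ``covariate_override`` maps ``(county, year, name) -> value or None``
    and may only touch the targeting indicators.  ``sign_convention``
    orients reported changes so positive values mean a protective effect
    of drug courts.  ``reporting_mask`` limits which counties appear in
    county-level output; statewide aggregates always use all counties.
    """

    name: str
    exposure_override: float | ExposureRule | None = None
    covariate_override: Mapping[str, float] | CovariateRule | None = None
    sign_convention: str = CF_MINUS_OBSERVED
    reporting_mask: frozenset | None = None

    def __post_init__(self) -> None:
        if self.sign_convention not in (CF_MINUS_OBSERVED, OBSERVED_MINUS_CF):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        if isinstance(self.covariate_override, Mapping):
            bad = set(self.covariate_override) - OVERRIDABLE
            if bad:
                raise ValueError(
                    f"covariate override not permitted for: {sorted(bad)}"
                )

    @property
    def sign(self) -> float:
        return 1.0 if self.sign_convention == CF_MINUS_OBSERVED else -1.0


def no_courts() -> Scenario:
    """Every drug-court indicator set to zero for the whole window."""
    return Scenario(
        name="no_courts", exposure_override=0.0, sign_convention=CF_MINUS_OBSERVED
    )


def universal_courts() -> Scenario:
    """Every county has a drug court for the whole window."""
    return Scenario(
        name="universal_courts", exposure_override=1.0, sign_convention=OBSERVED_MINUS_CF
    )


def universal_courts_no_high_targeting() -> Scenario:
    """Universal courts plus all high-targeting indicators removed.

    High-targeting county-years are reassigned to the reference (middle)
    tertile; low-targeting indicators are untouched.
    """
    return Scenario(
        name="universal_courts_no_high_targeting",
        exposure_override=1.0,
        covariate_override={"high_targeting": 0.0},
        sign_convention=OBSERVED_MINUS_CF,
    )


def identity_scenario() -> Scenario:
    """No overrides: the observed design passes through unchanged."""
    return Scenario(name="observed", sign_convention=CF_MINUS_OBSERVED)


def apply_scenario(design: DesignMatrices, scenario: Scenario) -> DesignMatrices:
    """Rewrite a design under a scenario.

    Exposure and permitted covariate columns are replaced; interaction
    columns are rebuilt as exact elementwise products; everything else is
    passed through unchanged.
    """
    exposure = design.exposure.copy()
    if scenario.exposure_override is not None:
        if callable(scenario.exposure_override):
            for i, county in enumerate(design.counties):
                for t, year in enumerate(design.years):
                    exposure[i, t] = scenario.exposure_override(county, year)
        else:
            exposure[:] = float(scenario.exposure_override)

    x = design.main_effects.copy()
    override = scenario.covariate_override
    if override is not None:
        if isinstance(override, Mapping):
            for name, value in override.items():
                x[..., design.main_effect_names.index(name)] = float(value)
        else:
            for k, name in enumerate(design.main_effect_names):
                for i, county in enumerate(design.counties):
                    for t, year in enumerate(design.years):
                        value = override(county, year, name)
                        if value is None:
                            continue
                        if name not in OVERRIDABLE:
                            raise ValueError(
                                f"covariate override not permitted for: {name}"
                            )
                        x[i, t, k] = float(value)

    interactions = x * exposure[..., None] if design.has_interactions else None
    return replace(design, main_effects=x, exposure=exposure, interactions=interactions)


@dataclass(frozen=True)
class PosteriorCounts:
    """Expected death counts per draw and their posterior mean.

    ``per_draw`` has shape (n_draws_total, n_counties, n_years) with the
    baseline year included as the first column.
    """

    per_draw: np.ndarray
    counties: tuple
    years: tuple[int, ...]

    @property
    def mean(self) -> np.ndarray:
        return self.per_draw.mean(axis=0)


def posterior_mean_counts(
    samples: PosteriorSamples, panel: CountyYearPanel, design: DesignMatrices
) -> PosteriorCounts:
    """Posterior-predictive expected counts under a (possibly modified) design.

    For each draw the log-rate recursion is propagated from the county
    baselines through the design's transition terms and scaled by
    population.  The posterior-predictive mean of a Poisson count equals
    the posterior mean of its mean, so no count sampling is needed; the
    per-draw values are retained for interval computation.
    """
    if tuple(design.counties) != tuple(panel.counties):
        raise ValueError("design and panel county sets differ")
    c, d = samples.n_chains, samples.n_draws
    s = c * d
    alpha = samples.alpha.reshape(s, -1)
    beta0 = samples.beta0.reshape(s)
    beta = samples.beta.reshape(s, -1)
    delta = samples.delta.reshape(s)
    phi = samples.phi.reshape(s, -1)

    # (s, n, t_trans) transition terms
    eta = (
        beta0[:, None, None]
        + np.einsum("ntp,sp->snt", design.main_effects, beta)
        + design.exposure[None, :, :] * delta[:, None, None]
        + phi[:, :, None]
    )
    if design.has_interactions:
        gamma = samples.gamma.reshape(s, -1)
        eta += np.einsum("ntp,sp->snt", design.interactions, gamma)
    elif samples.gamma.shape[-1]:
        raise ValueError("samples carry interaction coefficients but design has none")

    log_lam = np.concatenate(
        [alpha[:, :, None], alpha[:, :, None] + np.cumsum(eta, axis=2)], axis=2
    )
    pop = panel.population
    counts = pop[None, :, :] * np.exp(log_lam)
    years = (design.baseline_year,) + tuple(design.years)
    return PosteriorCounts(per_draw=counts, counties=tuple(design.counties), years=years)


@dataclass
class CounterfactualSummary:
    """County and statewide changes in deaths under a scenario.

    Count changes sum over transition years; rate changes average the
    yearly per-person changes and are reported per 10,000.  Statewide
    totals sum (counts) or average (rates) over all counties, and the
    credible intervals are equal-tailed 95% intervals of the per-draw
    statewide quantities.
    """

    scenario: str
    sign_convention: str
    per_county_count_change: dict
    per_county_rate_change: dict
    per_county_count_ci: dict
    per_county_rate_ci: dict
    statewide_count_change: float
    statewide_count_ci: tuple[float, float]
    statewide_rate_change: float
    statewide_rate_ci: tuple[float, float]
    reported_counties: tuple = field(default_factory=tuple)

    def county_table(self) -> pd.DataFrame:
        rows = []
        for county in self.reported_counties:
            rows.append(
                {
                    "county_id": county,
                    "count_change": self.per_county_count_change[county],
                    "count_ci_lower": self.per_county_count_ci[county][0],
                    "count_ci_upper": self.per_county_count_ci[county][1],
                    "rate_change_per_10k": self.per_county_rate_change[county],
                    "rate_ci_lower": self.per_county_rate_ci[county][0],
                    "rate_ci_upper": self.per_county_rate_ci[county][1],
                }
            )
        return pd.DataFrame(rows)

    def statewide_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario,
                    "count_change": self.statewide_count_change,
                    "count_ci_lower": self.statewide_count_ci[0],
                    "count_ci_upper": self.statewide_count_ci[1],
                    "rate_change_per_10k": self.statewide_rate_change,
                    "rate_ci_lower": self.statewide_rate_ci[0],
                    "rate_ci_upper": self.statewide_rate_ci[1],
                }
            ]
        )


def summarize_changes(
    cf_counts: PosteriorCounts,
    panel: CountyYearPanel,
    scenario: Scenario,
    rate_scale: float = 1e4,
    baseline: PosteriorCounts | None = None,
) -> CounterfactualSummary:
    """Aggregate per-draw counterfactual-vs-observed differences.

    Per draw and county: count change = signed sum over transition years
    of (counterfactual - observed); rate change = signed mean over years
    of the per-person difference, scaled by ``rate_scale``.  Point
    estimates are posterior means, intervals equal-tailed 95%.

    By default the comparison uses the panel's observed death counts.
    Passing ``baseline`` (typically the posterior counts under the
    unmodified design) compares draw-by-draw against the model's own
    observed-design predictions instead, which makes a no-op scenario
    yield exact zeros.
    """
    counties = list(cf_counts.counties)
    if counties != list(panel.counties):
        raise ValueError("county sets differ between counts and panel")
    trans = [y for y in cf_counts.years if y > panel.baseline_year]
    year_idx = [cf_counts.years.index(y) for y in trans]
    col_idx = [panel.years.index(y) for y in trans]

    pop = panel.population[:, col_idx]
    if np.isnan(pop).any():
        raise ValueError("population missing for a transition year")
    cf = cf_counts.per_draw[:, :, year_idx]
    if baseline is None:
        observed = panel.deaths[:, col_idx][None, :, :]
    else:
        if baseline.per_draw.shape != cf_counts.per_draw.shape:
            raise ValueError("baseline counts shape mismatch")
        observed = baseline.per_draw[:, :, year_idx]

    diff = scenario.sign * (cf - observed)  # (s, n, t)
    count_change = diff.sum(axis=2)  # (s, n)
    rate_change = (diff / pop[None, :, :]).mean(axis=2) * rate_scale

    state_count = count_change.sum(axis=1)  # (s,)
    state_rate = rate_change.mean(axis=1)

    def ci(arr, axis=0):
        lo, hi = np.quantile(arr, [0.025, 0.975], axis=axis)
        return lo, hi

    cc_lo, cc_hi = ci(count_change)
    rc_lo, rc_hi = ci(rate_change)
    sc_lo, sc_hi = ci(state_count)
    sr_lo, sr_hi = ci(state_rate)

    mask = scenario.reporting_mask
    reported = tuple(c for c in counties if mask is None or c in mask)
    return CounterfactualSummary(
        scenario=scenario.name,
        sign_convention=scenario.sign_convention,
        per_county_count_change={
            c: float(count_change[:, i].mean()) for i, c in enumerate(counties)
        },
        per_county_rate_change={
            c: float(rate_change[:, i].mean()) for i, c in enumerate(counties)
        },
        per_county_count_ci={
            c: (float(cc_lo[i]), float(cc_hi[i])) for i, c in enumerate(counties)
        },
        per_county_rate_ci={
            c: (float(rc_lo[i]), float(rc_hi[i])) for i, c in enumerate(counties)
        },
        statewide_count_change=float(state_count.mean()),
        statewide_count_ci=(float(sc_lo), float(sc_hi)),
        statewide_rate_change=float(state_rate.mean()),
        statewide_rate_ci=(float(sr_lo), float(sr_hi)),
        reported_counties=reported,
    )
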