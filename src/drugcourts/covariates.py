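"""Derived covariate construction.

Builds the enforcement "targeting index" with tertile bins, composite
deprivation indices via the first principal component of standardized
variables, and the standardized design matrices for the main-effects and
interaction model variants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import AdjacencyGraph, CountyYearPanel, PanelError

__all__ = [
    "MAIN_EFFECT_NAMES",
    "POVERTY_INDEX_VARIABLES",
    "HEALTHCARE_INDEX_VARIABLES",
    "TertileBins",
    "IndexModel",
    "DesignMatrices",
    "CovariateTransforms",
    "targeting_index",
    "fit_tertiles",
    "fit_principal_index",
    "score_index",
    "fit_transforms",
    "build_design",
]

#: model covariates in the order used throughout (middle tertile is the
#: reference category for the targeting bins)
MAIN_EFFECT_NAMES = (
    "low_targeting",
    "high_targeting",
    "crime_rate",
    "hidta",
    "democrat_da",
    "urban",
    "poverty_index",
    "healthcare_index",
)

CONTINUOUS_EFFECTS = ("crime_rate", "poverty_index", "healthcare_index")

POVERTY_INDEX_VARIABLES = (
    "poverty_pct",
    "unemployed_pct",
    "disabled_pct",
    "food_stamps_pct",
    "no_hs_diploma_pct",
)

HEALTHCARE_INDEX_VARIABLES = ("uninsured_pct", "mua", "otp_count")


def targeting_index(possession, persons, property):  # noqa: A002 - domain name
    """Share of enforcement directed at drug possession.

    Ratio of drug-possession arrests (marijuana excluded upstream) to the
    total arrests for crimes against persons or property.  A zero
    denominator yields NaN with a warning; vectorized over array inputs.
    """
    possession = np.asarray(possession, dtype=float)
    persons = np.asarray(persons, dtype=float)
    property = np.asarray(property, dtype=float)
    if (possession < 0).any() or (persons < 0).any() or (property < 0).any():
        raise ValueError("arrest counts must be non-negative")
    denom = persons + property
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} county-year(s) with zero person+property arrests; "
            "targeting index set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, possession / np.where(zero, 1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class TertileBins:
    """Cutpoints splitting the targeting-index scale into three bins.

    Classification follows strict inequalities: values strictly below
    ``lower`` are "low", strictly above ``upper`` are "high", everything
    else (boundaries included) is "middle".
    """

    lower: float
    upper: float
    labels: tuple[str, str, str] = ("low", "middle", "high")

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("lower cutoff must not exceed upper cutoff")

    def classify(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, self.labels[1], dtype=object)
        out[v < self.lower] = self.labels[0]
        out[v > self.upper] = self.labels[2]
        out[np.isnan(v)] = None
        return out

    def indicators(self, values) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) 0/1 indicator arrays; middle is the reference."""
        labels = self.classify(values)
        return (
            (labels == self.labels[0]).astype(float),
            (labels == self.labels[2]).astype(float),
        )


def fit_tertiles(values, method: str = "inverted_cdf") -> TertileBins:
    """Fit tertile cutoffs from pooled county-year index values.

    Cutoffs are the 1/3 and 2/3 empirical quantiles of the non-missing
    values under numpy quantile ``method`` (default the empirical-CDF
    rule, ``"inverted_cdf"``).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("need at least 3 non-missing values to fit tertiles")
    lower, upper = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method=method)
    return TertileBins(lower=float(lower), upper=float(upper))


@dataclass(frozen=True)
class IndexModel:
    """First-principal-component index over standardized variables.

    ``weights`` is the unit-norm leading eigenvector of the pooled
    correlation matrix, oriented so that ``orientation_anchor`` has a
    strictly positive loading (so higher scores mean worse conditions).
    """

    variable_names: tuple[str, ...]
    weights: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    orientation_anchor: str
    explained_variance_ratio: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
            raise ValueError("index weights must have unit norm")
        anchor = self.variable_names.index(self.orientation_anchor)
        if w[anchor] <= 0:
            raise ValueError("orientation anchor loading must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))


def _pooled_covariate_frame(panel: CountyYearPanel, variable_names: Sequence[str]) -> pd.DataFrame:
    """Covariate rows for all transition years, indexed by (county, year)."""
    df = panel.data[panel.data["year"] >= panel.baseline_year + 1]
    missing = [v for v in variable_names if v not in df.columns]
    if missing:
        raise PanelError(f"missing variable(s): {', '.join(missing)}")
    return df.set_index(["county_id", "year"])[list(variable_names)]


def fit_principal_index(
    panel: CountyYearPanel,
    variable_names: Sequence[str],
    orientation_anchor: str,
) -> IndexModel:
    """Fit a composite index as the oriented leading principal component.

    Variables are pooled over all transition-year county-years and
    standardized before the eigendecomposition, so the component is that
    of the correlation matrix.
    """
    variable_names = tuple(variable_names)
    if len(variable_names) < 2:
        raise ValueError("need at least 2 variables for a principal index")
    if orientation_anchor not in variable_names:
        raise ValueError(f"anchor {orientation_anchor!r} not among variables")
    x = _pooled_covariate_frame(panel, variable_names).to_numpy(dtype=float)
    centers = x.mean(axis=0)
    scales = x.std(axis=0)
    for name, s in zip(variable_names, scales):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"variable {name} has zero variance; cannot standardize")
    z = (x - centers) / scales
    corr = (z.T @ z) / z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    w = eigvecs[:, -1]
    anchor = variable_names.index(orientation_anchor)
    if w[anchor] < 0:
        w = -w
    return IndexModel(
        variable_names=variable_names,
        weights=w,
        centers=centers,
        scales=scales,
        orientation_anchor=orientation_anchor,
        explained_variance_ratio=float(eigvals[-1] / eigvals.sum()),
    )


def score_index(model: IndexModel, panel: CountyYearPanel) -> pd.Series:
    """Project county-years onto a fitted index.

    Uses the stored centers/scales, so scoring a new panel applies the
    training-time standardization exactly.  Returns a Series indexed by
    (county_id, year) over transition years.
    """
    frame = _pooled_covariate_frame(panel, model.variable_names)
    z = (frame.to_numpy(dtype=float) - model.centers) / model.scales
    return pd.Series(z @ model.weights, index=frame.index, name="score")


@dataclass(frozen=True)
class Standardizer:
    center: float
    scale: float

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale


@dataclass(frozen=True)
class CovariateTransforms:
    """Fitted transformers frozen at training time.

    Bundles the tertile bins, the two principal-component indices, and
    the standardization constants for the continuous design columns, so
    that counterfactual and scoring runs reuse the exact training-time
    transforms.  Serializes to a JSON sidecar.
    """

    tertiles: TertileBins
    poverty_index: IndexModel
    healthcare_index: IndexModel
    standardizers: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def index_payload(m: IndexModel) -> dict:
            return {
                "variable_names": list(m.variable_names),
                "weights": m.weights.tolist(),
                "centers": m.centers.tolist(),
                "scales": m.scales.tolist(),
                "orientation_anchor": m.orientation_anchor,
                "explained_variance_ratio": m.explained_variance_ratio,
            }

        payload = {
            "tertiles": {"lower": self.tertiles.lower, "upper": self.tertiles.upper},
            "poverty_index": index_payload(self.poverty_index),
            "healthcare_index": index_payload(self.healthcare_index),
            "standardizers": {
                k: {"center": s.center, "scale": s.scale}
                for k, s in self.standardizers.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CovariateTransforms":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)

        def index_model(d: dict) -> IndexModel:
            return IndexModel(
                variable_names=tuple(d["variable_names"]),
                weights=np.array(d["weights"]),
                centers=np.array(d["centers"]),
                scales=np.array(d["scales"]),
                orientation_anchor=d["orientation_anchor"],
                explained_variance_ratio=d.get("explained_variance_ratio", float("nan")),
            )

        return cls(
            tertiles=TertileBins(**payload["tertiles"]),
            poverty_index=index_model(payload["poverty_index"]),
            healthcare_index=index_model(payload["healthcare_index"]),
            standardizers={
                k: Standardizer(**v) for k, v in payload["standardizers"].items()
            },
        )


def fit_transforms(panel: CountyYearPanel, quantile_method: str = "inverted_cdf") -> CovariateTransforms:
    """Fit all covariate transformers on a panel's transition years."""
    arrests = _pooled_covariate_frame(
        panel, ["possession_arrests", "persons_arrests", "property_arrests"]
    )
    ti = targeting_index(
        arrests["possession_arrests"],
        arrests["persons_arrests"],
        arrests["property_arrests"],
    )
    tertiles = fit_tertiles(ti, method=quantile_method)
    poverty = fit_principal_index(panel, POVERTY_INDEX_VARIABLES, "poverty_pct")
    healthcare = fit_principal_index(panel, HEALTHCARE_INDEX_VARIABLES, "uninsured_pct")

    crime = _pooled_covariate_frame(panel, ["crime_rate"])["crime_rate"].to_numpy(float)
    pov_scores = score_index(poverty, panel).to_numpy()
    hc_scores = score_index(healthcare, panel).to_numpy()
    standardizers = {}
    for name, vals in (
        ("crime_rate", crime),
        ("poverty_index", pov_scores),
        ("healthcare_index", hc_scores),
    ):
        scale = vals.std()
        if scale == 0:
            raise ValueError(f"cannot standardize constant column {name}")
        standardizers[name] = Standardizer(center=float(vals.mean()), scale=float(scale))
    return CovariateTransforms(
        tertiles=tertiles,
        poverty_index=poverty,
        healthcare_index=healthcare,
        standardizers=standardizers,
    )


@dataclass(frozen=True)
class DesignMatrices:
    """Model inputs for the transition years.

    ``main_effects`` has shape (n_counties, n_transitions, p) with rows in
    ``counties`` order and columns in ``main_effect_names`` order;
    ``exposure`` is the 0/1 drug-court matrix; ``interactions`` (present
    only for the interaction model) is exactly
    ``main_effects * exposure[..., None]``.
    """

    counties: tuple
    years: tuple[int, ...]
    baseline_year: int
    main_effect_names: tuple[str, ...]
    main_effects: np.ndarray
    exposure: np.ndarray
    interactions: np.ndarray | None
    transforms: CovariateTransforms

    def __post_init__(self) -> None:
        n, t, p = self.main_effects.shape
        if self.exposure.shape != (n, t):
            raise ValueError("exposure shape mismatch")
        if self.interactions is not None and self.interactions.shape != (n, t, p):
            raise ValueError("interaction shape mismatch")
        if len(self.years) != t or len(self.counties) != n:
            raise ValueError("index shape mismatch")

    @property
    def has_interactions(self) -> bool:
        return self.interactions is not None

    @property
    def interaction_names(self) -> tuple[str, ...]:
        if not self.has_interactions:
            return ()
        return tuple(f"drug_court:{name}" for name in self.main_effect_names)

    def replace(self, **kwargs) -> "DesignMatrices":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def build_design(
    panel: CountyYearPanel,
    graph: AdjacencyGraph | None,
    include_interactions: bool,
    transforms: CovariateTransforms | None = None,
) -> DesignMatrices:
    """Assemble design matrices for the transition years.

    One row per (county, transition year).  Fits the covariate
    transformers on the panel when ``transforms`` is not supplied.
    Deterministic: repeated calls with identical inputs are
    bitwise-identical.
    """
    if transforms is None:
        transforms = fit_transforms(panel)
    counties = panel.counties
    years = panel.transition_years
    n, t = len(counties), len(years)

    df = panel.data[panel.data["year"] >= panel.baseline_year + 1]
    df = df.set_index(["county_id", "year"]).sort_index()
    grid = pd.MultiIndex.from_product([counties, years], names=["county_id", "year"])
    df = df.reindex(grid)
    raw_needed = [
        "possession_arrests", "persons_arrests", "property_arrests",
        "crime_rate", "hidta", "democrat_da", "urban", "drug_court",
    ]
    na = df[raw_needed].isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        cell = df.index[na[col]][0]
        raise PanelError(f"covariate {col} missing at {tuple(cell)}")

    ti = targeting_index(
        df["possession_arrests"].to_numpy(float),
        df["persons_arrests"].to_numpy(float),
        df["property_arrests"].to_numpy(float),
    )
    if np.isnan(ti).any():
        bad = grid[np.isnan(ti)][0]
        raise PanelError(
            f"targeting index undefined (zero denominator) at {tuple(bad)}"
        )
    low, high = transforms.tertiles.indicators(ti)

    pov = score_index(transforms.poverty_index, panel).reindex(grid).to_numpy()
    hc = score_index(transforms.healthcare_index, panel).reindex(grid).to_numpy()
    if np.isnan(pov).any() or np.isnan(hc).any():
        raise PanelError("index score missing for a transition year")

    columns = {
        "low_targeting": low,
        "high_targeting": high,
        "crime_rate": transforms.standardizers["crime_rate"](df["crime_rate"].to_numpy(float)),
        "hidta": df["hidta"].to_numpy(float),
        "democrat_da": df["democrat_da"].to_numpy(float),
        "urban": df["urban"].to_numpy(float),
        "poverty_index": transforms.standardizers["poverty_index"](pov),
        "healthcare_index": transforms.standardizers["healthcare_index"](hc),
    }
    x = np.stack([columns[name] for name in MAIN_EFFECT_NAMES], axis=-1)
    x = x.reshape(n, t, len(MAIN_EFFECT_NAMES))
    exposure = df["drug_court"].to_numpy(float).reshape(n, t)
    interactions = x * exposure[..., None] if include_interactions else None
    return DesignMatrices(
        counties=tuple(counties),
        years=tuple(years),
        baseline_year=panel.baseline_year,
        main_effect_names=MAIN_EFFECT_NAMES,
        main_effects=x,
        exposure=exposure,
        interactions=interactions,
        transforms=transforms,
    )
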