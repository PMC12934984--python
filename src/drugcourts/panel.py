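"""County-year panel and county adjacency structures.

The panel is a complete rectangular (county, year) table holding the
outcome (overdose death counts), populations, the binary drug-court
exposure, and the raw covariates from which all derived model inputs are
built.  The adjacency graph encodes county neighbor relations and drives
the intrinsic conditional autoregressive (ICAR) spatial prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountyYearPanel",
    "AdjacencyGraph",
    "ValidationReport",
    "PanelError",
    "REQUIRED_COLUMNS",
    "BINARY_FIELDS",
    "PERCENT_FIELDS",
    "COUNT_FIELDS",
    "COVARIATE_FIELDS",
    "load_panel",
    "write_panel",
    "load_adjacency",
    "write_adjacency",
    "validate",
]


class PanelError(ValueError):
    """Raised for fatal panel or adjacency problems."""


BINARY_FIELDS = ("drug_court", "hidta", "democrat_da", "urban", "mua")

PERCENT_FIELDS = (
    "uninsured_pct",
    "poverty_pct",
    "unemployed_pct",
    "disabled_pct",
    "food_stamps_pct",
    "public_assistance_pct",
    "no_hs_diploma_pct",
)

COUNT_FIELDS = (
    "deaths",
    "population",
    "possession_arrests",
    "persons_arrests",
    "property_arrests",
    "otp_count",
)

#: fields required from the first transition year onward (the baseline year
#: only needs deaths and population)
COVARIATE_FIELDS = (
    "drug_court",
    "possession_arrests",
    "persons_arrests",
    "property_arrests",
    "crime_rate",
    "hidta",
    "democrat_da",
    "urban",
    "mua",
    "uninsured_pct",
    "poverty_pct",
    "unemployed_pct",
    "disabled_pct",
    "food_stamps_pct",
    "public_assistance_pct",
    "no_hs_diploma_pct",
    "otp_count",
)

REQUIRED_COLUMNS = ("county_id", "year", "deaths", "population") + COVARIATE_FIELDS

DEFAULT_WINDOW = (2017, 2023)


@dataclass(frozen=True)
class CountyYearPanel:
    """Rectangular county x year table of outcomes, exposure and covariates.

    Parameters
    ----------
    data
        One row per (county, year), sorted by county then year, with at
        least :data:`REQUIRED_COLUMNS`.
    window
        Inclusive (first_year, last_year) of the modeled window.  The
        first year is the baseline; transitions run from the second year.
    """

    data: pd.DataFrame
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        _check_panel_frame(self.data, self.window)
        df = (
            self.data.sort_values(["county_id", "year"])
            .reset_index(drop=True)
        )
        object.__setattr__(self, "data", df)

    # -- basic accessors ---------------------------------------------------

    @property
    def counties(self) -> list:
        return sorted(self.data["county_id"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return list(range(self.window[0], self.window[1] + 1))

    @property
    def baseline_year(self) -> int:
        return self.window[0]

    @property
    def transition_years(self) -> list[int]:
        return list(range(self.window[0] + 1, self.window[1] + 1))

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_years(self) -> int:
        return self.window[1] - self.window[0] + 1

    def matrix(self, column: str) -> np.ndarray:
        """Return ``column`` as an (n_counties, n_years) array.

        Rows follow :attr:`counties` order, columns follow :attr:`years`.
        """
        wide = self.data.pivot(index="county_id", columns="year", values=column)
        wide = wide.reindex(index=self.counties, columns=self.years)
        return wide.to_numpy(dtype=float)

    @property
    def deaths(self) -> np.ndarray:
        return self.matrix("deaths")

    @property
    def population(self) -> np.ndarray:
        return self.matrix("population")

    @property
    def drug_court(self) -> np.ndarray:
        return self.matrix("drug_court")

    def rows_for(self, county, year: int) -> pd.Series:
        sel = self.data[(self.data["county_id"] == county) & (self.data["year"] == year)]
        if sel.empty:
            raise KeyError((county, year))
        return sel.iloc[0]


def _check_panel_frame(df: pd.DataFrame, window: tuple[int, int]) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"missing required column(s): {', '.join(missing)}")

    first, last = window
    years = list(range(first, last + 1))
    counties = sorted(df["county_id"].unique().tolist())

    observed = set(zip(df["county_id"], df["year"]))
    if len(observed) != len(df):
        dupes = df[df.duplicated(["county_id", "year"])][["county_id", "year"]]
        cell = tuple(dupes.iloc[0])
        raise PanelError(f"duplicate (county, year) row: {cell}")
    for county in counties:
        for year in years:
            if (county, year) not in observed:
                raise PanelError(
                    f"panel is not rectangular: missing ({county}, {year})"
                )
    extra_years = set(df["year"]) - set(years)
    if extra_years:
        raise PanelError(
            f"rows outside configured window {window}: years {sorted(extra_years)}"
        )

    transition = df["year"] >= first + 1

    for col in ("deaths", "population"):
        vals = df[col]
        if vals.isna().any():
            cell = _first_bad_cell(df, vals.isna())
            raise PanelError(f"missing {col} at {cell}")
        if (vals.to_numpy() % 1 != 0).any():
            cell = _first_bad_cell(df, vals % 1 != 0)
            raise PanelError(f"non-integer {col} at {cell}")
    if (df["deaths"] < 0).any():
        cell = _first_bad_cell(df, df["deaths"] < 0)
        raise PanelError(f"negative deaths at {cell}")
    if (df["population"] <= 0).any():
        cell = _first_bad_cell(df, df["population"] <= 0)
        raise PanelError(f"non-positive population at {cell}")

    # covariates are only required from the first transition year on
    for col in COVARIATE_FIELDS:
        bad = transition & df[col].isna()
        if bad.any():
            cell = _first_bad_cell(df, bad)
            raise PanelError(f"missing covariate {col} at {cell}")

    sub = df[transition]
    for col in BINARY_FIELDS:
        ok = sub[col].isin([0, 1])
        if not ok.all():
            cell = _first_bad_cell(sub, ~ok)
            raise PanelError(f"non-binary value in {col} at {cell}")
    for col in PERCENT_FIELDS:
        ok = (sub[col] >= 0) & (sub[col] <= 100)
        if not ok.all():
            cell = _first_bad_cell(sub, ~ok)
            raise PanelError(f"{col} outside [0, 100] at {cell}")
    for col in ("possession_arrests", "persons_arrests", "property_arrests", "otp_count"):
        ok = sub[col] >= 0
        if not ok.all():
            cell = _first_bad_cell(sub, ~ok)
            raise PanelError(f"negative count in {col} at {cell}")


def _first_bad_cell(df: pd.DataFrame, mask) -> tuple:
    row = df[np.asarray(mask, dtype=bool)].iloc[0]
    return (row["county_id"], int(row["year"]))


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected, simple county neighbor graph.

    Edges are stored deduplicated and without self-loops.  A disconnected
    graph is allowed at construction; :func:`validate` turns it into a
    warning and the ICAR machinery applies its sum-to-zero constraint per
    connected component.
    """

    nodes: tuple
    edges: tuple

    def __post_init__(self) -> None:
        nodes = tuple(sorted(set(self.nodes)))
        seen = set()
        edges = []
        for a, b in self.edges:
            if a == b:
                raise PanelError(f"self-loop edge ({a}, {a}) is not allowed")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
        for a, b in edges:
            if a not in nodes or b not in nodes:
                raise PanelError(f"edge ({a}, {b}) references unknown node")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", tuple(sorted(edges)))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], nodes: Iterable | None = None) -> "AdjacencyGraph":
        edges = [tuple(e) for e in edges]
        if nodes is None:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes=tuple(nodes), edges=tuple(edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.to_networkx())

    def components(self) -> list[tuple]:
        """Connected components as sorted node tuples, largest first."""
        comps = [tuple(sorted(c)) for c in nx.connected_components(self.to_networkx())]
        return sorted(comps, key=lambda c: (-len(c), c))

    def component_labels(self, order: Sequence | None = None) -> np.ndarray:
        """Integer component label per node, in ``order`` (default node order)."""
        order = list(order) if order is not None else list(self.nodes)
        label = {}
        for k, comp in enumerate(self.components()):
            for node in comp:
                label[node] = k
        return np.array([label[n] for n in order], dtype=int)

    def laplacian(self, order: Sequence | None = None) -> np.ndarray:
        """Dense graph Laplacian D - W with rows/cols in ``order``."""
        order = list(order) if order is not None else list(self.nodes)
        idx = {n: i for i, n in enumerate(order)}
        n = len(order)
        lap = np.zeros((n, n))
        for a, b in self.edges:
            i, j = idx[a], idx[b]
            lap[i, i] += 1.0
            lap[j, j] += 1.0
            lap[i, j] -= 1.0
            lap[j, i] -= 1.0
        return lap


@dataclass
class ValidationReport:
    """Findings from cross-checking a panel against an adjacency graph."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# -- I/O ---------------------------------------------------------------------


def load_panel(path: str | Path, window: tuple[int, int] = DEFAULT_WINDOW) -> CountyYearPanel:
    """Load a county-year panel from a CSV file.

    The CSV must have a header row with one row per (county, year) and the
    columns in :data:`REQUIRED_COLUMNS`.  Raises :class:`PanelError` with
    the offending column or cell on any invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return CountyYearPanel(data=df, window=window)


def write_panel(panel: CountyYearPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def load_adjacency(path: str | Path) -> AdjacencyGraph:
    """Load a county adjacency graph.

    Accepts a two-column CSV edge list (``county_a``, ``county_b``) or a
    JSON object mapping each county to its neighbor list.  Reversed and
    duplicate edges are deduplicated; self-loops are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        edges = [(a, b) for a, nbrs in mapping.items() for b in nbrs]
        return AdjacencyGraph.from_edges(edges, nodes=mapping.keys())
    df = pd.read_csv(path)
    if not {"county_a", "county_b"}.issubset(df.columns):
        raise PanelError("adjacency CSV needs columns county_a, county_b")
    return AdjacencyGraph.from_edges(zip(df["county_a"], df["county_b"]))


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> None:
    pd.DataFrame(list(graph.edges), columns=["county_a", "county_b"]).to_csv(
        path, index=False
    )


# -- validation --------------------------------------------------------------


def validate(panel: CountyYearPanel, graph: AdjacencyGraph) -> ValidationReport:
    """Cross-check a loaded panel and adjacency graph.

    Fatal findings go to ``errors`` (node-set mismatches); non-fatal ones
    to ``warnings`` (graph disconnection, a drug-court indicator that
    reverts 1 -> 0 within a county).  Pure function: neither input is
    modified.
    """
    report = ValidationReport()
    panel_counties = set(panel.counties)
    graph_nodes = set(graph.nodes)
    for county in sorted(panel_counties - graph_nodes):
        report.errors.append(f"county {county} in panel but absent from adjacency graph")
    for node in sorted(graph_nodes - panel_counties):
        report.errors.append(f"node {node} in adjacency graph but absent from panel")

    if graph.n_nodes and not graph.is_connected():
        k = len(graph.components())
        report.warnings.append(
            f"adjacency graph is disconnected ({k} components); "
            "ICAR sum-to-zero constraint will apply per component"
        )

    court = panel.drug_court
    for i, county in enumerate(panel.counties):
        seq = court[i]
        if np.any(np.diff(seq[~np.isnan(seq)]) < 0):
            report.warnings.append(
                f"county {county} has a non-monotone drug-court sequence (1 -> 0 reversal)"
            )
    return report
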