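"""IBD-sharing networks and degree-of-relatedness classification.

Pairs of individuals passing an edge rule form an undirected graph whose
connected components trace clusters of biological relatedness across
macroregions. The edge rules mirror the analysis thresholds: any tract at
8 cM or 20 cM, or the stricter false-positive filter (at least three
medium 8-12 cM tracts, or any tract over 12 cM).

Degree calls compare a pair's (total cM, segment count) against a
simulated pedigree reference cloud (see
:func:`ibdkit.simulate.build_reference_cloud`): per degree, a bivariate
Gaussian is fitted in (log1p(sum_cM), log1p(n_segments)) space and all
degrees whose density is within ``exp(-3)`` of the best are reported as an
inclusive range, mirroring interval-style reporting such as "5th- to
7th-degree relatives". This statistical rule is an explicit stand-in for
visual assignment against published pedigree distributions and is labelled
as such in exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import PAIR_SUMMARY_COLUMNS, REGIONS

__all__ = [
    "EDGE_RULES",
    "IBDGraph",
    "DegreeCall",
    "DegreeClassifier",
    "pair_filter_trans",
    "build_network",
    "classify_edges_by_region",
    "classify_degree",
    "export_edgelist",
    "read_edgelist",
]

EDGE_RULES = ("min_tract_8", "min_tract_20", "trans_filter")


class ConfigurationError(ValueError):
    """Invalid analysis configuration (unknown rule, incomplete reference)."""


def pair_filter_trans(summary, conjunctive: bool = False) -> bool:
    """Strict pair filter against false-positive IBD discovery.

    Default (disjunctive) reading: the pair passes with at least three
    shared tracts of 8-12 cM, *or* any tract longer than 12 cM. The
    conjunctive reading (both required) is available via ``conjunctive``.
    ``summary`` is a mapping/row with ``n_8_12`` and ``n_ge12`` computed at
    the 8 cM floor.
    """
    many_medium = summary["n_8_12"] >= 3
    any_long = summary["n_ge12"] >= 1
    return bool(many_medium and any_long) if conjunctive else bool(many_medium or any_long)


@dataclass
class IBDGraph:
    """Undirected IBD-sharing graph; isolated individuals are excluded."""

    graph: nx.Graph
    edge_rule: str
    components: list[frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        self.components = sorted(comps, key=lambda c: (-len(c), sorted(c)))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def component_sizes(self) -> list[int]:
        """Connected-component sizes in decreasing order."""
        return [len(c) for c in self.components]


def _edge_mask(summaries: pd.DataFrame, edge_rule: str, conjunctive: bool) -> pd.Series:
    if edge_rule == "min_tract_8":
        return summaries["max_cM"] >= 8.0
    if edge_rule == "min_tract_20":
        return summaries["max_cM"] >= 20.0
    if edge_rule == "trans_filter":
        if conjunctive:
            return (summaries["n_8_12"] >= 3) & (summaries["n_ge12"] >= 1)
        return (summaries["n_8_12"] >= 3) | (summaries["n_ge12"] >= 1)
    raise ConfigurationError(f"unknown edge rule {edge_rule!r}; use one of {EDGE_RULES}")


def build_network(
    summaries: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    edge_rule: str = "trans_filter",
    conjunctive: bool = False,
) -> IBDGraph:
    """Build the IBD-sharing network from per-pair summaries.

    Nodes carry ``region`` and ``group`` attributes when ``meta`` is given;
    only individuals with at least one passing edge are included
    ("interconnected individuals"). Components are computed on construction
    and reported in decreasing size order.
    """
    g = nx.Graph()
    if not summaries.empty:
        passing = summaries.loc[_edge_mask(summaries, edge_rule, conjunctive)]
        for row in passing.itertuples(index=False):
            g.add_edge(
                row.iid1,
                row.iid2,
                sum_cM=float(row.sum_cM),
                max_cM=float(row.max_cM),
                n_segments=int(row.n_segments),
            )
    if meta is not None:
        info = meta.set_index("iid")
        for node in g.nodes:
            if node in info.index:
                g.nodes[node]["region"] = info.loc[node, "region"]
                g.nodes[node]["group"] = info.loc[node, "group"]
    return IBDGraph(graph=g, edge_rule=edge_rule)


def classify_edges_by_region(
    graph: IBDGraph, meta: pd.DataFrame | None = None
) -> dict[tuple[str, str], int]:
    """Tally edges by unordered macroregion pair.

    Region labels are taken from node attributes, falling back to ``meta``.
    Every node must resolve to a region; the tally sums to the edge count.
    """
    lookup = {}
    if meta is not None:
        lookup = dict(zip(meta["iid"], meta["region"]))

    def region_of(node: str) -> str:
        reg = graph.graph.nodes[node].get("region", lookup.get(node))
        if reg is None:
            raise ConfigurationError(f"node {node!r} has no region label")
        if reg not in REGIONS:
            raise ConfigurationError(f"node {node!r} region {reg!r} not in {REGIONS}")
        return reg

    tally: dict[tuple[str, str], int] = {}
    for u, v in graph.graph.edges:
        key = tuple(sorted((region_of(u), region_of(v))))
        tally[key] = tally.get(key, 0) + 1
    return tally


@dataclass(frozen=True)
class DegreeCall:
    """Degree-of-relatedness call for one pair."""

    iid1: str
    iid2: str
    degree_lo: int | None
    degree_hi: int | None
    score: float
    unrelated: bool

    @property
    def degree_range(self) -> tuple[int, int] | str:
        if self.unrelated:
            return "unrelated"
        return (self.degree_lo, self.degree_hi)


class DegreeClassifier:
    """Gaussian density classifier over a pedigree reference cloud.

    Per degree, a bivariate Gaussian is fitted to the cloud in
    (log1p(sum_cM), log1p(n_segments)); a query pair is assigned the
    inclusive range of degrees whose log-density lies within
    ``log_ratio_band`` (default 3) of the best degree. Pairs whose total
    sharing falls below the ``unrelated_percentile`` (default 1st) of the
    deepest degree's cloud are called "unrelated".
    """

    REQUIRED_DEGREES = tuple(range(1, 9))

    def __init__(
        self,
        cloud: pd.DataFrame,
        log_ratio_band: float = 3.0,
        unrelated_percentile: float = 1.0,
        reg_var: float = 1e-4,
    ) -> None:
        missing = set(self.REQUIRED_DEGREES) - set(cloud["degree"].unique())
        if missing:
            raise ConfigurationError(
                f"reference cloud missing degree(s): {sorted(missing)}"
            )
        self.log_ratio_band = float(log_ratio_band)
        self._stats: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
        for degree, sub in cloud.groupby("degree"):
            x = np.column_stack(
                [np.log1p(sub["sum_cM"]), np.log1p(sub["n_segments"])]
            )
            mean = x.mean(axis=0)
            cov = np.cov(x, rowvar=False) + reg_var * np.eye(2)
            self._stats[int(degree)] = (mean, np.linalg.inv(cov),
                                        float(np.linalg.slogdet(cov)[1]))
        deepest = cloud.loc[cloud["degree"] == max(self.REQUIRED_DEGREES), "sum_cM"]
        self.unrelated_floor_cM = float(np.percentile(deepest, unrelated_percentile))

    def log_density(self, sum_cM: float, n_segments: int) -> dict[int, float]:
        p = np.array([np.log1p(sum_cM), np.log1p(n_segments)])
        out = {}
        for degree, (mean, prec, logdet) in self._stats.items():
            d = p - mean
            out[degree] = float(-0.5 * (d @ prec @ d) - 0.5 * logdet)
        return out

    def classify(
        self, sum_cM: float, n_segments: int, iid1: str = "", iid2: str = ""
    ) -> DegreeCall:
        # n_segments == 0 (no retained sharing) is trivially unrelated; the
        # percentile floor can itself be 0 when distant-degree replicates
        # often share nothing at the length floor, hence the non-strict test
        if n_segments == 0 or sum_cM <= max(self.unrelated_floor_cM, 0.0):
            return DegreeCall(iid1, iid2, None, None, float("-inf"), unrelated=True)
        dens = self.log_density(sum_cM, n_segments)
        best = max(dens, key=dens.get)
        in_band = [d for d, v in dens.items() if v >= dens[best] - self.log_ratio_band]
        return DegreeCall(
            iid1, iid2, min(in_band), max(in_band), dens[best], unrelated=False
        )


def classify_degree(summary, cloud: pd.DataFrame, **kwargs) -> DegreeCall:
    """Classify one pair summary against a reference cloud (convenience
    wrapper; build a :class:`DegreeClassifier` directly for many pairs)."""
    clf = DegreeClassifier(cloud, **kwargs)
    return clf.classify(
        float(summary["sum_cM"]),
        int(summary["n_segments"]),
        str(summary.get("iid1", "")),
        str(summary.get("iid2", "")),
    )


EDGELIST_COLUMNS = ["iid1", "iid2", "sum_cM", "max_cM", "n_segments", "region_pair"]


def export_edgelist(graph: IBDGraph, sink) -> pd.DataFrame:
    """Write the edge list as TSV (iid1, iid2, sum_cM, max_cM, n_segments,
    region_pair); returns the frame written."""
    rows = []
    for u, v, attrs in graph.graph.edges(data=True):
        a, b = sorted((u, v))
        r1 = graph.graph.nodes[a].get("region", "")
        r2 = graph.graph.nodes[b].get("region", "")
        pair = "-".join(sorted((r1, r2))) if r1 and r2 else ""
        rows.append(
            (a, b, attrs["sum_cM"], attrs["max_cM"], attrs["n_segments"], pair)
        )
    frame = pd.DataFrame(rows, columns=EDGELIST_COLUMNS).sort_values(
        ["iid1", "iid2"], ignore_index=True
    )
    if hasattr(sink, "write"):
        frame.to_csv(sink, sep="\t", index=False)
    else:
        frame.to_csv(Path(sink), sep="\t", index=False)
    return frame


def read_edgelist(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#", keep_default_na=False)


def export_components(graph: IBDGraph, sink) -> pd.DataFrame:
    """Component membership TSV (iid, component, component_size)."""
    rows = [
        (iid, idx, len(comp))
        for idx, comp in enumerate(graph.components)
        for iid in sorted(comp)
    ]
    frame = pd.DataFrame(rows, columns=["iid", "component", "component_size"])
    if hasattr(sink, "write"):
        frame.to_csv(sink, sep="\t", index=False)
    else:
        frame.to_csv(Path(sink), sep="\t", index=False)
    return frame
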