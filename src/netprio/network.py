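"""PPI network construction and topology-based gene scoring.

Candidate genes are scored by three topological attributes relative to a set
of known disease genes ("seeds"): node degree ``c_d``, unnormalized
betweenness centrality ``c_b``, and the mean shortest-path distance ``c_spl``
from the seed genes.  Each attribute is converted to a tie-averaged rank,
rescaled to [0, 1], and the three are averaged into the network score ``S_N``
(lower = more disease-like).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from typing import Literal, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GeneSet",
    "GeneNetwork",
    "BuildReport",
    "TopologyScores",
    "RankVector",
    "build_network",
    "degree_scores",
    "betweenness_scores",
    "seed_distance_scores",
    "rank_transform",
    "rescale_ranks",
    "network_rank_score",
]

Direction = Literal["better-is-high", "better-is-low"]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (seed sets, GO-derived sets, noise draws)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def require_nonempty(self) -> "GeneSet":
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        return self


@dataclasses.dataclass(frozen=True)
class BuildReport:
    """Bookkeeping from edge-table ingestion."""

    n_rows: int
    n_self_loops: int
    n_invalid: int
    n_duplicates: int


class GeneNetwork:
    """Undirected PPI graph over official gene symbols.

    Thin wrapper around :class:`networkx.Graph` guaranteeing no self-loops and
    no duplicate (undirected) edges; nodes are exactly the edge endpoints.
    """

    def __init__(self, graph: nx.Graph, report: BuildReport | None = None):
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        self.graph = graph
        self.report = report

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_list(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork({self.n_nodes} genes, {self.n_edges} interactions)"


def build_network(
    edge_tables: Iterable[pd.DataFrame | Iterable[tuple[str, str]]],
    alias_map: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Union edge tables into a deduplicated undirected network.

    Rows are pairs of gene symbols. An optional ``alias_map`` translates
    aliases to official symbols before deduplication. Self-loop rows and rows
    with empty/missing identifiers are dropped and counted in the report;
    nodes are only introduced by surviving edges.
    """
    n_rows = n_self = n_bad = n_dup = 0
    edges: set[frozenset[str]] = set()
    for table in edge_tables:
        if isinstance(table, pd.DataFrame):
            rows = table.iloc[:, :2].itertuples(index=False, name=None)
        else:
            rows = iter(table)
        for a, b in rows:
            n_rows += 1
            a = _clean_symbol(a, alias_map)
            b = _clean_symbol(b, alias_map)
            if a is None or b is None:
                n_bad += 1
                continue
            if a == b:
                n_self += 1
                continue
            e = frozenset((a, b))
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
    if not edges:
        raise ValueError("empty network: no valid interactions after filtering")
    g = nx.Graph()
    g.add_edges_from(tuple(sorted(e)) for e in edges)
    return GeneNetwork(g, BuildReport(n_rows, n_self, n_bad, n_dup))


def _clean_symbol(x: object, alias_map: Mapping[str, str] | None) -> str | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    if not s or s.lower() in {"nan", "null", "-"}:
        return None
    if alias_map is not None:
        s = alias_map.get(s, s)
    return s


# ---------------------------------------------------------------------------
# topology attributes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TopologyScores:
    """Per-gene raw topological attributes.

    ``c_spl`` is NaN for genes that reach no seed; ``n_reachable`` counts the
    seeds each gene can reach.
    """

    c_d: pd.Series | None = None
    c_b: pd.Series | None = None
    c_spl: pd.Series | None = None
    n_reachable: pd.Series | None = None


def degree_scores(net: GeneNetwork) -> pd.Series:
    """Number of direct neighbours of each gene."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = dict(net.graph.degree())
    return pd.Series(deg, dtype=int).reindex(net.node_list)


def betweenness_scores(net: GeneNetwork) -> pd.Series:
    """Unnormalized betweenness: sum over unordered source-target pairs of the
    fraction of shortest paths passing through the gene (endpoints excluded;
    disconnected pairs contribute nothing)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    cb = nx.betweenness_centrality(net.graph, normalized=False)
    return pd.Series(cb, dtype=float).reindex(net.node_list)


def seed_distance_scores(
    net: GeneNetwork, seeds: GeneSet, *, exclude_self: bool = False
) -> tuple[pd.Series, pd.Series]:
    """Mean shortest-path distance from each gene to the reachable seed genes.

    Returns ``(c_spl, n_reachable)``. For a seed gene its own distance 0 is
    included unless ``exclude_self``. Genes reaching no seed get NaN.
    """
    present = sorted(seeds.members & net.nodes)
    if not present:
        raise ValueError("no seed gene is present in the network")
    nodes = net.node_list
    dist_sum = pd.Series(0.0, index=nodes)
    count = pd.Series(0, index=nodes)
    for s in present:
        d = nx.single_source_shortest_path_length(net.graph, s)
        idx = list(d.keys())
        dist_sum.loc[idx] += list(d.values())
        count.loc[idx] += 1
    if exclude_self:
        for s in present:
            count.loc[s] -= 1  # d(s,s)=0 adds nothing to the sum
    with np.errstate(invalid="ignore", divide="ignore"):
        c_spl = dist_sum / count.replace(0, np.nan)
    return c_spl, count


# ---------------------------------------------------------------------------
# rank transform
# ---------------------------------------------------------------------------


class RankVector(NamedTuple):
    """Tie-averaged ranks (1 = best) plus the direction they encode."""

    ranks: pd.Series
    direction: Direction


def rank_transform(
    scores: pd.Series,
    direction: Direction = "better-is-low",
    *,
    na_is_worst: bool = True,
) -> RankVector:
    """Convert raw attribute values to fractional (tie-averaged) ranks.

    Rank 1 is the best gene under ``direction``. NaN entries (e.g. genes that
    reach no seed) share the worst positions, averaged, so the rank sum is
    always N(N+1)/2.
    """
    v = scores.astype(float)
    na = v.isna()
    if na.any() and not na_is_worst:
        raise ValueError("scores contain NaN and na_is_worst=False")
    finite = v[~na]
    if not np.isfinite(finite.to_numpy()).all():
        raise ValueError("scores must be finite")
    if direction == "better-is-high":
        finite = -finite
    elif direction != "better-is-low":
        raise ValueError(f"unknown direction {direction!r}")
    ranks = pd.Series(np.nan, index=v.index, dtype=float)
    ranks[~na] = rankdata(finite.to_numpy(), method="average")
    n, n_ok = len(v), int((~na).sum())
    if n_ok < n:
        # NaN genes share positions n_ok+1 .. n
        ranks[na] = (n_ok + 1 + n) / 2.0
    return RankVector(ranks, direction)


def rescale_ranks(ranks: pd.Series) -> pd.Series:
    """Map ranks 1..N onto [0, 1] via (rank-1)/(N-1); a single item maps to 0.5."""
    n = len(ranks)
    if n <= 1:
        return pd.Series(0.5, index=ranks.index)
    return (ranks - 1.0) / (n - 1.0)


def network_rank_score(
    net: GeneNetwork,
    seeds: GeneSet,
    *,
    exclude_self: bool = False,
    degree_direction: Direction = "better-is-high",
    betweenness_direction: Direction = "better-is-high",
    spl_direction: Direction = "better-is-low",
    degree: pd.Series | None = None,
    betweenness: pd.Series | None = None,
) -> pd.DataFrame:
    """Topology score table with the fused network score ``S_N``.

    ``S_N`` is the mean of the three rescaled rank vectors (degree and
    betweenness: high is good; seed distance: low is good); 0 = ranked best on
    every attribute, 1 = ranked worst on every attribute. ``degree`` /
    ``betweenness`` may be passed precomputed (they do not depend on seeds).

    Returns a DataFrame indexed by gene with columns
    ``c_d, c_b, c_spl, n_reachable, rank_d, rank_b, rank_spl, S_N``.
    """
    seeds.require_nonempty()
    c_d = degree if degree is not None else degree_scores(net)
    c_b = betweenness if betweenness is not None else betweenness_scores(net)
    c_spl, n_reach = seed_distance_scores(net, seeds, exclude_self=exclude_self)
    rank_d = rank_transform(c_d, degree_direction).ranks
    rank_b = rank_transform(c_b, betweenness_direction).ranks
    rank_spl = rank_transform(c_spl, spl_direction).ranks
    s_n = (
        rescale_ranks(rank_d) + rescale_ranks(rank_b) + rescale_ranks(rank_spl)
    ) / 3.0
    return pd.DataFrame(
        {
            "c_d": c_d,
            "c_b": c_b,
            "c_spl": c_spl,
            "n_reachable": n_reach,
            "rank_d": rank_d,
            "rank_b": rank_b,
            "rank_spl": rank_spl,
            "S_N": s_n,
        }
    )
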