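"""End-to-end prioritization pipeline.

:class:`GenePrioritizer` wires the pieces together: topology scores from the
network, a GOSet derived from the seed genes by enrichment (or supplied
directly), expression-cluster overlap scores, and the fused ranking. Seed-
independent work (degree, betweenness, clustering) is computed once and
cached so the seed set can change cheaply — which the cross-validation
benchmark exploits heavily.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .annotation import build_goset, enrich_terms, select_term_set
from .expression import (
    ClusterAssignment,
    ExpressionDataset,
    cluster_genes,
    expression_rank_score,
    score_cluster_overlaps,
)
from .integration import IntegratedRanking, combine
from .network import (
    GeneNetwork,
    GeneSet,
    betweenness_scores,
    degree_scores,
    network_rank_score,
)

__all__ = ["GenePrioritizer"]


class GenePrioritizer:
    """Rank candidate disease genes from a PPI network plus optional GO
    annotations and expression datasets.

    Parameters
    ----------
    net
        The PPI network; its genes are the ranked universe.
    annotations
        GO annotation table (gene, term, evidence, aspect). Needed to rebuild
        a GOSet from a seed set; optional if a GOSet is always supplied.
    datasets
        Preprocessed expression datasets. Without them S_E is neutral (0.5)
        and the fusion reduces to the network score.
    lam
        Weight of the expression side in the fused score (default 0.2).
    top_k_terms, hallmark_terms
        Enrichment term selection: top-K smallest-p terms unioned with a
        user-supplied hallmark list.
    n_perm
        Permutation draws per cluster-overlap test.
    seed
        Master seed for every stochastic step.
    """

    def __init__(
        self,
        net: GeneNetwork,
        annotations: pd.DataFrame | None = None,
        datasets: Sequence[ExpressionDataset] = (),
        *,
        lam: float = 0.2,
        top_k_terms: int = 50,
        hallmark_terms: Sequence[str] = (),
        n_perm: int = 1000,
        ap_damping: float = 0.9,
        exclude_self: bool = False,
        seed: int = 0,
    ):
        self.net = net
        self.annotations = annotations
        self.datasets = list(datasets)
        self.lam = lam
        self.top_k_terms = top_k_terms
        self.hallmark_terms = tuple(hallmark_terms)
        self.n_perm = n_perm
        self.ap_damping = ap_damping
        self.exclude_self = exclude_self
        self.seed = seed
        self._degree: pd.Series | None = None
        self._betweenness: pd.Series | None = None
        self._clusters: list[ClusterAssignment] | None = None

    # ---- cached seed-independent pieces ----

    @property
    def degree(self) -> pd.Series:
        if self._degree is None:
            self._degree = degree_scores(self.net)
        return self._degree

    @property
    def betweenness(self) -> pd.Series:
        if self._betweenness is None:
            self._betweenness = betweenness_scores(self.net)
        return self._betweenness

    @property
    def clusters(self) -> list[ClusterAssignment]:
        """Per-dataset affinity-propagation partitions (unscored)."""
        if self._clusters is None:
            self._clusters = [
                cluster_genes(ds, damping=self.ap_damping, seed=self.seed)
                for ds in self.datasets
            ]
        return self._clusters

    # ---- pipeline stages ----

    def network_scores(self, seeds: GeneSet) -> pd.DataFrame:
        """Topology score table (c_d, c_b, c_spl, ranks, S_N) for ``seeds``."""
        return network_rank_score(
            self.net,
            seeds,
            exclude_self=self.exclude_self,
            degree=self.degree,
            betweenness=self.betweenness,
        )

    def goset_from_seeds(self, seeds: GeneSet, *, universe: GeneSet | None = None) -> GeneSet:
        """Enrich GO terms on ``seeds`` and map the selected terms back to a
        gene set restricted to the network."""
        if self.annotations is None:
            raise ValueError("no annotation table supplied")
        if universe is None:
            universe = GeneSet("network", self.net.nodes)
        result = enrich_terms(seeds, self.annotations, universe)
        terms = select_term_set(result, self.top_k_terms, self.hallmark_terms)
        return build_goset(terms, self.annotations, self.net)

    def expression_scores(self, goset: GeneSet, *, overlap_seed: int | None = None) -> pd.Series:
        """Per-gene S_E from cluster/GOSet overlap p-values.

        ``overlap_seed`` overrides the master seed for the permutation nulls
        (the benchmark keys it by experiment/method/ratio/fold).
        """
        seed = self.seed if overlap_seed is None else overlap_seed
        scored = [
            score_cluster_overlaps(asg, goset, n_perm=self.n_perm, seed=seed)
            for asg in self.clusters
        ]
        return expression_rank_score(scored, self.net.node_list)

    def rank(
        self,
        seeds: GeneSet,
        *,
        goset: GeneSet | None = None,
        lam: float | None = None,
        overlap_seed: int | None = None,
    ) -> IntegratedRanking:
        """Full fused ranking of every network gene.

        The GOSet is rebuilt from ``seeds`` by enrichment unless supplied.
        With no expression datasets S_E is neutral for every gene.
        """
        s_n = self.network_scores(seeds)["S_N"]
        if self.datasets:
            if goset is None:
                goset = self.goset_from_seeds(seeds)
            s_e = self.expression_scores(goset, overlap_seed=overlap_seed)
        else:
            s_e = pd.Series(0.5, index=s_n.index)
        return combine(s_n, s_e, self.lam if lam is None else lam)
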