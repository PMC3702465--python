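"""Expression-based gene scoring via cluster/GOSet overlap.

Each expression dataset is preprocessed (missing rows out, off-network genes
out, duplicate gene rows resolved to the largest-mean profile), clustered by
affinity propagation on pairwise Pearson correlation, and each cluster is
scored by how strongly it overlaps the GO-enriched gene set: the observed
overlap is compared against a permutation null (same-size random draws from
the dataset's genes, 1000 by default) and summarized as an upper-tail normal
p-value. Clusters are ranked by p within a dataset; a gene inherits its
cluster's rescaled rank and its final expression score ``S_E`` is the mean
over all datasets containing it (0.5 when none does).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from ._rng import substream
from .network import GeneNetwork, GeneSet, rescale_ranks

__all__ = [
    "ExpressionDataset",
    "ClusterAssignment",
    "preprocess",
    "filter_datasets",
    "cluster_genes",
    "cluster_overlap_pvalue",
    "score_cluster_overlaps",
    "expression_rank_score",
]


@dataclasses.dataclass
class ExpressionDataset:
    """A preprocessed genes x samples expression matrix."""

    id: str
    matrix: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass
class ClusterAssignment:
    """Partition of one dataset's genes plus per-cluster overlap statistics.

    ``table`` has one row per cluster: size, overlap, perm_mean, perm_sd, p,
    rank (filled by :func:`score_cluster_overlaps`; NaN before).
    """

    dataset_id: str
    labels: pd.Series  # gene -> cluster label (int)
    exemplars: list[str]
    table: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def preprocess(raw: pd.DataFrame, net: GeneNetwork, *, dataset_id: str = "ds") -> ExpressionDataset:
    """Clean a raw matrix: drop rows with missing values or off-network genes;
    resolve duplicate gene rows to the profile with the largest mean (first
    occurrence on ties)."""
    df = raw.copy()
    df.index = df.index.astype(str)
    df = df.dropna(axis=0, how="any")
    df = df[df.index.isin(net.nodes)]
    if df.index.has_duplicates:
        means = df.mean(axis=1).to_numpy()
        df = df.assign(_mean=means, _order=np.arange(len(df)))
        # stable sort keeps first occurrence ahead among equal means
        df = df.sort_values("_mean", ascending=False, kind="stable")
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_values("_order").drop(columns=["_mean", "_order"])
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"dataset too small after preprocessing: {df.shape}")
    return ExpressionDataset(dataset_id, df.astype(float))


def filter_datasets(
    datasets: Iterable[ExpressionDataset], min_samples: int = 5
) -> list[ExpressionDataset]:
    """Keep datasets with at least ``min_samples`` samples (strict 'fewer
    than' deletion rule)."""
    kept = [ds for ds in datasets if ds.n_samples >= min_samples]
    if not kept:
        raise ValueError("all datasets removed by the sample-count filter")
    return kept


def cluster_genes(
    ds: ExpressionDataset,
    *,
    damping: float = 0.9,
    preference: float | None = None,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Affinity-propagation clustering on pairwise Pearson correlation.

    ``preference`` defaults to the median off-diagonal similarity. Rows with
    zero variance (Pearson undefined) are dropped with a warning. If message
    passing does not converge every gene becomes its own singleton cluster.
    """
    x = ds.matrix.to_numpy()
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{ds.id}: dropped {int((~keep).sum())} constant expression rows "
            "(Pearson correlation undefined)",
            stacklevel=2,
        )
    genes = [g for g, k in zip(ds.genes, keep) if k]
    x = x[keep]
    if len(genes) < 2:
        raise ValueError("fewer than 2 usable genes for clustering")
    sim = np.corrcoef(x)
    if preference is None:
        preference = float(np.median(sim[~np.eye(len(genes), dtype=bool)]))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            preference=preference,
            max_iter=max_iter,
            convergence_iter=convergence_iter,
            random_state=int(seed) % (2**31),
        ).fit(sim)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    labels = np.asarray(ap.labels_)
    centers = ap.cluster_centers_indices_
    if not converged or (labels < 0).any() or centers is None or len(centers) == 0:
        warnings.warn(
            f"{ds.id}: affinity propagation did not converge; "
            "falling back to singleton clusters",
            stacklevel=2,
        )
        labels = np.arange(len(genes))
        exemplars = list(genes)
    else:
        exemplars = [genes[i] for i in centers]
    label_series = pd.Series(labels, index=genes, name="cluster")
    sizes = label_series.value_counts().sort_index()
    table = pd.DataFrame(
        {
            "cluster": sizes.index,
            "size": sizes.to_numpy(),
            "overlap": np.nan,
            "perm_mean": np.nan,
            "perm_sd": np.nan,
            "p": np.nan,
            "rank": np.nan,
        }
    ).set_index("cluster")
    return ClusterAssignment(ds.id, label_series, exemplars, table)


def cluster_overlap_pvalue(
    cluster: Iterable[str],
    goset: GeneSet,
    universe: Sequence[str],
    *,
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
    continuity: bool = True,
    method: str = "normal",
) -> tuple[int, float, float, float]:
    """Significance of a cluster's overlap with the GOSet by permutation.

    The null redraws ``len(cluster)`` genes from the dataset's gene universe
    without replacement ``n_perm`` times. Returns (observed, null mean, null
    sd, p) where p is the upper-tail normal p-value of the standardized
    observed overlap (continuity-corrected by default), or the empirical
    exceedance probability with ``method="empirical"``.

    Degenerate null (sd = 0): p = 1 when observed <= mean, else the smallest
    positive float.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cluster = list(cluster)
    universe = list(universe)
    csize = len(cluster)
    if csize > len(universe):
        raise ValueError("cluster is larger than the universe")
    in_goset = np.fromiter((g in goset for g in universe), dtype=bool, count=len(universe))
    observed = sum(1 for g in cluster if g in goset)
    # without-replacement draws: random keys, take the csize smallest per row
    keys = rng.random((n_perm, len(universe)))
    idx = np.argpartition(keys, csize - 1, axis=1)[:, :csize]
    null = in_goset[idx].sum(axis=1)
    mean = float(null.mean())
    sd = float(null.std(ddof=0))
    if method == "empirical":
        p = float((np.count_nonzero(null >= observed) + 1) / (n_perm + 1))
    elif sd == 0.0:
        p = 1.0 if observed <= mean else float(np.nextafter(0, 1))
    else:
        shift = 0.5 if continuity else 0.0
        z = (observed - shift - mean) / sd
        p = float(norm.sf(z))
    return observed, mean, sd, p


def score_cluster_overlaps(
    assignment: ClusterAssignment,
    goset: GeneSet,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    continuity: bool = True,
    method: str = "normal",
) -> ClusterAssignment:
    """Fill a :class:`ClusterAssignment`'s table with overlap p-values and
    within-dataset cluster ranks (rank 1 = smallest p, ties averaged).

    Each cluster draws from its own RNG substream keyed by
    (seed, dataset id, cluster label), so results do not depend on cluster
    evaluation order.
    """
    universe = list(assignment.labels.index)
    table = assignment.table.copy()
    for label in table.index:
        rng = substream(seed, "overlap", assignment.dataset_id, label)
        obs, mean, sd, p = cluster_overlap_pvalue(
            assignment.members(label),
            goset,
            universe,
            n_perm=n_perm,
            rng=rng,
            continuity=continuity,
            method=method,
        )
        table.loc[label, ["overlap", "perm_mean", "perm_sd", "p"]] = (obs, mean, sd, p)
    table["rank"] = rankdata(table["p"].to_numpy(), method="average")
    return ClusterAssignment(assignment.dataset_id, assignment.labels, assignment.exemplars, table)


def expression_rank_score(
    assignments: Sequence[ClusterAssignment],
    gene_universe: Iterable[str],
    *,
    neutral: float = 0.5,
) -> pd.Series:
    """Per-gene expression score ``S_E`` over ``gene_universe``.

    Within a dataset each cluster's rank is rescaled to [0, 1] (a lone cluster
    maps to 0.5) and shared by its member genes; a gene's S_E averages those
    values over the datasets that contain it. Genes seen in no dataset get the
    neutral score 0.5 — absence of expression evidence is not negative
    evidence.
    """
    if not assignments:
        raise ValueError("at least one dataset assignment is required")
    genes = sorted(gene_universe)
    total = pd.Series(0.0, index=genes)
    count = pd.Series(0, index=genes)
    for asg in assignments:
        if asg.table["p"].isna().any():
            raise ValueError(
                f"{asg.dataset_id}: cluster overlaps not scored; "
                "run score_cluster_overlaps first"
            )
        scaled = rescale_ranks(asg.table["rank"])
        per_gene = asg.labels.map(scaled)
        common = per_gene.index.intersection(total.index)
        total.loc[common] += per_gene.loc[common]
        count.loc[common] += 1
    s_e = pd.Series(neutral, index=genes, name="S_E")
    seen = count > 0
    s_e[seen] = total[seen] / count[seen]
    return s_e
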