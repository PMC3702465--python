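"""GO-term enrichment of a seed gene set and back-mapping to a gene set.

The seed set is tested term-by-term with a one-sided hypergeometric test
against a gene universe (by default the network's genes). The top-K terms —
optionally unioned with a user-supplied list of cancer-hallmark terms — are
mapped back to every gene carrying one of them, intersected with the network,
yielding the "GO-enriched gene set" (GOSet): a deliberately noisy pool of
plausible disease genes.

GO annotations are noisy by construction (most are uncurated IEA records);
that noise is the point of the downstream robustness benchmark, so evidence
codes are kept by default and filtering is opt-in.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .network import GeneNetwork, GeneSet

__all__ = [
    "make_annotation_table",
    "enrich_terms",
    "select_term_set",
    "build_goset",
]


def make_annotation_table(records: Iterable[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Annotation table from (gene, term, evidence, aspect) records,
    collapsing duplicate (gene, term) pairs."""
    df = pd.DataFrame(records, columns=["gene", "term", "evidence", "aspect"])
    return df.drop_duplicates(subset=["gene", "term"]).reset_index(drop=True)


def _filter_annotations(
    annotations: pd.DataFrame,
    aspects: tuple[str, ...] | None,
    exclude_evidence: tuple[str, ...],
) -> pd.DataFrame:
    df = annotations
    if aspects:
        df = df[df["aspect"].isin(aspects)]
    if exclude_evidence:
        df = df[~df["evidence"].isin(exclude_evidence)]
    return df


def enrich_terms(
    study: GeneSet,
    annotations: pd.DataFrame,
    universe: GeneSet,
    *,
    aspects: tuple[str, ...] | None = ("P",),
    exclude_evidence: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    For a term annotating K of the N universe genes, of which k fall in the
    n-gene study set, p = P(X >= k) for X ~ Hypergeom(N, K, n). Only the
    biological-process aspect is tested by default. Study genes outside the
    universe are ignored (they carry no draw from the urn).

    Returns a DataFrame (term, study_count, pop_count, p) sorted by p.
    """
    uni = set(universe.require_nonempty().members)
    study_in = set(study.require_nonempty().members) & uni
    if not study_in:
        raise ValueError("no study gene lies in the universe")
    ann = _filter_annotations(annotations, aspects, exclude_evidence)
    ann = ann[ann["gene"].isin(uni)]
    n_universe, n_study = len(uni), len(study_in)
    pop_counts = ann.groupby("term")["gene"].nunique()
    study_counts = (
        ann[ann["gene"].isin(study_in)].groupby("term")["gene"].nunique()
    ).reindex(pop_counts.index, fill_value=0)
    p = hypergeom.sf(
        study_counts.to_numpy() - 1, n_universe, pop_counts.to_numpy(), n_study
    )
    out = pd.DataFrame(
        {
            "term": pop_counts.index,
            "study_count": study_counts.to_numpy(),
            "pop_count": pop_counts.to_numpy(),
            "p": p,
        }
    ).sort_values(["p", "term"], kind="stable", ignore_index=True)
    return out


def select_term_set(
    result: pd.DataFrame,
    top_k: int = 50,
    hallmark_terms: Iterable[str] = (),
) -> set[str]:
    """Union of the top-K smallest-p terms and the hallmark term list.

    Terms tied with the K-th smallest p are all included.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    chosen: set[str] = set()
    if len(result):
        ordered = result.sort_values(["p", "term"], kind="stable")
        if len(ordered) <= top_k:
            chosen = set(ordered["term"])
        else:
            cutoff = ordered["p"].iloc[top_k - 1]
            chosen = set(ordered.loc[ordered["p"] <= cutoff, "term"])
    return chosen | set(hallmark_terms)


def build_goset(
    terms: Iterable[str],
    annotations: pd.DataFrame,
    net: GeneNetwork,
    *,
    name: str = "GOSet",
) -> GeneSet:
    """Genes annotated with at least one selected term, restricted to the
    network (genes the method can actually rank)."""
    terms = set(terms)
    if not terms:
        raise ValueError("term set is empty")
    genes = set(annotations.loc[annotations["term"].isin(terms), "gene"]) & net.nodes
    if not genes:
        raise ValueError("GOSet is empty: no annotated gene lies in the network")
    return GeneSet(name, genes)
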