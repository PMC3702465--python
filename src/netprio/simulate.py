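"""Synthetic data with planted structure for every pipeline stage.

The generator emulates, at desk scale, the statistical structure the method
exploits in real data:

* a scale-free (preferential-attachment) PPI background with a planted
  disease module — a gene subset densified well above background density;
* a known-gene seed set drawn from the module, and a "GO-enriched" gene set
  of intermediate quality (a purity-controlled mixture of module and
  background genes: better than random, worse than the seed set);
* GO annotations whose planted terms hit module genes at a much higher rate
  than background genes, so enrichment on the seed set recovers them;
* expression datasets in which module genes share a latent factor (planted
  co-expression cluster) on top of white noise, with configurable duplicate
  rows, ``null`` cells and off-network genes to exercise preprocessing.

Everything derives from one master seed via labelled substreams, so a
scenario regenerates bit-identically and no fixture ever needs checking in.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .expression import ExpressionDataset, filter_datasets, preprocess
from .io import write_gene_list, write_gmt
from .network import GeneNetwork, GeneSet

__all__ = [
    "SyntheticScenario",
    "SyntheticData",
    "make_network",
    "make_gene_sets",
    "make_annotations",
    "make_expression",
    "write_scenario",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults define the reference recovery scenario: a 500-gene scale-free
    network with a 30-gene module (internal edge probability 0.3), a 20-gene
    known set, a GOSet of 40 genes at purity 0.6, and 4 expression datasets
    of 20 samples with within-module Pearson correlation ~0.8.
    """

    seed: int = 0
    n_genes: int = 500
    attachment: int = 2  # preferential-attachment edges per new node
    module_size: int = 30
    module_p: float = 0.3  # internal edge probability of the planted module
    known_size: int = 20
    goset_size: int = 40
    goset_purity: float = 0.6  # fraction of GOSet genes inside the module
    n_datasets: int = 4
    samples_per_dataset: int = 20
    genes_per_dataset: int = 250
    within_corr: float = 0.8  # target pairwise Pearson among module genes
    noise_sd: float = 1.0  # extra white-noise scale (1 keeps within_corr)
    n_terms: int = 30
    n_planted_terms: int = 5
    module_annotation_rate: float = 0.8
    background_annotation_rate: float = 0.05
    duplicate_frac: float = 0.05
    null_frac: float = 0.02
    n_offnetwork_genes: int = 5

    def __post_init__(self):
        if self.module_size > self.n_genes:
            raise ValueError("module larger than the network")
        if self.known_size > self.module_size:
            raise ValueError("known set larger than the module")
        if not (0.0 <= self.goset_purity <= 1.0):
            raise ValueError("goset_purity must lie in [0, 1]")
        if round(self.goset_purity * self.goset_size) > self.module_size:
            raise ValueError("GOSet purity demands more module genes than exist")

    def replace(self, **kw) -> "SyntheticScenario":
        return dataclasses.replace(self, **kw)

    @classmethod
    def noise_benchmark(cls, seed: int = 0) -> "SyntheticScenario":
        """Desk-scale analogue of the noise-robustness study: 800 genes,
        40-gene module, 10 known genes, and a 280-gene GOSet with 30 module
        genes (~2.9x chance enrichment) — large enough to supply noise draws
        up to 25x the known-set size."""
        return cls(
            seed=seed,
            n_genes=800,
            module_size=40,
            known_size=10,
            goset_size=280,
            goset_purity=30 / 280,
            n_datasets=3,
            genes_per_dataset=300,
        )

    # ---- derived helpers ----

    @property
    def symbols(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    def module_genes(self) -> list[str]:
        """Module membership is a pure function of the scenario, so every
        generator op agrees on it without passing state around."""
        rng = substream(self.seed, "module")
        return sorted(rng.choice(self.symbols, size=self.module_size, replace=False))

    def generate(self) -> "SyntheticData":
        net = make_network(self)
        known, goset, truth = make_gene_sets(self, net)
        annotations = make_annotations(self, net, truth)
        raw = make_expression(self, net, truth)
        datasets = filter_datasets(
            [preprocess(df, net, dataset_id=ds_id) for ds_id, df in raw.items()]
        )
        return SyntheticData(self, net, self.module_genes(), known, goset, truth, annotations, raw, datasets)


@dataclass
class SyntheticData:
    """One generated study: network, gene sets, annotations, expression."""

    scenario: SyntheticScenario
    net: GeneNetwork
    module: list[str]
    known: GeneSet
    goset: GeneSet
    truth: pd.DataFrame
    annotations: pd.DataFrame
    raw_expression: dict[str, pd.DataFrame]
    datasets: list[ExpressionDataset] = field(default_factory=list)

    @property
    def heldout_module_genes(self) -> list[str]:
        return sorted(set(self.module) - self.known.members)


def make_network(scn: SyntheticScenario) -> GeneNetwork:
    """Scale-free background plus the densified planted module."""
    rng = substream(scn.seed, "network")
    g = nx.barabasi_albert_graph(scn.n_genes, scn.attachment, seed=int(rng.integers(2**31)))
    # decouple module membership from preferential-attachment age
    perm = rng.permutation(scn.n_genes)
    mapping = {i: scn.symbols[perm[i]] for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    module = scn.module_genes()
    erng = substream(scn.seed, "module_edges")
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if erng.random() < scn.module_p:
                g.add_edge(a, b)
    g.remove_edges_from(nx.selfloop_edges(g))
    return GeneNetwork(g)


def make_gene_sets(
    scn: SyntheticScenario, net: GeneNetwork
) -> tuple[GeneSet, GeneSet, pd.DataFrame]:
    """KnownSet (random module subset), GOSet (purity-weighted module/background
    mixture) and the truth table of module membership."""
    module = scn.module_genes()
    background = sorted(set(scn.symbols) - set(module))
    rng = substream(scn.seed, "gene_sets")
    known = GeneSet("KnownSet", rng.choice(module, size=scn.known_size, replace=False))
    n_mod = round(scn.goset_purity * scn.goset_size)
    goset_genes = list(rng.choice(module, size=n_mod, replace=False)) + list(
        rng.choice(background, size=scn.goset_size - n_mod, replace=False)
    )
    goset = GeneSet("GOSet", goset_genes)
    truth = pd.DataFrame(
        {"gene": scn.symbols, "is_module": [g in set(module) for g in scn.symbols]}
    )
    return known, goset, truth


def make_annotations(
    scn: SyntheticScenario, net: GeneNetwork, truth: pd.DataFrame
) -> pd.DataFrame:
    """GO annotations with planted terms enriched in the module.

    The first ``n_planted_terms`` terms annotate module genes at
    ``module_annotation_rate`` and background genes at
    ``background_annotation_rate``; remaining terms annotate uniformly at the
    background rate.
    """
    if scn.n_terms < 1:
        raise ValueError("need at least one term")
    rng = substream(scn.seed, "annotations")
    module = set(truth.loc[truth["is_module"], "gene"])
    terms = [f"GO:{i + 1:07d}" for i in range(scn.n_terms)]
    records = []
    for t_idx, term in enumerate(terms):
        planted = t_idx < scn.n_planted_terms
        for gene in scn.symbols:
            rate = (
                scn.module_annotation_rate
                if planted and gene in module
                else scn.background_annotation_rate
            )
            if rng.random() < rate:
                records.append((gene, term, "IEA", "P"))
    return pd.DataFrame(records, columns=["gene", "term", "evidence", "aspect"])


def planted_terms(scn: SyntheticScenario) -> list[str]:
    return [f"GO:{i + 1:07d}" for i in range(scn.n_planted_terms)]


def make_expression(
    scn: SyntheticScenario, net: GeneNetwork, truth: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Raw expression matrices (pre-preprocessing) with a planted module
    co-expression cluster.

    Module genes load on a shared latent factor: with loading sqrt(rho) and
    residual sd sqrt(1-rho)*noise_sd their pairwise Pearson correlation is
    rho / (rho + (1-rho) * noise_sd**2) — the configured ``within_corr`` at
    noise_sd = 1, decaying to 0 as noise_sd grows. Background genes are
    independent white noise. Duplicate rows (lower mean, so the structured
    profile survives the largest-mean rule), ``null`` cells and off-network
    rows are injected to exercise preprocessing.
    """
    module = list(truth.loc[truth["is_module"], "gene"])
    background = list(truth.loc[~truth["is_module"], "gene"])
    out: dict[str, pd.DataFrame] = {}
    rho = scn.within_corr
    for d in range(scn.n_datasets):
        rng = substream(scn.seed, "expression", d)
        m = scn.samples_per_dataset
        n_bg = max(0, min(scn.genes_per_dataset - len(module), len(background)))
        bg_genes = sorted(rng.choice(background, size=n_bg, replace=False))
        genes = module + bg_genes
        factor = rng.normal(size=m)
        x = np.empty((len(genes), m))
        n_mod = len(module)
        eps = rng.normal(size=(len(genes), m))
        x[:n_mod] = math.sqrt(rho) * factor + math.sqrt(1 - rho) * scn.noise_sd * eps[:n_mod]
        x[n_mod:] = eps[n_mod:]
        df = pd.DataFrame(
            x, index=pd.Index(genes, name="gene"),
            columns=[f"s{j + 1:02d}" for j in range(m)],
        )
        # duplicate decoy rows with strictly lower means
        n_dup = round(scn.duplicate_frac * len(genes))
        if n_dup:
            dup_genes = rng.choice(genes, size=n_dup, replace=False)
            dup = df.loc[dup_genes] - 2.0
            df = pd.concat([df, dup])
        # null cells on background rows only
        n_null = round(scn.null_frac * len(genes))
        if n_null and bg_genes:
            null_genes = rng.choice(bg_genes, size=min(n_null, len(bg_genes)), replace=False)
            for g in null_genes:
                df.loc[g, df.columns[int(rng.integers(m))]] = np.nan
        for i in range(scn.n_offnetwork_genes):
            df.loc[f"x{i + 1:04d}"] = rng.normal(size=m)
        out[f"sim{d + 1:02d}"] = df
    return out


def write_scenario(data: SyntheticData, outdir: str | Path) -> None:
    """Write every artifact in the dialects the readers consume: edges.tsv,
    known.txt, goset.gmt, annotations.gaf, expr_*.tsv, truth.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w") as fh:
        fh.write("# synthetic PPI edge list\n")
        for a, b in sorted(tuple(sorted(e)) for e in data.net.graph.edges):
            fh.write(f"{a}\t{b}\n")
    write_gene_list(data.known.members, out / "known.txt")
    write_gmt([data.goset], out / "goset.gmt")
    with open(out / "annotations.gaf", "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for rec in data.annotations.itertuples(index=False):
            cols = ["SYN", rec.gene, rec.gene, "", rec.term, "SYN:0000000",
                    rec.evidence, "", rec.aspect, "", "", "gene_product",
                    "taxon:9606", "20130303", "netprio", "", ""]
            fh.write("\t".join(cols) + "\n")
    for ds_id, df in data.raw_expression.items():
        df.to_csv(out / f"expr_{ds_id}.tsv", sep="\t", na_rep="null")
    data.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
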