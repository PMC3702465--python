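"""Packaged reference gene lists."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import GeneSet

__all__ = ["load_known_breast_cancer_genes", "load_hallmark_terms"]


def _data_path(name: str):
    return resources.files("netprio").joinpath("data", name)


def load_known_breast_cancer_genes(
    *, sources: tuple[str, ...] | None = None, include_unusable: bool = False
) -> GeneSet:
    """The curated breast-cancer gene list (OMIM + Cancer Gene Census).

    By default returns the 37 usable symbols (the KnownSet); restrict to
    ``sources=("omim",)`` or ``("cgc",)`` for the component sets.
    """
    with resources.as_file(_data_path("known_breast_cancer_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#",
                         names=["symbol", "ncbi_id", "sources", "usable"])
    if not include_unusable:
        df = df[df["usable"] == 1]
    if sources is not None:
        wanted = set(sources)
        df = df[df["sources"].str.split(",").apply(lambda s: bool(wanted & set(s)))]
    name = "KnownSet" if sources is None else "+".join(sorted(sources)) + "Set"
    return GeneSet(name, df["symbol"])


def load_hallmark_terms() -> list[str]:
    """The editable default list of cancer-hallmark GO BP terms."""
    with resources.as_file(_data_path("hallmark_go_terms.txt")) as p:
        return [
            line.strip()
            for line in p.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
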