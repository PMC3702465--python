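"""Readers and writers for the plain-text formats the toolkit consumes.

Edge lists, alias maps and gene lists are simple TSV/line formats; gene sets
travel as GMT; GO annotations as GAF 2.x. Minimal readers for PSI-MITAB 2.5
interaction records and SOFT GDS expression dumps are included for
convenience — both extract just the columns the pipeline needs.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .network import GeneSet

__all__ = [
    "read_edge_list",
    "read_mitab",
    "read_alias_map",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_term_list",
    "read_gaf",
    "read_expression_matrix",
    "read_soft_gds",
    "read_config",
]

GO_ID = re.compile(r"^GO:\d{7}$")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Two-column TSV of interacting gene symbols; ``#`` lines are comments."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"edge line needs two columns: {line!r}")
        rows.append((parts[0], parts[1]))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


_MITAB_GENE = re.compile(r"[^|]*:([^|()]+)\(gene name\)")


def read_mitab(path: str | Path) -> pd.DataFrame:
    """Extract gene-symbol pairs from a PSI-MITAB 2.5 file.

    Uses the alias columns (5, 6), taking each interactor's first
    ``(gene name)``-tagged alias; records without one are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            continue
        a = _MITAB_GENE.search(cols[4])
        b = _MITAB_GENE.search(cols[5])
        if a and b:
            rows.append((a.group(1), b.group(1)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def read_alias_map(path: str | Path) -> dict[str, str]:
    """TSV ``alias<TAB>symbol``."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, symbol = line.rstrip("\n").split("\t")[:2]
        out[alias] = symbol
    return out


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line; ``#`` lines are comments."""
    genes = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet(name or Path(path).stem, genes)


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs >=3 columns: {line!r}")
        sets[parts[0]] = GeneSet(parts[0], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets, path: str | Path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, "netprio", *sorted(s.members)]))
    Path(path).write_text("".join(f"{x}\n" for x in lines))


def read_term_list(path: str | Path) -> list[str]:
    """Plain-text list of GO ids, one per line."""
    terms = []
    for line in Path(path).read_text().splitlines():
        t = line.strip()
        if not t or t.startswith("#"):
            continue
        if not GO_ID.match(t):
            raise ValueError(f"not a GO id: {t!r}")
        terms.append(t)
    return terms


def read_gaf(path: str | Path) -> pd.DataFrame:
    """GAF 2.1/2.2 reader keeping symbol, GO id, evidence code and aspect.

    Comment lines start with ``!``. Columns (1-based): 3 = DB object symbol,
    5 = GO id, 7 = evidence code, 9 = aspect. Duplicate (gene, term) pairs
    are collapsed.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            raise ValueError(f"GAF line has {len(cols)} columns, need >=9")
        term = cols[4]
        if not GO_ID.match(term):
            raise ValueError(f"invalid GO id in GAF: {term!r}")
        rows.append((cols[2], term, cols[6], cols[8]))
    df = pd.DataFrame(rows, columns=["gene", "term", "evidence", "aspect"])
    return df.drop_duplicates(subset=["gene", "term"]).reset_index(drop=True)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV; first column = gene symbol, header = sample ids.

    Literal ``null`` (any case) and empty cells become NaN. Duplicate gene
    rows are preserved (resolved later during preprocessing).
    """
    return pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["null", "NULL", "Null", ""],
        keep_default_na=True,
    )


def read_soft_gds(path: str | Path) -> pd.DataFrame:
    """Minimal SOFT GDS reader: the table between ``!dataset_table_begin`` and
    ``!dataset_table_end``, indexed by the IDENTIFIER column with GSM* value
    columns coerced to float (unparseable cells become NaN)."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!dataset_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!dataset_table_end"))
    except StopIteration as exc:
        raise ValueError("no dataset table found in SOFT file") from exc
    header = lines[start + 1].split("\t")
    if "IDENTIFIER" not in header:
        raise ValueError("SOFT table lacks an IDENTIFIER column")
    rows = [l.split("\t") for l in lines[start + 2 : end] if l.strip()]
    df = pd.DataFrame(rows, columns=header)
    sample_cols = [c for c in header if c.startswith("GSM")]
    out = df.set_index("IDENTIFIER")[sample_cols].apply(pd.to_numeric, errors="coerce")
    out.index.name = "gene"
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """key=value configuration file mirroring the CLI flags."""
    cfg = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line is not key=value: {line!r}")
        k, v = line.split("=", 1)
        cfg[k.strip()] = v.strip()
    return cfg
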