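"""Fusion of the network and expression scores into the final ranking.

The final score of gene v is the convex combination

    S(v) = (1 - lam) * S_N(v) + lam * S_E(v),        0 <= lam <= 1,

with lower S meaning more disease-like. Genes are assigned ordinal positions
(1 = best, ties averaged). The tuning criterion for lam is the P-score: the
mean final position of the seed genes that land in the top 10% of the list
(smaller = better; absent when no seed makes the cut).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import GeneSet

__all__ = ["IntegratedRanking", "combine", "p_score", "tune_lambda"]


@dataclasses.dataclass
class IntegratedRanking:
    """Fused per-gene scores and final ordinal positions.

    ``table`` is indexed by gene with columns S_N, S_E, S, position and is
    sorted ascending by position.
    """

    lam: float
    table: pd.DataFrame

    @property
    def positions(self) -> pd.Series:
        return self.table["position"]

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])


def combine(s_n: pd.Series, s_e: pd.Series, lam: float = 0.2) -> IntegratedRanking:
    """Fuse S_N and S_E with weight ``lam`` on the expression side.

    lam = 0 reproduces the pure network ordering, lam = 1 the pure
    expression ordering. Both score maps must cover the same genes.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if set(s_n.index) != set(s_e.index):
        raise ValueError("S_N and S_E must cover the same gene universe")
    s_e = s_e.reindex(s_n.index)
    s = (1.0 - lam) * s_n + lam * s_e
    position = pd.Series(rankdata(s.to_numpy(), method="average"), index=s.index)
    table = pd.DataFrame({"S_N": s_n, "S_E": s_e, "S": s, "position": position})
    table = table.sort_values(["position", "S"], kind="stable")
    table.index.name = "gene"
    return IntegratedRanking(lam, table)


def p_score(ranking: IntegratedRanking, seeds: GeneSet) -> float | None:
    """Mean final position of seed genes inside the top 10% (cutoff =
    floor(0.1 N)); ``None`` when no seed gene qualifies."""
    if ranking.n_genes == 0:
        raise ValueError("empty ranking")
    cutoff = math.floor(0.1 * ranking.n_genes)
    pos = ranking.positions
    hits = pos[pos.index.isin(seeds.members) & (pos <= cutoff)]
    if hits.empty:
        return None
    return float(hits.mean())


def tune_lambda(
    s_n: pd.Series,
    s_e: pd.Series,
    seeds: GeneSet,
    grid: Sequence[float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Sweep lam over ``grid`` (default 0, 0.1, ..., 1) and pick the value
    minimizing the P-score (smallest lam wins ties).

    Returns (best lam, curve) where curve has columns lam, p_score
    (NaN where undefined).
    """
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 11), 10)
    rows = []
    for lam in grid:
        ps = p_score(combine(s_n, s_e, float(lam)), seeds)
        rows.append((float(lam), np.nan if ps is None else ps))
    curve = pd.DataFrame(rows, columns=["lam", "p_score"])
    if curve["p_score"].isna().all():
        raise ValueError("P-score undefined for every lambda on the grid")
    best = float(curve.loc[curve["p_score"].idxmin(), "lam"])
    return best, curve
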