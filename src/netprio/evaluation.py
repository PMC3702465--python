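"""Noise-robustness evaluation protocols.

Two experiments quantify how gracefully a prioritization method degrades as
its seed set is contaminated:

* **GOSet noise + stratified five-fold cross-validation.** Noise genes are
  drawn from the GO-enriched gene set (realistic, partially informative
  noise) in multiples of the known-set size. Known and noise genes are each
  split into five near-equal parts; each fold trains on 4/5 of both and is
  scored on the held-out pool by Precision/Recall/F at a ranking threshold k.
* **Completely random noise.** Random network genes are added to the seed set
  and the fraction of them that lands in the top 10% of the final ranking is
  reported — a method that promotes whatever it is fed scores high here.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from ._rng import substream, substream_seed
from .network import GeneSet
from .pipeline import GenePrioritizer
from .rwr import rank_by_rwr, rwr

__all__ = [
    "Fold",
    "sample_noise",
    "stratified_folds",
    "f_score",
    "run_noise_benchmark",
    "random_noise_experiment",
]


@dataclasses.dataclass(frozen=True)
class Fold:
    """One cross-validation fold: a noisy training seed set and held-out
    known/noise genes (the test pool)."""

    index: int
    train: GeneSet
    test_known: GeneSet
    test_noise: GeneSet

    @property
    def test_pool(self) -> set[str]:
        return set(self.test_known.members) | set(self.test_noise.members)


def sample_noise(
    goset: GeneSet,
    known: GeneSet,
    ratio: int,
    rng: np.random.Generator | int = 0,
) -> GeneSet:
    """Draw ``ratio * |known|`` noise genes uniformly without replacement from
    the GOSet excluding known genes; ratio 0 means no noise."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    pool = sorted(goset.members - known.members)
    need = ratio * len(known)
    if need > len(pool):
        raise ValueError(
            f"GOSet too small: need {need} noise genes, only {len(pool)} available"
        )
    picked = rng.choice(pool, size=need, replace=False) if need else []
    return GeneSet(f"noise_x{ratio}", picked)


def stratified_folds(
    known: GeneSet,
    noise: GeneSet,
    n_folds: int = 5,
    rng: np.random.Generator | int = 0,
) -> list[Fold]:
    """Split known and noise genes separately into ``n_folds`` near-equal
    parts (sizes differ by at most 1). Fold i trains on everything except the
    i-th parts and is tested on the i-th part of each."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if len(known) < n_folds:
        raise ValueError("known set smaller than the number of folds")
    known_order = rng.permutation(sorted(known.members))
    noise_order = rng.permutation(sorted(noise.members)) if len(noise) else np.array([], dtype=object)
    known_parts = np.array_split(known_order, n_folds)
    noise_parts = np.array_split(noise_order, n_folds)
    all_genes = set(known.members) | set(noise.members)
    folds = []
    for i in range(n_folds):
        test_known = set(known_parts[i])
        test_noise = set(noise_parts[i])
        train = all_genes - test_known - test_noise
        folds.append(
            Fold(
                i,
                GeneSet(f"train_f{i}", train),
                GeneSet(f"test_known_f{i}", test_known),
                GeneSet(f"test_noise_f{i}", test_noise),
            )
        )
    return folds


def f_score(
    positions: pd.Series,
    test_known: GeneSet,
    k: int,
) -> tuple[float, float, float]:
    """Precision, recall and F at ranking threshold ``k``.

    ``positions`` holds the (global) ranking positions of the evaluated
    genes; B = those with position <= k, A = the held-out known genes.
    Precision = |A∩B|/|B| (0 when B is empty), Recall = |A∩B|/|A|, and F is
    their harmonic mean with the 0/0 -> 0 convention.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b = set(positions.index[positions <= k])
    a = set(test_known.members)
    hit = len(a & b)
    precision = hit / len(b) if b else 0.0
    recall = hit / len(a) if a else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def _method_positions(
    method: str,
    prioritizer: GenePrioritizer,
    seeds: GeneSet,
    *,
    goset: GeneSet | None,
    lam: float | None,
    overlap_seed: int | None,
) -> pd.Series:
    if method == "proposed":
        ranking = prioritizer.rank(seeds, goset=goset, lam=lam, overlap_seed=overlap_seed)
        return ranking.positions
    if method == "rwr":
        return rank_by_rwr(rwr(prioritizer.net, seeds))
    raise ValueError(f"unknown method {method!r}")


def run_noise_benchmark(
    prioritizer: GenePrioritizer,
    known: GeneSet,
    goset: GeneSet,
    *,
    methods: Sequence[str] = ("proposed", "rwr"),
    ratios: Sequence[int] = tuple(range(0, 51, 5)),
    k_values: Sequence[int] = (300, 400),
    n_folds: int = 5,
    lam: float | None = None,
    rebuild_goset: bool = True,
    global_topk: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-fold cross-validated F-scores for each (method, noise ratio, k).

    Per fold the method ranks every network gene from the noisy training seed
    set; precision/recall are computed over the held-out pool (known + noise
    genes of the fold) against the global top-k cutoff, or against the whole
    genome's top k with ``global_topk=True``. With ``rebuild_goset`` the
    proposed method re-derives its GOSet from the training seeds only, so
    held-out genes never leak into the expression-overlap reference.

    Returns a tidy frame: method, ratio, k, fold, precision, recall, f_score.
    """
    rows = []
    for ratio in ratios:
        noise = sample_noise(goset, known, ratio, substream(seed, "noise", ratio))
        folds = stratified_folds(known, noise, n_folds, substream(seed, "folds", ratio))
        for fold in folds:
            for method in methods:
                positions = _method_positions(
                    method,
                    prioritizer,
                    fold.train,
                    goset=None if (rebuild_goset or method != "proposed") else goset,
                    lam=lam,
                    overlap_seed=substream_seed(seed, "overlap", method, ratio, fold.index),
                )
                eval_pos = positions if global_topk else positions[positions.index.isin(fold.test_pool)]
                for k in k_values:
                    prec, rec, f = f_score(eval_pos, fold.test_known, k)
                    rows.append((method, ratio, k, fold.index, prec, rec, f))
    return pd.DataFrame(
        rows, columns=["method", "ratio", "k", "fold", "precision", "recall", "f_score"]
    )


def random_noise_experiment(
    prioritizer: GenePrioritizer,
    known: GeneSet,
    ratios: Sequence[int],
    *,
    methods: Sequence[str] = ("proposed", "rwr"),
    lam: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Add completely random network genes to the seed set and report the
    proportion of them that each method ranks inside the top 10%.

    Ratio 0 adds nothing and is reported with an absent (NaN) proportion.
    Returns a tidy frame: method, ratio, n_added, proportion_top10.
    """
    net = prioritizer.net
    background = sorted(net.nodes - known.members)
    cutoff = math.floor(0.1 * net.n_nodes)
    rows = []
    for ratio in ratios:
        need = ratio * len(known)
        if need > len(background):
            raise ValueError(f"not enough non-seed genes for ratio {ratio}")
        rng = substream(seed, "random_noise", ratio)
        added = list(rng.choice(background, size=need, replace=False)) if need else []
        seeds_aug = GeneSet(f"known+random_x{ratio}", set(known.members) | set(added))
        for method in methods:
            if not added:
                rows.append((method, ratio, 0, np.nan))
                continue
            positions = _method_positions(
                method,
                prioritizer,
                seeds_aug,
                goset=None,
                lam=lam,
                overlap_seed=substream_seed(seed, "rand_overlap", method, ratio),
            )
            prop = float((positions.loc[added] <= cutoff).mean())
            rows.append((method, ratio, len(added), prop))
    return pd.DataFrame(rows, columns=["method", "ratio", "n_added", "proportion_top10"])
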