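"""Random walk with restart (RWR): the diffusion baseline.

A walker starts uniformly on the seed genes and at each step either restarts
(probability r) or moves to a uniformly chosen neighbour:

    p^{t+1} = (1 - r) W p^t + r p^0,

with W the column-normalized adjacency matrix. The fixed point
p = r (I - (1-r) W)^{-1} p^0 ranks genes by steady-state visiting
probability (higher = closer to the seed neighbourhood). Column
normalization is required for convergence; columns of isolated genes are
left zero (their mass is re-injected through the restart term).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .network import GeneNetwork, GeneSet

__all__ = ["restart_vector", "transition_matrix", "rwr", "rank_by_rwr"]


def restart_vector(net: GeneNetwork, seeds: GeneSet) -> pd.Series:
    """Initial probability p^0: 1/|seeds in network| on each seed, 0 elsewhere."""
    nodes = net.node_list
    present = sorted(seeds.members & net.nodes)
    if not present:
        raise ValueError("no seed gene is present in the network")
    p0 = pd.Series(0.0, index=nodes, name="p0")
    p0.loc[present] = 1.0 / len(present)
    return p0


def transition_matrix(net: GeneNetwork) -> sp.csr_array:
    """Column-normalized adjacency over ``net.node_list`` order."""
    a = nx.to_scipy_sparse_array(net.graph, nodelist=net.node_list, format="csc", dtype=float)
    colsum = np.asarray(a.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return (a @ sp.diags_array(inv)).tocsr()


def rwr(
    net: GeneNetwork,
    seeds: GeneSet,
    r: float = 0.7,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """Iterate the restart recursion to its steady state.

    Stops when the L1 change between iterates drops below ``tol``; raises if
    ``max_iter`` is exhausted (reporting the residual). r = 1 returns p^0.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError(f"restart probability must lie in (0, 1], got {r}")
    p0 = restart_vector(net, seeds)
    w = transition_matrix(net)
    p = p0.to_numpy().copy()
    p0v = p0.to_numpy()
    for _ in range(max_iter):
        p_next = (1.0 - r) * (w @ p) + r * p0v
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            return pd.Series(p, index=net.node_list, name="probability")
    raise RuntimeError(f"RWR did not converge in {max_iter} iterations (residual {delta:.3e})")


def rank_by_rwr(probabilities: pd.Series) -> pd.Series:
    """Ranks from steady-state probabilities: rank 1 = highest probability,
    ties averaged (zero-probability genes share the worst ranks)."""
    return pd.Series(
        rankdata(-probabilities.to_numpy(), method="average"),
        index=probabilities.index,
        name="rank",
    )
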