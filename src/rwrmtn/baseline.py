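"""RWRMDA baseline: restart walks on a homogeneous miRNA similarity network.

The comparison method projects the bipartite miRNA-target network onto
miRNA-miRNA similarities — the weight of a pair is the number of target
genes they share (or the Jaccard index of their target sets) — and runs the
same restart walk with miRNA-only seeding.  miRNAs sharing no target with
anyone are isolated; they keep stationary score 0 and rank last, so the
two methods rank the same candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import sparse

from .network import MirnaTargetNetwork, _norm
from .propagation import (
    RankingResult,
    TransitionMatrix,
    initial_vector_mirna_only,
    propagate,
    rank_candidates,
)

__all__ = ["MirnaSimilarityNetwork", "build_similarity_network", "rank_rwrmda",
           "write_similarity_network"]


@dataclass(frozen=True)
class MirnaSimilarityNetwork:
    """Symmetric shared-target similarity among miRNAs (zero diagonal)."""

    mirna_ids: tuple[str, ...]
    weights: sparse.csr_array  # square, symmetric, zero diagonal
    measure: str = "shared_count"

    @cached_property
    def mirna_index(self) -> dict[str, int]:
        return {_norm(m): i for i, m in enumerate(self.mirna_ids)}

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=0)).ravel()

    def weight(self, a: str, b: str) -> float:
        i, j = self.mirna_index[_norm(a)], self.mirna_index[_norm(b)]
        return float(self.weights[i, j])

    def pairs(self) -> list[tuple[str, str, float]]:
        """Unordered similar pairs (a < b) with their weights."""
        coo = sparse.triu(sparse.csr_matrix(self.weights), k=1).tocoo()
        out = [
            (self.mirna_ids[i], self.mirna_ids[j], float(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]
        out.sort(key=lambda t: (_norm(t[0]), _norm(t[1])))
        return out


def build_similarity_network(
    net: MirnaTargetNetwork, measure: str = "shared_count"
) -> MirnaSimilarityNetwork:
    """Project the bipartite network onto miRNA-miRNA shared-target weights.

    measure="shared_count": |targets(i) & targets(j)|;
    measure="jaccard": |&| / ||, both zero (edge absent) when the
    intersection is empty.
    """
    if measure not in ("shared_count", "jaccard"):
        raise ValueError(f"unknown similarity measure: {measure!r}")
    n_m = net.n_mirnas
    rows, cols = [], []
    for m, g in net.edges:
        rows.append(net.mirna_index[_norm(m)])
        cols.append(net.gene_index[_norm(g)] - n_m)
    b = sparse.coo_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n_m, net.n_genes)
    ).tocsr()
    shared = (b @ b.T).tocoo()
    mask = shared.row != shared.col
    r, c, v = shared.row[mask], shared.col[mask], shared.data[mask]
    if measure == "jaccard":
        n_targets = np.asarray(b.sum(axis=1)).ravel()
        v = v / (n_targets[r] + n_targets[c] - v)
    w = sparse.coo_array((v, (r, c)), shape=(n_m, n_m)).tocsr()
    return MirnaSimilarityNetwork(net.mirna_ids, w, measure)


def rank_rwrmda(
    simnet: MirnaSimilarityNetwork,
    seed_mirnas,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> RankingResult:
    """Restart walk with miRNA-only seeding on the similarity network.

    The weighted adjacency is column-normalized over the non-isolated
    miRNAs; isolated miRNAs receive score 0 and are ranked last (ties by
    id).  Raises if no seed has a similarity neighbour.
    """
    seed_keys = {_norm(m) for m in seed_mirnas}
    present = [k for k in seed_keys if k in simnet.mirna_index]
    if not present:
        raise ValueError("no seed miRNA in similarity network")
    connected = simnet.degrees > 0
    live_seeds = [k for k in present if connected[simnet.mirna_index[k]]]
    if not live_seeds:
        raise ValueError(
            "all seed miRNAs are isolated in the similarity network"
        )
    # transition matrix over the non-isolated subgraph only
    idx = np.flatnonzero(connected)
    sub = simnet.weights[idx][:, idx].tocsc()
    colsum = np.asarray(sub.sum(axis=0)).ravel()
    w = (sub @ sparse.diags_array(1.0 / colsum)).tocsc()
    sub_ids = tuple(simnet.mirna_ids[i] for i in idx)
    tm = TransitionMatrix(matrix=w, node_order=sub_ids, n_mirnas=len(sub_ids))

    sub_net = _SubOrder(sub_ids)
    p0 = initial_vector_mirna_only(sub_net, live_seeds)
    p_inf, n_iter, _ = propagate(tm, p0, gamma=gamma, tol=tol, max_iter=max_iter)

    # lift scores back to the full miRNA set; isolated miRNAs score 0
    full = np.zeros(len(simnet.mirna_ids))
    full[idx] = p_inf
    ranking = rank_candidates(
        _pad_to_nodes(full),
        _FullOrder(simnet.mirna_ids),
        seed_mirnas=sorted(seed_keys),
        params={"gamma": gamma, "tol": tol, "max_iter": max_iter,
                "measure": simnet.measure, "n_iter": n_iter},
        method="rwrmda",
    )
    return ranking


class _SubOrder:
    """Minimal node-order adapter so seeding/propagation code can be reused."""

    def __init__(self, mirna_ids: tuple[str, ...]):
        self.mirna_ids = mirna_ids
        self.gene_ids: tuple[str, ...] = ()
        self.mirna_index = {_norm(m): i for i, m in enumerate(mirna_ids)}
        self.gene_index: dict[str, int] = {}
        self.n_mirnas = len(mirna_ids)
        self.n_nodes = len(mirna_ids)


class _FullOrder(_SubOrder):
    pass


def _pad_to_nodes(scores: np.ndarray) -> np.ndarray:
    # rank_candidates checks the vector is a (sub-)distribution; scores of a
    # restart walk already sum to 1 over the full miRNA set here
    return scores


def write_similarity_network(simnet: MirnaSimilarityNetwork, path) -> None:
    """Three-column TSV: mirna_a, mirna_b, weight."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_a\tmirna_b\tweight\n")
        for a, b, w in simnet.pairs():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
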