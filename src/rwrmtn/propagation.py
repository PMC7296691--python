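"""Random walk with restart on the heterogeneous miRNA-target network.

The walker update is

    p_{t+1} = (1 - gamma) W' p_t + gamma p_0

where W' is the column-stochastic transition matrix of the network, gamma
is the restart probability and p_0 the initial (seed) distribution.
Iteration stops when the L1 residual ||p_{t+1} - p_t||_1 drops below a
tolerance (1e-6 by default).  Candidate miRNAs are ranked by their
stationary probability.

Two seeding schemes are provided:

* miRNA-only seeding: uniform mass 1/|S_m| on the known disease miRNAs
  (the classical homogeneous-network scheme).
* heterogeneous seeding: mass alpha/|S_m| on each seed miRNA and
  (1 - alpha)/|S_g| on each of their target genes, alpha in (0, 1).
  As alpha -> 1 this reduces to miRNA-only seeding.

W' is built from the symmetric, unweighted bipartite adjacency, column-
normalized by degree: mutual regulation between a miRNA and its targets is
modelled as an undirected edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import sparse

from .network import MirnaTargetNetwork, SeedSet, _norm

__all__ = [
    "TransitionMatrix",
    "RwrParams",
    "RankingResult",
    "RankedMirna",
    "PropagationResult",
    "build_transition_matrix",
    "initial_vector_heterogeneous",
    "initial_vector_mirna_only",
    "propagate",
    "stationary_direct",
    "rank_candidates",
    "write_ranking",
]

_COLSUM_TOL = 1e-12       # column-stochasticity check
_DENSE_SOLVE_LIMIT = 2000  # stationary_direct densifies; guard its size


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix aligned with a node ordering."""

    matrix: sparse.csc_array
    node_order: tuple[str, ...]
    n_mirnas: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)


@dataclass(frozen=True)
class RwrParams:
    """Random-walk parameters.

    gamma: restart probability in (0, 1]; default 0.5.
    alpha: seed-weight between miRNA and gene seeds, in (0, 1); default 0.5.
    tol: L1 convergence threshold; default 1e-6.
    max_iter: iteration cap; the contraction bound guarantees convergence
        in well under 1000 steps for gamma >= 0.1.
    """

    gamma: float = 0.5
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class RankedMirna(NamedTuple):
    rank: int
    mirna_id: str
    score: float


@dataclass(frozen=True)
class RankingResult:
    """Ordered candidate miRNAs with stationary scores (seeds excluded)."""

    rows: tuple[RankedMirna, ...]
    seed_mirnas: tuple[str, ...]
    params: dict = field(default_factory=dict)
    method: str = "rwrmtn"
    n_seed_overlap_excluded: int = 0

    def top(self, limit: int) -> tuple[RankedMirna, ...]:
        if limit < 0:
            raise ValueError("limit must be >= 0")
        return self.rows[:limit]


class PropagationResult(NamedTuple):
    p_inf: np.ndarray
    n_iter: int
    residuals: tuple[float, ...]


def build_transition_matrix(net: MirnaTargetNetwork) -> TransitionMatrix:
    """Column-normalized symmetric adjacency of the bipartite network.

    W'[i, j] = A[i, j] / degree(v_j); every column sums to one because
    edge-list-derived networks contain no isolated nodes.
    """
    n_m, n = net.n_mirnas, net.n_nodes
    rows = np.empty(2 * net.n_edges, dtype=np.int64)
    cols = np.empty(2 * net.n_edges, dtype=np.int64)
    for k, (m, g) in enumerate(net.edges):
        i = net.mirna_index[_norm(m)]
        j = net.gene_index[_norm(g)]
        rows[2 * k], cols[2 * k] = i, j
        rows[2 * k + 1], cols[2 * k + 1] = j, i
    data = np.ones(2 * net.n_edges)
    adj = sparse.coo_array((data, (rows, cols)), shape=(n, n)).tocsc()
    degree = adj.sum(axis=0)
    if np.any(degree == 0):  # unreachable for edge-list networks
        raise ValueError("network contains a zero-degree node")
    w = (adj @ sparse.diags_array(1.0 / degree)).tocsc()
    return TransitionMatrix(matrix=w, node_order=net.node_order, n_mirnas=n_m)


def initial_vector_heterogeneous(
    net: MirnaTargetNetwork, seeds: SeedSet, alpha: float
) -> np.ndarray:
    """Two-part seed distribution: alpha on S_m, (1 - alpha) on S_g.

    Each seed miRNA receives alpha/|S_m|, each seed gene (1-alpha)/|S_g|.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if seeds.n_mirnas < 1:
        raise ValueError("seed set has no miRNAs")
    if seeds.n_genes < 1:
        raise ValueError(
            "seed miRNAs have no target genes; use miRNA-only seeding instead"
        )
    p0 = np.zeros(net.n_nodes)
    for m in seeds.mirnas:
        p0[net.mirna_index[_norm(m)]] = alpha / seeds.n_mirnas
    for g in seeds.genes:
        p0[net.gene_index[_norm(g)]] = (1.0 - alpha) / seeds.n_genes
    return p0


def initial_vector_mirna_only(
    net: MirnaTargetNetwork, seed_mirnas: Sequence[str]
) -> np.ndarray:
    """Uniform seed distribution over the known miRNAs only."""
    if not seed_mirnas:
        raise ValueError("seed miRNA list is empty")
    p0 = np.zeros(net.n_nodes)
    for m in seed_mirnas:
        p0[net.mirna_index[_norm(m)]] = 1.0 / len(seed_mirnas)
    return p0


def _check_stochastic(w: sparse.csc_array) -> None:
    colsums = np.asarray(w.sum(axis=0)).ravel()
    if not np.allclose(colsums, 1.0, atol=1e-9):
        raise ValueError("transition matrix is not column-stochastic")


def _check_simplex(p0: np.ndarray, n: int) -> None:
    if p0.shape != (n,):
        raise ValueError("initial vector is not aligned with the node order")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-10:
        raise ValueError("initial vector is not a probability distribution")


def propagate(
    tm: TransitionMatrix,
    p0: np.ndarray,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationResult:
    """Iterate the restart update to the stationary distribution.

    Returns the converged vector, the number of iterations taken and the
    per-step L1 residuals.  Raises if ``max_iter`` is exhausted.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    w = tm.matrix
    _check_stochastic(w)
    _check_simplex(p0, tm.n_nodes)
    p = p0.copy()
    residuals: list[float] = []
    for it in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (w @ p) + gamma * p0
        res = float(np.abs(p_next - p).sum())
        residuals.append(res)
        p = p_next
        if res < tol:
            return PropagationResult(p, it, tuple(residuals))
    raise RuntimeError(
        f"no convergence after {max_iter} iterations "
        f"(last residual {residuals[-1]:.3e})"
    )


def stationary_direct(
    tm: TransitionMatrix, p0: np.ndarray, gamma: float
) -> np.ndarray:
    """Closed-form stationary vector gamma (I - (1-gamma) W')^-1 p0.

    Dense linear solve; intended as an independent cross-check for
    :func:`propagate` on small networks.
    """
    if gamma == 0:
        raise ValueError("gamma = 0 has no restart component; matrix may be singular")
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    n = tm.n_nodes
    if n > _DENSE_SOLVE_LIMIT:
        raise ValueError(f"dense solve limited to {_DENSE_SOLVE_LIMIT} nodes")
    _check_simplex(p0, n)
    a = np.eye(n) - (1.0 - gamma) * tm.matrix.toarray()
    return gamma * np.linalg.solve(a, p0)


def rank_candidates(
    p_inf: np.ndarray,
    net: MirnaTargetNetwork,
    seed_mirnas: Sequence[str],
    candidates: Sequence[str] | None = None,
    params: dict | None = None,
    method: str = "rwrmtn",
) -> RankingResult:
    """Rank candidate miRNAs by stationary probability.

    Without an explicit candidate list, candidates are all network miRNAs
    except the seeds.  With one, only listed-and-present miRNAs are ranked;
    listed seeds are silently excluded (counted in the result).  Ties are
    broken lexicographically by miRNA id; genes never appear.
    """
    _check_simplex(np.maximum(p_inf, 0.0), net.n_nodes)
    seed_keys = {_norm(m) for m in seed_mirnas}
    n_excluded = 0
    if candidates is None:
        pool = [m for m in net.mirna_ids if _norm(m) not in seed_keys]
    else:
        present: dict[str, str] = {}
        for c in candidates:
            key = _norm(c)
            if key in net.mirna_index:
                present.setdefault(key, net.mirna_ids[net.mirna_index[key]])
        if not present:
            raise ValueError("no candidate miRNA is present in the network")
        n_excluded = sum(1 for key in present if key in seed_keys)
        if n_excluded:
            warnings.warn(
                f"{n_excluded} candidate(s) are seed miRNAs and were excluded",
                stacklevel=2,
            )
        pool = [d for k, d in present.items() if k not in seed_keys]
    scored = sorted(
        ((float(p_inf[net.mirna_index[_norm(m)]]), m) for m in pool),
        key=lambda t: (-t[0], _norm(t[1])),
    )
    rows = tuple(
        RankedMirna(rank=i + 1, mirna_id=m, score=s)
        for i, (s, m) in enumerate(scored)
    )
    return RankingResult(
        rows=rows,
        seed_mirnas=tuple(sorted({_norm(m) for m in seed_mirnas})),
        params=dict(params or {}),
        method=method,
        n_seed_overlap_excluded=n_excluded,
    )


def write_ranking(result: RankingResult, path, metadata: dict | None = None) -> None:
    """Write a ranking as TSV with run metadata in comment lines."""
    meta = {**result.params, **(metadata or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {result.method}\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("rank\tmirna\tscore\n")
        for rank, mirna, score in result.rows:
            fh.write(f"{rank}\t{mirna}\t{score:.17g}\n")
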