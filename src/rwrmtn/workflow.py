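"""End-to-end ranking driver shared by the CLI and the REST facade."""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Sequence

from .baseline import build_similarity_network, rank_rwrmda
from .network import AssociationTable, MirnaTargetNetwork, derive_seed_set
from .propagation import (
    RankingResult,
    RwrParams,
    build_transition_matrix,
    initial_vector_heterogeneous,
    propagate,
    rank_candidates,
)

__all__ = ["UnknownDiseaseError", "RunInfo", "rank_for_disease"]


class UnknownDiseaseError(KeyError):
    """Disease id absent from the association table; carries suggestions."""

    def __init__(self, disease_id: str, suggestions: list[str]):
        self.disease_id = disease_id
        self.suggestions = suggestions
        hint = f"; close matches: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown disease id {disease_id!r}{hint}")


@dataclass(frozen=True)
class RunInfo:
    disease_id: str
    disease_name: str
    n_known: int
    n_seed_mirnas: int
    n_seed_genes: int
    dropped: tuple[str, ...]
    n_iter: int


def _resolve_disease(assoc: AssociationTable, disease_id: str) -> tuple[str, str]:
    did = str(disease_id).strip()
    if did in assoc.diseases:
        return did, assoc.diseases[did]
    pool = list(assoc.diseases) + list(assoc.diseases.values())
    suggestions = difflib.get_close_matches(did, pool, n=3, cutoff=0.4)
    raise UnknownDiseaseError(did, suggestions)


def rank_for_disease(
    net: MirnaTargetNetwork,
    assoc: AssociationTable,
    disease_id: str,
    params: RwrParams | None = None,
    candidates: Sequence[str] | None = None,
    method: str = "rwrmtn",
) -> tuple[RankingResult, RunInfo]:
    """Load -> seed -> propagate -> rank for one disease.

    Candidates default to all network miRNAs except the known disease
    miRNAs; an explicit list is intersected with the network.
    """
    params = params or RwrParams()
    did, name = _resolve_disease(assoc, disease_id)
    known = assoc.mirnas_for(did)
    seeds = derive_seed_set(net, known)

    if method == "rwrmda":
        simnet = build_similarity_network(net)
        ranking = rank_rwrmda(
            simnet, seeds.mirnas,
            gamma=params.gamma, tol=params.tol, max_iter=params.max_iter,
        )
        if candidates is not None:
            ranking = _restrict(ranking, candidates, net)
        n_iter = int(ranking.params.get("n_iter", 0))
    elif method == "rwrmtn":
        tm = build_transition_matrix(net)
        p0 = initial_vector_heterogeneous(net, seeds, params.alpha)
        p_inf, n_iter, _ = propagate(
            tm, p0, gamma=params.gamma, tol=params.tol, max_iter=params.max_iter
        )
        ranking = rank_candidates(
            p_inf, net, seeds.mirnas, candidates=candidates,
            params={"alpha": params.alpha, "gamma": params.gamma,
                    "tol": params.tol, "n_iter": n_iter,
                    "disease_id": did, "disease_name": name},
            method="rwrmtn",
        )
    else:
        raise ValueError(f"method must be 'rwrmtn' or 'rwrmda', got {method!r}")

    info = RunInfo(
        disease_id=did,
        disease_name=name,
        n_known=len(known),
        n_seed_mirnas=seeds.n_mirnas,
        n_seed_genes=seeds.n_genes,
        dropped=seeds.dropped,
        n_iter=n_iter,
    )
    return ranking, info


def _restrict(ranking: RankingResult, candidates, net) -> RankingResult:
    from .network import _norm
    from .propagation import RankedMirna, RankingResult as RR

    wanted = {_norm(c) for c in candidates}
    present = {_norm(c) for c in candidates if net.has_mirna(c)}
    if not present:
        raise ValueError("no candidate miRNA is present in the network")
    rows = [r for r in ranking.rows if _norm(r.mirna_id) in wanted]
    rows = tuple(
        RankedMirna(i + 1, r.mirna_id, r.score) for i, r in enumerate(rows)
    )
    return RR(
        rows=rows,
        seed_mirnas=ranking.seed_mirnas,
        params=ranking.params,
        method=ranking.method,
        n_seed_overlap_excluded=len(wanted & set(ranking.seed_mirnas)),
    )
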