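"""Synthetic bipartite networks with a planted disease module.

The generator emulates the modular structure the walk-based method
exploits: a subset of miRNAs and genes form a densely connected disease
module (edge probability ``p_in``), while all other miRNA-gene pairs are
wired sparsely at random (``p_bg``).  Known disease miRNAs are drawn from
the module, so held-out module members should be reachable through shared
module genes.  Every draw is reproducible from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import AssociationTable, MirnaTargetNetwork, write_associations, write_edge_list

__all__ = ["GeneratorConfig", "ModuleTruth", "generate", "write_dataset"]

DISEASE_ID = "SYN1"
DISEASE_NAME = "synthetic planted-module disease"


@dataclass(frozen=True)
class GeneratorConfig:
    """Planted-module generator settings.

    Defaults give a strong but not saturated signal: 12 of 60 miRNAs and
    40 of 200 genes form the module; module pairs are wired with
    probability 0.35 against a 0.02 background, and 8 module miRNAs are
    reported as known disease miRNAs.
    """

    n_mirna: int = 60
    n_gene: int = 200
    n_module_mirna: int = 12
    n_module_gene: int = 40
    p_in: float = 0.35
    p_bg: float = 0.02
    n_known: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_gene) < 1:
            raise ValueError("network dimensions must be positive")
        if not (0 < self.n_module_mirna <= self.n_mirna):
            raise ValueError("n_module_mirna out of range")
        if not (0 < self.n_module_gene <= self.n_gene):
            raise ValueError("n_module_gene out of range")
        if not (0.0 <= self.p_bg <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_bg <= p_in <= 1")
        if not (1 <= self.n_known <= self.n_module_mirna):
            raise ValueError("n_known must be in [1, n_module_mirna]")


@dataclass(frozen=True)
class ModuleTruth:
    """Planted module membership, for truth-based evaluation in tests."""

    module_mirnas: tuple[str, ...]
    module_genes: tuple[str, ...]
    known_mirnas: tuple[str, ...]


def generate(
    config: GeneratorConfig,
) -> tuple[MirnaTargetNetwork, AssociationTable, ModuleTruth]:
    """Draw a planted-module network and its association table.

    Module miRNA x module gene pairs carry edges with ``p_in``, all other
    pairs with ``p_bg``.  Any node left with degree 0 receives one
    uniformly chosen edge (within the module for module nodes), so the
    network never contains isolated nodes.
    """
    rng = np.random.default_rng(config.rng_seed)
    mirnas = np.array([f"mir-{i:03d}" for i in range(config.n_mirna)])
    genes = np.array([f"gene-{i:03d}" for i in range(config.n_gene)])

    mod_m = np.sort(rng.choice(config.n_mirna, config.n_module_mirna, replace=False))
    mod_g = np.sort(rng.choice(config.n_gene, config.n_module_gene, replace=False))
    in_mod_m = np.zeros(config.n_mirna, bool)
    in_mod_m[mod_m] = True
    in_mod_g = np.zeros(config.n_gene, bool)
    in_mod_g[mod_g] = True

    prob = np.full((config.n_mirna, config.n_gene), config.p_bg)
    prob[np.ix_(mod_m, mod_g)] = config.p_in
    adj = rng.random((config.n_mirna, config.n_gene)) < prob

    # degree repair: every node must appear in the edge list
    for i in np.flatnonzero(~adj.any(axis=1)):
        pool = mod_g if in_mod_m[i] else np.arange(config.n_gene)
        adj[i, rng.choice(pool)] = True
    for j in np.flatnonzero(~adj.any(axis=0)):
        pool = mod_m if in_mod_g[j] else np.arange(config.n_mirna)
        adj[rng.choice(pool), j] = True

    rows, cols = np.nonzero(adj)
    net = MirnaTargetNetwork.from_edges(
        (mirnas[i], genes[j]) for i, j in zip(rows, cols)
    )

    known_idx = np.sort(rng.choice(mod_m, config.n_known, replace=False))
    assoc = AssociationTable.from_records(
        (DISEASE_ID, DISEASE_NAME, mirnas[i]) for i in known_idx
    )
    truth = ModuleTruth(
        module_mirnas=tuple(mirnas[mod_m]),
        module_genes=tuple(genes[mod_g]),
        known_mirnas=tuple(mirnas[known_idx]),
    )
    return net, assoc, truth


def write_dataset(
    net: MirnaTargetNetwork,
    assoc: AssociationTable,
    directory: str | Path,
) -> tuple[Path, Path]:
    """Write the standard edge-list and association TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net_path = directory / "network.tsv"
    assoc_path = directory / "associations.tsv"
    write_edge_list(net, net_path)
    write_associations(assoc, assoc_path)
    return net_path, assoc_path
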