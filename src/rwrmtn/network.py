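"""Bipartite miRNA-target network model and disease-miRNA association tables.

The method operates on a heterogeneous network G(V, E) whose nodes are
miRNAs and their target genes, connected by (undirected) targeting
interactions.  Networks are defined purely by an edge list, so every node
has degree >= 1 by construction and every column of the derived transition
matrix is normalizable.

Identifier conventions
----------------------
miRNA and gene identifiers live in disjoint namespaces; an identifier that
appears in both columns of an edge list is rejected.  Matching is
case-insensitive after whitespace trimming ("hsa-miR-506" == "hsa-mir-506"),
because capitalisation conventions differ between public target and
association databases.  The first spelling seen is kept for display.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MirnaTargetNetwork",
    "AssociationTable",
    "SeedSet",
    "load_target_network",
    "load_associations",
    "list_diseases",
    "derive_seed_set",
    "write_edge_list",
    "write_associations",
]

# Column names that mark a first row as a header rather than data.  A first
# row whose miRNA column matches the standard miRBase naming pattern is
# always treated as data.
_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "microrna", "source",
    "gene", "gene_id", "target", "target_gene", "symbol",
    "disease", "disease_id", "disease_name", "omim", "omim_id", "name", "id",
}


def _norm(identifier: str) -> str:
    """Canonical (trimmed, lower-cased) form of an identifier."""
    return str(identifier).strip().lower()


def _looks_like_mirbase(token: str) -> bool:
    t = _norm(token)
    return ("-mir-" in t) or ("-let-" in t) or t.startswith(("mir-", "let-"))


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _read_delimited(path: str | Path, min_cols: int) -> list[list[str]]:
    """Read a TSV/CSV file, auto-detecting the delimiter and an optional header."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: file is empty")
    delimiter = _sniff_delimiter(lines[0])
    rows = [row for row in csv.reader(lines, delimiter=delimiter)]
    first = [c.strip() for c in rows[0]]
    is_header = (
        not _looks_like_mirbase(first[0])
        and any(_norm(c) in _HEADER_TOKENS for c in first)
    )
    if is_header:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    out = []
    for i, row in enumerate(rows, start=2 if is_header else 1):
        cells = [c.strip() for c in row]
        if len(cells) < min_cols or any(not c for c in cells[:min_cols]):
            raise ValueError(
                f"{path}: line {i}: expected at least {min_cols} "
                f"non-empty columns, got {row!r}"
            )
        out.append(cells[:min_cols])
    return out


@dataclass(frozen=True)
class MirnaTargetNetwork:
    """Bipartite miRNA-target gene network.

    Attributes
    ----------
    mirna_ids, gene_ids:
        Display identifiers, sorted lexicographically by canonical form.
    edges:
        Deduplicated (mirna, gene) pairs using display identifiers.
    """

    mirna_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "MirnaTargetNetwork":
        mirna_disp: dict[str, str] = {}
        gene_disp: dict[str, str] = {}
        edge_keys: set[tuple[str, str]] = set()
        for m, g in pairs:
            nm, ng = _norm(m), _norm(g)
            if not nm or not ng:
                raise ValueError("empty identifier in edge list")
            mirna_disp.setdefault(nm, str(m).strip())
            gene_disp.setdefault(ng, str(g).strip())
            edge_keys.add((nm, ng))
        if not edge_keys:
            raise ValueError("edge list is empty")
        clash = sorted(set(mirna_disp) & set(gene_disp))
        if clash:
            raise ValueError(
                "identifier(s) appear as both miRNA and gene "
                f"(disjoint namespaces required): {', '.join(clash)}"
            )
        mirnas = tuple(mirna_disp[k] for k in sorted(mirna_disp))
        genes = tuple(gene_disp[k] for k in sorted(gene_disp))
        edges = frozenset((mirna_disp[a], gene_disp[b]) for a, b in edge_keys)
        return cls(mirnas, genes, edges)

    # -- derived, cached views -------------------------------------------

    @cached_property
    def node_order(self) -> tuple[str, ...]:
        """Canonical node ordering: all miRNAs first, then all genes."""
        return self.mirna_ids + self.gene_ids

    @cached_property
    def mirna_index(self) -> dict[str, int]:
        """Canonical miRNA id -> position in ``node_order``."""
        return {_norm(m): i for i, m in enumerate(self.mirna_ids)}

    @cached_property
    def gene_index(self) -> dict[str, int]:
        """Canonical gene id -> position in ``node_order``."""
        n = len(self.mirna_ids)
        return {_norm(g): n + i for i, g in enumerate(self.gene_ids)}

    @cached_property
    def _targets(self) -> dict[str, tuple[str, ...]]:
        by_mirna: dict[str, list[str]] = {_norm(m): [] for m in self.mirna_ids}
        for m, g in self.edges:
            by_mirna[_norm(m)].append(g)
        return {k: tuple(sorted(v, key=_norm)) for k, v in by_mirna.items()}

    # -- queries ----------------------------------------------------------

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_ids) + len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_mirna(self, mirna_id: str) -> bool:
        return _norm(mirna_id) in self.mirna_index

    def targets_of(self, mirna_id: str) -> tuple[str, ...]:
        """Display ids of the target genes of one miRNA."""
        return self._targets[_norm(mirna_id)]


@dataclass(frozen=True)
class AssociationTable:
    """Known disease-miRNA associations: (disease_id, disease_name, mirna_id)."""

    records: tuple[tuple[str, str, str], ...]

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, str, str]]
    ) -> "AssociationTable":
        names: dict[str, str] = {}
        seen: set[tuple[str, str]] = set()
        records: list[tuple[str, str, str]] = []
        for did, name, mirna in rows:
            did, name = str(did).strip(), str(name).strip()
            prior = names.setdefault(did, name)
            if prior != name:
                raise ValueError(
                    f"disease id {did!r} has conflicting names: "
                    f"{prior!r} and {name!r}"
                )
            key = (did, _norm(mirna))
            if key in seen:
                continue
            seen.add(key)
            records.append((did, name, str(mirna).strip()))
        if not records:
            raise ValueError("association table is empty")
        return cls(tuple(records))

    @cached_property
    def diseases(self) -> dict[str, str]:
        """disease_id -> disease_name, in first-seen order."""
        return {did: name for did, name, _ in self.records}

    def mirnas_for(self, disease_id: str) -> tuple[str, ...]:
        did = str(disease_id).strip()
        return tuple(m for d, _, m in self.records if d == did)


@dataclass(frozen=True)
class SeedSet:
    """Seed nodes S = S_m | S_g: known disease miRNAs plus their targets.

    ``dropped`` records input miRNAs absent from the network.
    """

    mirnas: tuple[str, ...]
    genes: tuple[str, ...]
    dropped: tuple[str, ...]

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def load_target_network(path: str | Path) -> MirnaTargetNetwork:
    """Load a two-column (miRNA, gene) edge list; TSV or CSV, optional header.

    Duplicate rows are collapsed; identifiers are matched case-insensitively.
    """
    rows = _read_delimited(path, min_cols=2)
    return MirnaTargetNetwork.from_edges((m, g) for m, g in rows)


def load_associations(path: str | Path) -> AssociationTable:
    """Load a three-column (disease_id, disease_name, mirna) table."""
    rows = _read_delimited(path, min_cols=3)
    return AssociationTable.from_records((d, n, m) for d, n, m in rows)


def list_diseases(
    assoc: AssociationTable, query: str | None = None
) -> list[tuple[str, str, int]]:
    """All diseases, or those whose name contains ``query`` (case-insensitive).

    Returns (disease_id, disease_name, n_known) sorted by disease id.
    """
    q = (query or "").strip().lower()
    counts: dict[str, int] = {}
    for did, _, _ in assoc.records:
        counts[did] = counts.get(did, 0) + 1
    out = [
        (did, name, counts[did])
        for did, name in assoc.diseases.items()
        if q in name.lower()
    ]
    out.sort(key=lambda t: t[0])
    return out


def derive_seed_set(
    net: MirnaTargetNetwork, known_mirnas: Sequence[str]
) -> SeedSet:
    """Intersect known miRNAs with the network and add their target genes.

    S_m = known & network miRNAs; S_g = union of targets of S_m.
    Raises if no known miRNA is present in the network.
    """
    if not known_mirnas:
        raise ValueError("known miRNA list is empty")
    present: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for m in known_mirnas:
        key = _norm(m)
        if key in net.mirna_index:
            present.setdefault(key, net.mirna_ids[net.mirna_index[key]])
        else:
            dropped.setdefault(key, str(m).strip())
    if not present:
        raise ValueError("no seed miRNA in network")
    genes: dict[str, str] = {}
    for key in present:
        for g in net._targets[key]:
            genes.setdefault(_norm(g), g)
    return SeedSet(
        mirnas=tuple(present[k] for k in sorted(present)),
        genes=tuple(genes[k] for k in sorted(genes)),
        dropped=tuple(dropped[k] for k in sorted(dropped)),
    )


def write_edge_list(
    net: MirnaTargetNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the network back to the two-column edge-list format."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for m, g in sorted(net.edges, key=lambda e: (_norm(e[0]), _norm(e[1]))):
            writer.writerow([m, g])


def write_associations(
    assoc: AssociationTable, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the association table in the three-column format."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for rec in assoc.records:
            writer.writerow(rec)
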