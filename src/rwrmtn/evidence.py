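"""Literature co-occurrence evidence via PubMed.

A candidate miRNA is considered "evidenced" when at least one PubMed
record mentions both the miRNA name and the disease term.  The retrieval
backend is injectable: :class:`PubMedFetcher` queries the live NCBI
E-utilities endpoint, while tests supply an in-memory stub, so the default
test suite never touches the network.  A fetcher is any callable
``fetcher(mirna_id, disease_name) -> iterable of PubMed id strings``.
"""

from __future__ import annotations

import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Sequence

__all__ = ["EvidenceRow", "EvidenceTable", "StubFetcher", "PubMedFetcher",
           "build_query", "search_evidence", "write_evidence_table"]

Fetcher = Callable[[str, str], Iterable[str]]

EUTILS_ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"


def build_query(mirna_id: str, disease_name: str) -> str:
    """Co-occurrence query: both terms anywhere in the record."""
    return f'("{mirna_id}"[All Fields]) AND ("{disease_name}"[All Fields])'


@dataclass(frozen=True)
class EvidenceRow:
    mirna_id: str
    pubmed_ids: tuple[str, ...]
    error: str | None = None

    @property
    def n_hits(self) -> int:
        return len(self.pubmed_ids)


@dataclass(frozen=True)
class EvidenceTable:
    rows: tuple[EvidenceRow, ...]
    disease_name: str
    retrieved_at: str

    @property
    def partial(self) -> bool:
        """True when at least one per-miRNA fetch failed."""
        return any(r.error is not None for r in self.rows)


def search_evidence(
    mirnas: Sequence[str], disease_name: str, fetcher: Fetcher
) -> EvidenceTable:
    """One co-occurrence query per miRNA; zero-hit miRNAs are retained.

    A fetcher failure is recorded on that row only; other rows are
    unaffected and the table is marked partial.
    """
    if not str(disease_name).strip():
        raise ValueError("disease name must be non-empty")
    rows = []
    for m in mirnas:
        try:
            ids = tuple(dict.fromkeys(str(i) for i in fetcher(m, disease_name)))
            rows.append(EvidenceRow(m, ids))
        except Exception as exc:  # noqa: BLE001 - isolate per-row failures
            rows.append(EvidenceRow(m, (), error=str(exc)))
    return EvidenceTable(
        rows=tuple(rows),
        disease_name=str(disease_name),
        retrieved_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


@dataclass
class StubFetcher:
    """Deterministic in-memory fetcher keyed by (mirna_id, disease_name)."""

    mapping: dict[tuple[str, str], Sequence[str]] = field(default_factory=dict)

    def __call__(self, mirna_id: str, disease_name: str) -> list[str]:
        return list(self.mapping.get((mirna_id, disease_name), []))


class PubMedFetcher:
    """Live NCBI E-utilities esearch client (JSON mode).

    Enforces a minimum delay between requests to respect NCBI rate limits;
    excluded from the default test suite.
    """

    def __init__(self, delay: float = 0.34, retmax: int = 100,
                 api_key: str | None = None, timeout: float = 30.0):
        self.delay = delay
        self.retmax = retmax
        self.api_key = api_key
        self.timeout = timeout
        self._last_request = 0.0

    def __call__(self, mirna_id: str, disease_name: str) -> list[str]:
        wait = self.delay - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        params = {
            "db": "pubmed",
            "term": build_query(mirna_id, disease_name),
            "retmode": "json",
            "retmax": str(self.retmax),
        }
        if self.api_key:
            params["api_key"] = self.api_key
        url = f"{EUTILS_ESEARCH}?{urllib.parse.urlencode(params)}"
        self._last_request = time.monotonic()
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            payload = json.loads(resp.read().decode("utf-8"))
        return list(payload["esearchresult"]["idlist"])


def write_evidence_table(table: EvidenceTable, path) -> None:
    """TSV: mirna, n_hits, comma-joined PubMed ids, per-row error if any."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# disease: {table.disease_name}\n")
        fh.write(f"# retrieved_at: {table.retrieved_at}\n")
        if table.partial:
            fh.write("# WARNING: partial results (some fetches failed)\n")
        fh.write("mirna\tn_hits\tpubmed_ids\terror\n")
        for r in table.rows:
            fh.write(
                f"{r.mirna_id}\t{r.n_hits}\t{','.join(r.pubmed_ids)}\t"
                f"{r.error or ''}\n"
            )
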