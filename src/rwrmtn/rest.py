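"""REST facade mirroring the app's four automation endpoints.

    GET  /v1/diseaseList                 all diseases (id, name, n_known)
    GET  /v1/diseaseList/{diseaseName}   case-insensitive name filter
    POST /v1/rank                        run a ranking; body: JSON with
                                         disease_id, alpha, gamma,
                                         candidates (optional), method
    GET  /v1/getRank/{limit}             top rows of the stored ranking

The facade is stateful: POST /v1/rank stores the most recent ranking and
getRank reads it back, mirroring the POST-then-GET automation design.
:class:`RankingService` holds the logic; the HTTP layer is a thin
standard-library server around it, so programmatic and HTTP access share
one code path.
"""

from __future__ import annotations

import json
import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .network import AssociationTable, MirnaTargetNetwork, list_diseases
from .propagation import RankingResult, RwrParams
from .workflow import UnknownDiseaseError, rank_for_disease

__all__ = ["RankingService", "NoRankingError", "serve"]


class NoRankingError(RuntimeError):
    """getRank was called before any ranking was stored (409 semantics)."""


class RankingService:
    """Stateful ranking service over one network + association table."""

    def __init__(self, net: MirnaTargetNetwork, assoc: AssociationTable):
        self.net = net
        self.assoc = assoc
        self._last: RankingResult | None = None
        self._lock = threading.Lock()

    def disease_list(self, query: str | None = None) -> list[dict]:
        return [
            {"disease_id": did, "disease_name": name, "n_known": n}
            for did, name, n in list_diseases(self.assoc, query)
        ]

    def rank(
        self,
        disease_id: str,
        alpha: float = 0.5,
        gamma: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
        candidates=None,
        method: str = "rwrmtn",
    ) -> dict:
        params = RwrParams(gamma=gamma, alpha=alpha, tol=tol, max_iter=max_iter)
        ranking, info = rank_for_disease(
            self.net, self.assoc, disease_id,
            params=params, candidates=candidates, method=method,
        )
        with self._lock:
            self._last = ranking
        return {
            "disease_id": info.disease_id,
            "disease_name": info.disease_name,
            "n_ranked": len(ranking.rows),
            "n_seed_mirnas": info.n_seed_mirnas,
            "n_seed_genes": info.n_seed_genes,
            "n_iter": info.n_iter,
            "method": method,
        }

    def get_rank(self, limit: int) -> list[dict]:
        if limit < 0:
            raise ValueError("limit must be >= 0")
        with self._lock:
            last = self._last
        if last is None:
            raise NoRankingError("no ranking stored; POST /v1/rank first")
        return [
            {"rank": r.rank, "mirna": r.mirna_id, "score": r.score}
            for r in last.top(limit)
        ]


class _Handler(BaseHTTPRequestHandler):
    server_version = "rwrmtn/0.1"

    @property
    def service(self) -> RankingService:
        return self.server.service  # type: ignore[attr-defined]

    def log_message(self, *args):  # quiet by default
        pass

    def _send(self, status: int, payload) -> None:
        body = json.dumps(payload).encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self) -> None:  # noqa: N802 - http.server API
        parts = [p for p in urllib.parse.unquote(self.path).split("/") if p]
        try:
            if parts[:2] == ["v1", "diseaseList"]:
                query = parts[2] if len(parts) > 2 else None
                self._send(200, self.service.disease_list(query))
            elif parts[:2] == ["v1", "getRank"] and len(parts) == 3:
                self._send(200, self.service.get_rank(int(parts[2])))
            else:
                self._send(404, {"error": f"unknown endpoint {self.path}"})
        except NoRankingError as exc:
            self._send(409, {"error": str(exc)})
        except (ValueError, KeyError) as exc:
            self._send(400, {"error": str(exc)})

    def do_POST(self) -> None:  # noqa: N802
        parts = [p for p in urllib.parse.unquote(self.path).split("/") if p]
        if parts != ["v1", "rank"]:
            self._send(404, {"error": f"unknown endpoint {self.path}"})
            return
        try:
            length = int(self.headers.get("Content-Length", 0))
            body = json.loads(self.rfile.read(length) or b"{}")
            summary = self.service.rank(
                disease_id=body["disease_id"],
                alpha=float(body.get("alpha", 0.5)),
                gamma=float(body.get("gamma", 0.5)),
                tol=float(body.get("tol", 1e-6)),
                max_iter=int(body.get("max_iter", 1000)),
                candidates=body.get("candidates"),
                method=body.get("method", "rwrmtn"),
            )
            self._send(200, summary)
        except UnknownDiseaseError as exc:
            self._send(404, {"error": str(exc), "suggestions": exc.suggestions})
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            self._send(400, {"error": str(exc)})


def serve(
    service: RankingService, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Create (but do not start) an HTTP server bound to the service.

    ``port=0`` binds an ephemeral port; call ``serve_forever`` (typically
    in a thread) and read ``server.server_address`` for the bound port.
    """
    server = ThreadingHTTPServer((host, port), _Handler)
    server.service = service  # type: ignore[attr-defined]
    return server
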