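"""CLI workflow, evidence search, result-graph export and the REST facade."""

import json
import threading
import urllib.error
import urllib.request

import networkx as nx
import pytest
from click.testing import CliRunner

from rwrmtn import (
    RankingService,
    StubFetcher,
    build_query,
    build_result_graph,
    export_result_graph,
    rank_for_disease,
    search_evidence,
    serve,
)
from rwrmtn.cli import main
from rwrmtn.network import load_associations, load_target_network

# miRNAs with literature co-occurrence evidence for breast cancer
BREAST_EVIDENCE = {
    ("hsa-miR-506", "breast cancer"): [
        "23717581", "25707493", "26059632", "26398880", "27542202",
    ],
    ("hsa-miR-520d-5p", "breast cancer"): ["28721278"],
}


def read_ranking_rows(path):
    lines = [ln for ln in open(path) if not ln.startswith("#")]
    return lines[1:]  # drop header


class TestCliRank:
    def run(self, *args):
        return CliRunner().invoke(main, list(args), catch_exceptions=False)

    def test_end_to_end_row_count(self, synth_files, synth):
        net_path, assoc_path = synth_files
        net, assoc, _ = synth
        with CliRunner().isolated_filesystem():
            result = self.run(
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--out", "ranking.tsv",
            )
            assert result.exit_code == 0
            rows = read_ranking_rows("ranking.tsv")
            n_seeds = len(assoc.mirnas_for("SYN1"))
            assert len(rows) == net.n_mirnas - n_seeds

    def test_top_limits_rows(self, synth_files):
        net_path, assoc_path = synth_files
        with CliRunner().isolated_filesystem():
            result = self.run(
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--top", "10",
                "--out", "ranking.tsv",
            )
            assert result.exit_code == 0
            assert len(read_ranking_rows("ranking.tsv")) == 10

    def test_candidate_file_restricts_ranking(self, synth_files, synth, tmp_path):
        net_path, assoc_path = synth_files
        net, assoc, _ = synth
        seeds = set(assoc.mirnas_for("SYN1"))
        wanted = [m for m in net.mirna_ids if m not in seeds][:5] + ["not-a-mirna"]
        cand = tmp_path / "candidates.txt"
        cand.write_text("\n".join(wanted))
        with CliRunner().isolated_filesystem():
            result = self.run(
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--candidates",
                str(cand), "--out", "ranking.tsv",
            )
            assert result.exit_code == 0
            rows = read_ranking_rows("ranking.tsv")
            assert len(rows) == 5
            listed = {r.split("\t")[1] for r in rows}
            assert listed == set(wanted[:5])

    def test_unknown_disease_fails_with_suggestion(self, synth_files):
        net_path, assoc_path = synth_files
        runner = CliRunner()
        result = runner.invoke(main, [
            "rank", "--network", str(net_path), "--associations",
            str(assoc_path), "--disease", "SYN", "--out", "x.tsv",
        ])
        assert result.exit_code != 0
        assert "SYN1" in result.output

    def test_config_file_defaults_and_flag_override(self, synth_files, tmp_path):
        net_path, assoc_path = synth_files
        cfg = tmp_path / "config.yaml"
        cfg.write_text("alpha: 0.9\ngamma: 0.3\n")
        with CliRunner().isolated_filesystem():
            r1 = self.run(
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--config", str(cfg),
                "--out", "a.tsv",
            )
            r2 = self.run(
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--config", str(cfg),
                "--alpha", "0.5", "--out", "b.tsv",
            )
            assert r1.exit_code == 0 and r2.exit_code == 0
            meta_a = [ln for ln in open("a.tsv") if ln.startswith("# alpha")]
            meta_b = [ln for ln in open("b.tsv") if ln.startswith("# alpha")]
            assert meta_a == ["# alpha: 0.9\n"]
            assert meta_b == ["# alpha: 0.5\n"]

    def test_diseases_and_simulate_subcommands(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--out-dir", str(out_dir), "--seed", "7",
        ])
        assert result.exit_code == 0
        assert (out_dir / "network.tsv").exists()
        result = runner.invoke(main, [
            "diseases", "--associations", str(out_dir / "associations.tsv"),
            "--query", "planted",
        ])
        assert result.exit_code == 0
        assert "SYN1" in result.output


class TestEvidence:
    def test_query_form(self):
        q = build_query("hsa-miR-506", "breast cancer")
        assert q == '("hsa-miR-506"[All Fields]) AND ("breast cancer"[All Fields])'

    def test_stub_fetcher_rows(self):
        table = search_evidence(
            ["hsa-miR-506", "hsa-miR-520d-5p", "hsa-miR-000"],
            "breast cancer",
            StubFetcher(BREAST_EVIDENCE),
        )
        by_id = {r.mirna_id: r for r in table.rows}
        assert by_id["hsa-miR-506"].n_hits == 5
        assert by_id["hsa-miR-506"].pubmed_ids == (
            "23717581", "25707493", "26059632", "26398880", "27542202",
        )
        assert by_id["hsa-miR-520d-5p"].pubmed_ids == ("28721278",)
        assert by_id["hsa-miR-000"].n_hits == 0
        assert not table.partial

    def test_all_empty_stub(self):
        table = search_evidence(["a", "b"], "breast cancer", StubFetcher())
        assert all(r.n_hits == 0 for r in table.rows)

    def test_fetcher_failure_isolated_per_row(self):
        def flaky(mirna, disease):
            if mirna == "bad":
                raise OSError("connection refused")
            return ["123"]

        table = search_evidence(["ok", "bad"], "breast cancer", flaky)
        assert table.partial
        by_id = {r.mirna_id: r for r in table.rows}
        assert by_id["ok"].pubmed_ids == ("123",)
        assert by_id["bad"].error and by_id["bad"].n_hits == 0

    def test_empty_disease_name_rejected(self):
        with pytest.raises(ValueError):
            search_evidence(["m"], "  ", StubFetcher())


class TestExport:
    def _toy_ranking(self, toy_net, toy_assoc):
        ranking, _ = rank_for_disease(toy_net, toy_assoc, "114480")
        return ranking

    def test_graph_composition(self, toy_net):
        from rwrmtn import AssociationTable

        assoc = AssociationTable.from_records([("D1", "disease one", "m1")])
        ranking, _ = rank_for_disease(toy_net, assoc, "D1")
        g = build_result_graph(ranking, toy_net, assoc, "D1")
        classes = {}
        for _, data in g.nodes(data=True):
            classes[data["node_class"]] = classes.get(data["node_class"], 0) + 1
        assert classes["disease"] == 1
        assert classes["known_mirna"] == 1
        assert classes["candidate_mirna"] == 2
        assert classes.get("pubmed", 0) == 0
        # genes of known + candidates
        assert classes["gene"] == 4

    def test_evidence_nodes_and_edges(self, toy_net, toy_assoc):
        ranking = self._toy_ranking(toy_net, toy_assoc)
        stub = StubFetcher({(ranking.rows[0].mirna_id, "Breast cancer"):
                            ["11", "22", "33", "44", "55"]})
        ev = search_evidence(
            [r.mirna_id for r in ranking.rows], "Breast cancer", stub
        )
        g = build_result_graph(ranking, toy_net, toy_assoc, "114480", ev)
        pubmed = [n for n, d in g.nodes(data=True) if d["node_class"] == "pubmed"]
        ev_edges = [
            (u, v) for u, v, d in g.edges(data=True)
            if d["edge_class"] == "evidence"
        ]
        assert len(pubmed) == 5 and len(ev_edges) == 5

    def test_graphml_round_trip(self, toy_net, toy_assoc, tmp_path):
        ranking = self._toy_ranking(toy_net, toy_assoc)
        paths = export_result_graph(
            ranking, toy_net, toy_assoc, "114480", tmp_path / "graph",
            fmt="graphml",
        )
        g2 = nx.read_graphml(paths[0])
        g1 = build_result_graph(ranking, toy_net, toy_assoc, "114480")
        assert sorted(g1.nodes) == sorted(g2.nodes)
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        attrs1 = sorted(d["node_class"] for _, d in g1.nodes(data=True))
        attrs2 = sorted(d["node_class"] for _, d in g2.nodes(data=True))
        assert attrs1 == attrs2

    def test_sif_line_count_equals_edge_count(self, toy_net, toy_assoc, tmp_path):
        ranking = self._toy_ranking(toy_net, toy_assoc)
        paths = export_result_graph(
            ranking, toy_net, toy_assoc, "114480", tmp_path / "graph", fmt="sif"
        )
        g = build_result_graph(ranking, toy_net, toy_assoc, "114480")
        sif_lines = [ln for ln in open(paths[0]) if ln.strip()]
        assert len(sif_lines) == g.number_of_edges()

    def test_unknown_format_rejected(self, toy_net, toy_assoc, tmp_path):
        ranking = self._toy_ranking(toy_net, toy_assoc)
        with pytest.raises(ValueError, match="format"):
            export_result_graph(
                ranking, toy_net, toy_assoc, "114480", tmp_path / "g", fmt="xgmml"
            )


class TestRestFacade:
    @pytest.fixture
    def service(self, synth):
        net, assoc, _ = synth
        return RankingService(net, assoc)

    def test_disease_list_and_filter(self, service):
        full = service.disease_list()
        assert full == service.disease_list("PLANTED")  # case-insensitive
        assert full[0]["disease_id"] == "SYN1"
        assert service.disease_list("no such disease") == []

    def test_get_rank_before_rank_is_conflict(self, service):
        from rwrmtn import NoRankingError

        with pytest.raises(NoRankingError):
            service.get_rank(5)

    def test_rank_then_get_rank(self, service):
        summary = service.rank("SYN1")
        assert summary["n_ranked"] == 52
        top = service.get_rank(10)
        assert len(top) == 10
        scores = [row["score"] for row in top]
        assert scores == sorted(scores, reverse=True)
        assert service.get_rank(0) == []

    def test_http_endpoints(self, service):
        server = serve(service, port=0)
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        host, port = server.server_address
        base = f"http://{host}:{port}"
        try:
            # getRank before any rank -> 409
            with pytest.raises(urllib.error.HTTPError) as err:
                urllib.request.urlopen(f"{base}/v1/getRank/5")
            assert err.value.code == 409

            with urllib.request.urlopen(f"{base}/v1/diseaseList/planted") as r:
                listed = json.loads(r.read())
            assert listed[0]["disease_id"] == "SYN1"

            # unknown disease -> 404 with suggestions
            req = urllib.request.Request(
                f"{base}/v1/rank",
                data=json.dumps({"disease_id": "SYNX"}).encode(),
                method="POST",
            )
            with pytest.raises(urllib.error.HTTPError) as err:
                urllib.request.urlopen(req)
            assert err.value.code == 404
            assert "SYN1" in json.loads(err.value.read())["suggestions"]

            req = urllib.request.Request(
                f"{base}/v1/rank",
                data=json.dumps(
                    {"disease_id": "SYN1", "alpha": 0.5, "gamma": 0.5}
                ).encode(),
                method="POST",
            )
            with urllib.request.urlopen(req) as r:
                summary = json.loads(r.read())
            assert summary["n_ranked"] == 52

            with urllib.request.urlopen(f"{base}/v1/getRank/10") as r:
                top = json.loads(r.read())
            assert len(top) == 10
        finally:
            server.shutdown()
            server.server_close()

    def test_cli_and_rest_rankings_are_identical(
        self, synth, synth_files
    ):
        net_path, assoc_path = synth_files
        net, assoc, _ = synth
        with CliRunner().isolated_filesystem():
            result = CliRunner().invoke(main, [
                "rank", "--network", str(net_path), "--associations",
                str(assoc_path), "--disease", "SYN1", "--out", "ranking.tsv",
            ], catch_exceptions=False)
            assert result.exit_code == 0
            cli_rows = [
                tuple(ln.rstrip("\n").split("\t"))
                for ln in read_ranking_rows("ranking.tsv")
            ]
        service = RankingService(
            load_target_network(net_path), load_associations(assoc_path)
        )
        service.rank("SYN1", alpha=0.5, gamma=0.5)
        rest_rows = [
            (str(r["rank"]), r["mirna"], f'{r["score"]:.17g}')
            for r in service.get_rank(len(cli_rows))
        ]
        assert cli_rows == rest_rows
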