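import pytest

from rwrmtn import (
    AssociationTable,
    GeneratorConfig,
    MirnaTargetNetwork,
    build_transition_matrix,
    generate,
)

TOY_EDGES = [("m1", "g1"), ("m1", "g2"), ("m2", "g2"), ("m2", "g3"), ("m3", "g4")]


@pytest.fixture
def toy_net():
    """5-edge bipartite fixture: m1-{g1,g2}, m2-{g2,g3}, m3-{g4}."""
    return MirnaTargetNetwork.from_edges(TOY_EDGES)


@pytest.fixture
def toy_tm(toy_net):
    return build_transition_matrix(toy_net)


@pytest.fixture
def toy_assoc():
    return AssociationTable.from_records(
        [
            ("114480", "Breast cancer", "m1"),
            ("114480", "Breast cancer", "m2"),
            ("211980", "Lung cancer", "m3"),
        ]
    )


@pytest.fixture
def toy_network_file(tmp_path):
    path = tmp_path / "toy_network.tsv"
    path.write_text("".join(f"{m}\t{g}\n" for m, g in TOY_EDGES))
    return path


@pytest.fixture
def toy_assoc_file(tmp_path):
    path = tmp_path / "toy_assoc.tsv"
    path.write_text(
        "114480\tBreast cancer\tm1\n"
        "114480\tBreast cancer\tm2\n"
        "211980\tLung cancer\tm3\n"
    )
    return path


@pytest.fixture(scope="session")
def synth():
    """One planted-module dataset (defaults, seed 1), shared across tests."""
    return generate(GeneratorConfig(rng_seed=1))


@pytest.fixture(scope="session")
def synth_files(synth, tmp_path_factory):
    from rwrmtn.synthetic import write_dataset

    net, assoc, _ = synth
    directory = tmp_path_factory.mktemp("synth")
    return write_dataset(net, assoc, directory)
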