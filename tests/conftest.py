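import numpy as np
import pytest

from causyn.io import PPINetwork, load_dataset
from causyn.synthetic import SyntheticSpec, generate


def write_toy_tables(tmp_path):
    """A tiny self-consistent bundle: 3 drugs, 2 cell lines, 4 records."""
    (tmp_path / "drugs.tsv").write_text(
        "drug_id\tsmiles\nd1\tCCO\nd2\tc1ccccc1\nd3\tCC(=O)O\n"
    )
    (tmp_path / "ppi_edges.tsv").write_text(
        "protein_a\tprotein_b\n"
        "g1\tg2\ng2\tg3\ng3\tg4\ng4\tg5\ng2\tg5\n"
    )
    (tmp_path / "targets.tsv").write_text(
        "cell_line_id\tgene_id\n"
        "c1\tg1\nc1\tg3\nc2\tg2\nc2\tg5\n"
    )
    (tmp_path / "expression.tsv").write_text(
        "gene_id\tc1\tc2\n"
        "g1\t1.0\t2.0\ng2\t0.5\t-0.5\ng3\t3.0\t1.0\ng4\t0.0\t0.0\ng5\t-1.0\t1.0\n"
    )
    (tmp_path / "synergy.tsv").write_text(
        "drug1\tdrug2\tcell_line\tscore\n"
        "d1\td2\tc1\t5.5\nd1\td3\tc1\t-2.0\nd2\td3\tc2\t0.7\nd1\td2\tc2\t-4.1\n"
    )
    return {
        "drug_table": tmp_path / "drugs.tsv",
        "ppi_edges": tmp_path / "ppi_edges.tsv",
        "target_table": tmp_path / "targets.tsv",
        "expression_matrix": tmp_path / "expression.tsv",
        "synergy_table": tmp_path / "synergy.tsv",
    }


@pytest.fixture
def toy_paths(tmp_path):
    return write_toy_tables(tmp_path)


@pytest.fixture
def toy_bundle(toy_paths):
    return load_dataset(**toy_paths)


@pytest.fixture
def path_graph():
    net = PPINetwork()
    net.add_edge("a", "b")
    net.add_edge("b", "c")
    return net


@pytest.fixture(scope="session")
def small_synth():
    """A reduced synthetic bundle for fast model-level tests."""
    spec = SyntheticSpec(
        n_genes=25, n_cell_lines=4, n_planted=4, n_extra_targets=4,
        n_records=100, seed=11,
        drug_names=("aspirin", "caffeine", "glycerol", "metformin",
                    "urea", "benzylalcohol", "glycine", "hexanoate"),
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_dataset(small_synth):
    from causyn.train import SynergyDataset

    return SynergyDataset.from_bundle(small_synth.load())


def random_graph_adjacency(rng, n, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T
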