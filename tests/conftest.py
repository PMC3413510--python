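import numpy as np
import pytest

from orgcircle import contigraph, synthio
from orgcircle.seqio import GenomeSequence, SequenceRecord

BASES = np.array(list("ACGT"))


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, n)])


def make_genome(n: int, seed: int, topology: str = "circular",
                name: str = "g") -> GenomeSequence:
    return GenomeSequence(SequenceRecord(name, random_dna(n, seed)), topology)


@pytest.fixture(scope="session")
def mito_fixture():
    """Small plant-mitochondrial-style layout: 5 single-copy regions, 4 repeats, ~4.3 kb."""
    spec = synthio.plant_mito_spec(scale=0.1, seed=11)
    genome, truth = synthio.build_genome(spec)
    contigs, graph_text = synthio.emit_truth_contigs(genome, truth, seed=11)
    return dict(spec=spec, genome=genome, truth=truth, contigs=contigs,
                graph_text=graph_text)


@pytest.fixture()
def mito_graph(mito_fixture, tmp_path):
    path = tmp_path / "contigs.graph"
    path.write_text(mito_fixture["graph_text"])
    g = contigraph.parse_graph(path)
    contigraph.load_residues(g, mito_fixture["contigs"])
    return g
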