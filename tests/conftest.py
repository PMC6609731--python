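import pytest

from mitoirg4.synthetic_data import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def standard_synthetic():
    """One mid-sized synthetic genome with IR, genes and planted motifs,
    shared across tests (generation is deterministic given the seed)."""
    spec = SyntheticSpec(genome_length=120_000, ir_arm_length=30_000, seed=2024)
    return generate_genome(spec)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(seq, name="x", path_name="g.fa"):
        p = tmp_path / path_name
        p.write_text(f">{name}\n{seq}\n")
        return p

    return _write
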