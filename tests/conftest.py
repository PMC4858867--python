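import pytest

from chromotile import parse_gff, write_fixture


@pytest.fixture()
def small_gff(tmp_path):
    """A small seeded annotation file with sequence: 2 chromosomes, 3 types."""
    return write_fixture(
        tmp_path / "small.gff3",
        seed=11,
        n_seqs=2,
        seq_length=40_000,
        n_features=300,
        types=("gene", "exon", "ncRNA"),
        gc_bias=0.45,
    )


@pytest.fixture()
def small_parsed(small_gff):
    return parse_gff(small_gff, {"gene", "exon", "ncRNA"})
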