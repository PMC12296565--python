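import pytest

from agarcode.alignio import LabeledAlignment
from agarcode.synthgen import SpeciesSpec, SynthConfig, generate_alignment


def make_alignment(seqs, species=None, marker="other", ids=None):
    n = len(seqs)
    ids = ids or tuple(f"s{i+1}" for i in range(n))
    species = species or tuple([None] * n)
    return LabeledAlignment(
        marker=marker,
        ids=tuple(ids),
        seqs=tuple(seqs),
        species=tuple(species),
        origin=tuple([None] * n),
    )


@pytest.fixture
def toy_alignment():
    return make_alignment(
        ["ACGTACGTAC", "ACGTACGTAC", "ACTTACGTAC"],
        species=("spA", "spA", "spB"),
    )


@pytest.fixture
def two_species_alignment():
    """Two well-separated species, 4 samples each, distinct haplotypes."""
    cfg = SynthConfig(
        marker="matK",
        length=500,
        species=(
            SpeciesSpec("spA", 4, 4),
            SpeciesSpec("spB", 4, 4),
        ),
        theta_intra=0.004,
        theta_inter=0.08,
        seed=11,
    )
    aln, truth = generate_alignment(cfg)
    return aln, truth
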