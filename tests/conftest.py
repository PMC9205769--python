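import numpy as np
import pytest

from fourcscape.genome_builder import FragmentEnd, FragmentEndMap, Genome, digest
from fourcscape.profile_norm import ContactProfile, Viewpoint
from fourcscape.synthetic_data import make_toy_genome


def random_genome(rng: np.random.Generator, length: int, name: str = "chr1") -> Genome:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome({name: seq}, build_label=f"rand{length}")


def simple_fragmap(counts_per_fragment: list[int], chrom: str = "chr1", frag_len: int = 1000):
    """A fragment-end map with one non-blind end per fragment plus a matching
    raw profile whose fragment-level counts are as given."""
    ends = []
    counts = {}
    for i, c in enumerate(counts_per_fragment):
        fs, fe = i * frag_len, (i + 1) * frag_len
        e = FragmentEnd(chrom, fs, fe, fs, fs, fs + 200, "left", blind=False)
        ends.append(e)
        counts[e.end_id] = c
    fragmap = FragmentEndMap(ends, build_label="simple", chrom_lengths={chrom: len(counts_per_fragment) * frag_len})
    profile = ContactProfile(Viewpoint(chrom, 0), counts, genome_build="simple")
    return fragmap, profile


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(50_000, motif_spacing_first=1000, motif_spacing_second=300, seed=11)


@pytest.fixture(scope="session")
def toy_fragmap(toy_genome):
    return digest(toy_genome)
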