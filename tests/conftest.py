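import numpy as np
import pytest

from codonusage import CdsRecord, CdsSet, SyntheticSpec, sample_cds_set
from codonusage.genetics import standard_code
from codonusage.indices import CodonCounts


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def make_record():
    def _make(sequence, species="sp1", gene="geneX"):
        return CdsRecord(species=species, gene=gene, sequence=sequence)

    return _make


@pytest.fixture
def uniform_counts(code):
    """Every sense codon observed the same number of times."""
    return CodonCounts(counts={c: 1000 for c in code.sense_codons}, source="uniform")


@pytest.fixture
def degenerate_counts(code):
    """Exactly one codon used per family (maximal bias)."""
    counts = {fam[0]: 100 for fam in code.families.values()}
    return CodonCounts(counts=counts, source="degenerate")


@pytest.fixture(scope="session")
def small_synthetic_set():
    spec = SyntheticSpec(n_species=6, length_codons=300, beta=1.0, seed=42)
    cds, truth = sample_cds_set(spec)
    return cds, truth


def random_cds(rng, n_codons, code, species="spX", gene="geneX"):
    """A random in-frame CDS without stops, for oracle comparisons."""
    sense = [c for c in code.sense_codons]
    picks = rng.choice(len(sense), size=n_codons)
    body = "".join(sense[i].replace("U", "T") for i in picks)
    return CdsRecord(species=species, gene=gene, sequence=body)
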