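import numpy as np
import pandas as pd
import pytest

from adrpgx.locus import load_allele_definitions, load_gene_model


@pytest.fixture(scope="session")
def defs():
    return load_allele_definitions()


@pytest.fixture(scope="session")
def gene():
    return load_gene_model()


@pytest.fixture(scope="session")
def exons15_union(gene):
    """Union of exon 1-5 bases, for brute-force interval oracles."""
    bases = set()
    for s, e in gene.exon_intervals(1, 5):
        bases.update(range(s, e))
    return bases


def haplotype_for(defs, label):
    """State vector carrying exactly the defining variants of ``label``."""
    positions = defs.positions
    vec = np.zeros(len(positions), dtype=np.int8)
    for p, _ in defs.entries[label]:
        vec[positions.index(p)] = 1
    return vec


@pytest.fixture(scope="session")
def hap():
    return haplotype_for


def make_records(rows):
    """Build a records frame from (sample, drug, side_effect, present, layer) tuples."""
    return pd.DataFrame(rows, columns=["sample_id", "drug", "side_effect", "present", "layer"])


@pytest.fixture
def records_factory():
    return make_records
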