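import numpy as np
import pytest

from omscaffold.assembly_io import ScaffoldRecord
from omscaffold.digest import digest_record, get_enzyme
from omscaffold.synthetic import make_chromosome, split_chromosome


@pytest.fixture(scope="session")
def kpni():
    return get_enzyme("KpnI")


@pytest.fixture(scope="session")
def small_truth(kpni):
    """A 2 Mb chromosome split into 5 scaffolds, with its digest — the
    shared substrate for extension/joining tests."""
    rng = np.random.default_rng(2024)
    chrom = make_chromosome(rng, 2_000_000, kpni, mean_frag_kb=10.0)
    truth = split_chromosome(rng, chrom, 5)
    return truth


@pytest.fixture(scope="session")
def small_ref_map(small_truth, kpni):
    return digest_record(small_truth.chromosome, kpni)


def make_record(seq: str, rid: str = "s") -> ScaffoldRecord:
    return ScaffoldRecord(rid, seq)
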