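import numpy as np
import pytest

from piwas.io import STANDARD_AA, ProteinRecord, ReadSet
from piwas.pipeline import analyze_cohort
from piwas.simulate import SyntheticCohortConfig, generate_cohort

AA = np.array(list(STANDARD_AA))


def random_readset(rng: np.random.Generator, n_reads: int,
                   sample_id: str = "S") -> ReadSet:
    """Unique random 12mers with i.i.d. uniform letters."""
    reads: dict[str, None] = {}
    while len(reads) < n_reads:
        block = AA[rng.integers(0, 20, size=(n_reads - len(reads) + 8, 12))]
        for row in block:
            reads.setdefault("".join(row), None)
            if len(reads) >= n_reads:
                break
    return ReadSet(sample_id, tuple(reads))


def random_protein(rng: np.random.Generator, length: int,
                   protein_id: str = "P") -> ProteinRecord:
    return ProteinRecord(protein_id, "random", "".join(AA[rng.integers(0, 20, size=length)]))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Desk-scale planted-epitope cohort shared across pipeline tests:
    3 cases, 5 controls, 500 reads/sample, 10 decoys of 120 residues."""
    config = SyntheticCohortConfig(
        n_cases=3, n_controls=5, reads_per_sample=500,
        n_decoys=10, decoy_length=120, epitope_start=50,
        plant_rate=0.3, prevalence=1.0, seed=20,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_cohort_result(tiny_cohort):
    return analyze_cohort(tiny_cohort.proteins, tiny_cohort.readsets,
                          tiny_cohort.manifest, n_perm=200, seed=7)
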