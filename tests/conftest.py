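import numpy as np
import pytest
from hypothesis import settings

from graftmob.io import GeneModel, GenotypeReference, ReadRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from graftmob.pipeline import GraftDataset, run_pipeline
from graftmob.simulate import SimulationParams, generate_dataset

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def make_read(seq: str, read_id: str = "r0", phred: int = 35, sample_id: str = "s") -> ReadRecord:
    return ReadRecord(read_id, 1, seq, chr(phred + 33) * len(seq), sample_id)


def mutate(rng: np.random.Generator, seq: str, n_sub: int = 0, n_indel: int = 0) -> str:
    """Apply random substitutions and single-base indels."""
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(s)))
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    for _ in range(n_indel):
        i = int(rng.integers(0, len(s)))
        if rng.random() < 0.5 and len(s) > 1:
            del s[i]
        else:
            s.insert(i, str(rng.choice(list("ACGT"))))
    return "".join(s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_reference(rng) -> GenotypeReference:
    """Single-chromosome 5 kb reference with two genes."""
    seq = random_sequence(rng, 5000)
    genes = [
        GeneModel("gA", "c1", 500, 1700, "+", 1200),
        GeneModel("gB", "c1", 2500, 3600, "-", 1100),
    ]
    return GenotypeReference("geno", {"c1": seq}, genes)


# Reduced problem size for the shared fixture: fewer genes and fragments
# than the full-scale defaults, with the spiked sink abundance raised so the
# expected read support per spike stays comparable (support scales with
# TPM x depth, independent of gene count).
TINY_PARAMS = SimulationParams(
    seed=11,
    n_genes_per_genotype=60,
    fragments_per_sample=4000,
    mobile_abundance_range=(1500.0, 10000.0),
)


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """Small but complete synthetic heterograft dataset (shared)."""
    outdir = tmp_path_factory.mktemp("tiny_sim")
    return generate_dataset(TINY_PARAMS, outdir)


@pytest.fixture(scope="session")
def tiny_result(tiny_sim, tmp_path_factory):
    """Pipeline result on the shared small dataset."""
    outdir = tmp_path_factory.mktemp("tiny_out")
    return run_pipeline(GraftDataset.from_simulated(tiny_sim), outdir)
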