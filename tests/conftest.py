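import numpy as np
import pytest

from svbench.pipeline import run_trio_pipeline
from svbench.simulate import simulate_reference, simulate_trio, simulate_reads
from svbench.triobin import VotingPolicy, build_kmer_index, partition_reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_trio():
    """Compact trio fixture for unit tests (300 kb, 50 planted SVs)."""
    ref, elements = simulate_reference(300_000, seed=101)
    return simulate_trio(ref, 50, seed=102, elements=elements)


@pytest.fixture(scope="session")
def small_binning(small_trio):
    """Reads + k-mer indexes + partition result on the compact trio (20x)."""
    reads = simulate_reads(
        {"paternal": small_trio.child_paternal, "maternal": small_trio.child_maternal},
        depth=20,
        seed=103,
    )
    policy = VotingPolicy()
    indices = {
        k: build_kmer_index(list(small_trio.father), list(small_trio.mother), k)
        for k in policy.k_values
    }
    result = partition_reads(reads, indices, policy)
    return {"reads": reads, "indices": indices, "policy": policy, "result": result}


@pytest.fixture(scope="session")
def study_run():
    """The standard study-condition fixture: 2 Mb trio, 300 planted SVs,
    platform sensitivities 0.9/0.8/0.7 across CCS/CLR/ONT."""
    return run_trio_pipeline(seed=11)


@pytest.fixture(scope="session")
def study_binning(study_run):
    """60x child reads of the study fixture, partitioned at all five k."""
    truth = study_run.truth
    reads = simulate_reads(
        {"paternal": truth.child_paternal, "maternal": truth.child_maternal},
        depth=60,
        seed=12,
    )
    policy = VotingPolicy()
    indices = {
        k: build_kmer_index(list(truth.father), list(truth.mother), k)
        for k in policy.k_values
    }
    result = partition_reads(reads, indices, policy)
    return {"reads": reads, "indices": indices, "policy": policy, "result": result}
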