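import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from targetpolish.fixtures import FixtureConfig, make_draft, make_reads, make_truth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL = FixtureConfig(genome_len=30_000, n_contigs=1, n_target_windows=2, seed=5)


@pytest.fixture(scope="session")
def small_fixture():
    """30 kb single-contig fixture with two soft-masked windows."""
    truth = make_truth(SMALL)
    draft, ledger = make_draft(truth, SMALL)
    reads, paf = make_reads(truth, SMALL, ledger)
    return SMALL, truth, draft, ledger, reads, paf


def random_masked_assembly(rng: np.random.Generator, n_contigs: int = 8):
    """Random assemblies with random soft-masked runs, for fuzz tests."""
    from targetpolish.io_formats import SequenceRecord

    records = []
    for i in range(n_contigs):
        length = int(rng.integers(300, 4000))
        bases = rng.choice(list("ACGT"), size=length)
        seq = np.array(bases, dtype="U1")
        pos = 0
        while pos < length:
            run = int(rng.integers(10, 400))
            if rng.random() < 0.3:
                lo, hi = pos, min(length, pos + run)
                seq[lo:hi] = np.char.lower(seq[lo:hi])
            pos += run
        records.append(SequenceRecord(f"contig-{i}.a", "".join(seq)))
    return records
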