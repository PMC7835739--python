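import numpy as np
import pandas as pd
import pytest

from splice_prognosis import ClinicalTable, ExpressionMatrix
from splice_prognosis.simulate import SyntheticCohortConfig, TranscriptSpec, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tiny_matrix():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.5, 0.0], [3.0, 2.0]],
            index=["f1", "f2"],
            columns=["s1", "s2"],
        ),
        unit="tpm",
    )


def make_clinical(times, events, prefix="s"):
    ids = [f"{prefix}{i + 1}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"sample_id": ids, "time_days": times, "event": events})
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across read-only tests."""
    cfg = SyntheticCohortConfig(
        n_samples=120,
        n_background_genes=300,
        modules=(),
        seed=424242,
    )
    return simulate_cohort(cfg)


def null_config(seed, n_samples=100):
    """Generator config with no survival or module effects."""
    tx = tuple(
        TranscriptSpec(t.transcript_id, t.share, 0.0, t.sigma)
        for t in SyntheticCohortConfig().transcripts
    )
    return SyntheticCohortConfig(
        n_samples=n_samples,
        transcripts=tx,
        n_background_genes=0,
        modules=(),
        seed=seed,
    )
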