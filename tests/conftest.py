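import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from floraltse.io_formats import HitRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def mk_hit(
    query="q1",
    subject="s1",
    bitscore=100.0,
    evalue=1e-30,
    q_start=1,
    q_end=100,
    s_start=1,
    s_end=100,
    pct_identity=95.0,
    aln_length=None,
):
    """Terse HitRecord factory for tests."""
    if aln_length is None:
        aln_length = abs(q_end - q_start) + 1
    return HitRecord(
        query_id=query,
        subject_id=subject,
        pct_identity=pct_identity,
        aln_length=aln_length,
        mismatches=0,
        gap_opens=0,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_hits(rng, n_queries=10, n_subjects=8, n_hits=40):
    """A random hit table with deliberate bitscore/e-value ties."""
    hits = []
    for _ in range(n_hits):
        q = f"c{rng.integers(n_queries)}"
        s = f"g{rng.integers(n_subjects)}"
        bit = float(rng.choice([50.0, 80.0, 80.0, 120.0, 200.0]))
        ev = float(10.0 ** -rng.choice([5, 20, 20, 40]))
        hits.append(mk_hit(query=q, subject=s, bitscore=bit, evalue=ev))
    return hits
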