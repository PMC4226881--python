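import numpy as np
import pandas as pd
import pytest

from msea.io_model import MutationClass, MutationRecord, TranscriptProfile


def make_profile(counts, transcript_id="T1", gene="G1", domains=()):
    counts = np.asarray(counts, dtype=np.int64)
    return TranscriptProfile(
        transcript_id=transcript_id,
        gene=gene,
        length_L=len(counts),
        counts_Y=counts,
        domains=list(domains),
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def toy_profile():
    """L=10 with two records at position 3 and one at position 7."""
    y = np.zeros(10, dtype=np.int64)
    y[2] = 2
    y[6] = 1
    return make_profile(y)


def make_record(
    gene="G1",
    transcript="T1",
    sample="s1",
    position=1,
    mclass=MutationClass.MISSENSE,
    deleterious=None,
):
    return MutationRecord(
        gene=gene,
        transcript_id=transcript,
        sample_id=sample,
        aa_position=position,
        mutation_class=mclass,
        deleterious=deleterious,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def transcript_table():
    def build(entries):
        return pd.DataFrame(
            [(t, g, l) for t, g, l in entries],
            columns=["transcript_id", "gene", "aa_length"],
        )

    return build


@pytest.fixture
def domain_table():
    def build(entries):
        return pd.DataFrame(
            [(t, d, d, s, e) for t, d, s, e in entries],
            columns=["transcript_id", "domain_id", "domain_name", "aa_start", "aa_end"],
        )

    return build
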