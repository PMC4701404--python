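import numpy as np
import pytest

from metaepi.core_data import (
    DesignProfile,
    MetaAnalysisSet,
    TwoByTwoTable,
    ValidationStudy,
)


def make_study(
    study_id,
    meta_id,
    tp,
    fp,
    fn,
    tn,
    **design,
):
    table = TwoByTwoTable(tp=tp, fp=fp, fn=fn, tn=tn)
    profile = DesignProfile.from_raw(design, table=table)
    return ValidationStudy(study_id, meta_id, table, profile)


@pytest.fixture
def six_study_set():
    """Six studies with a case-control / cohort split and varying thresholds."""
    counts = [
        (90, 10, 10, 90),
        (45, 25, 5, 55),
        (120, 40, 30, 160),
        (60, 8, 20, 70),
        (30, 12, 6, 80),
        (75, 30, 15, 45),
    ]
    spectra = ["cohort", "case_control", "cohort", "case_control", "cohort", "case_control"]
    studies = tuple(
        make_study(f"s{i}", "m1", *c, spectrum=sp)
        for i, (c, sp) in enumerate(zip(counts, spectra))
    )
    return MetaAnalysisSet("m1", studies)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
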