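import numpy as np
import pytest

from egmfrac import RunConfig, cgcd_record, gen_dataset
from egmfrac.synthgen import SynthParams


@pytest.fixture(scope="session")
def default_params():
    return SynthParams()


@pytest.fixture(scope="session")
def group1_records():
    """24 synthetic records, 8 per Type I/II/III, fixed master seed."""
    return gen_dataset([("I", 8), ("II", 8), ("III", 8)], seed=1)


@pytest.fixture(scope="session")
def group1_medians(group1_records):
    """Per-record median CGCDs and labels for the 24-record dataset."""
    medians, labels = [], []
    for rec in group1_records:
        seg = cgcd_record(rec)
        assert seg.median_cgcd is not None
        medians.append(seg.median_cgcd)
        labels.append(rec.label)
    return np.asarray(medians), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
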