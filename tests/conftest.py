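import numpy as np
import pytest

import bpmll


@pytest.fixture(scope="session")
def small_records():
    """200 default-signal synthetic introns (session-cached, deterministic)."""
    return bpmll.simulate_introns(bpmll.SimConfig(n_introns=200, seed=42))


@pytest.fixture(scope="session")
def fitted_feature_models(small_records):
    pos, neg = bpmll.extract_nonamers(small_records)
    return bpmll.fit_pwm(pos), bpmll.fit_markov(pos, neg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def intron_files(tmp_path, small_records):
    """Round-trip the small record set through the on-disk dialects."""
    fasta = tmp_path / "introns.fasta"
    annot = tmp_path / "annotations.tsv"
    bpmll.write_introns(small_records, fasta, annot)
    return fasta, annot
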