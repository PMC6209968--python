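import numpy as np
import pytest

from ppgabp import CohortSpec, PipelineConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 12-subject cohort (60 s records) shared across tests."""
    spec = CohortSpec(n_per_group=(4, 4, 4), duration_s=60.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    """Quality-screened epochs from the small cohort."""
    from ppgabp.preprocessing import preprocess_record

    out = []
    for rec in small_cohort:
        epochs, _ = preprocess_record(rec)
        out.extend(ep for ep in epochs if ep.quality_ok)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
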