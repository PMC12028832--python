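import numpy as np
import pytest

from fetalgp import CurveSet, assess_cohort, default_cohort_spec, generate_group_conditional


@pytest.fixture(scope="session")
def curves():
    return CurveSet.default()


@pytest.fixture(scope="session")
def default_cohort(curves):
    """One default synthetic cohort (777 subjects, 52 events), fixed seed."""
    return generate_group_conditional(default_cohort_spec(), curves=curves, seed=7)


@pytest.fixture(scope="session")
def assessed(default_cohort, curves):
    """Cohort table joined with the per-subject assessment columns."""
    return default_cohort.data.join(assess_cohort(default_cohort.data, curves))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
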