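import numpy as np
import pandas as pd
import pytest

from efrd.design import Stratification
from efrd.factors import EFComparison
from efrd.core import DesignSpec, SubjectTable


def make_comparison(y, assignment, labels, level=1):
    """EFComparison over all subjects with the given stratum labels."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    strata = {int(i): np.flatnonzero(labels == i) for i in np.unique(labels)}
    keys = {int(i): (int(i),) for i in strata}
    return EFComparison(level, np.arange(len(y)), np.asarray(assignment),
                        Stratification(labels, strata, keys), False, "raw")


def make_table(running, z, y, cov=None, ids=None):
    z = np.atleast_2d(np.asarray(z))
    n = z.shape[0]
    if cov is None:
        cov = pd.DataFrame({"c": np.zeros(n, dtype=int)})
    elif not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame({"c": np.asarray(cov)})
    if ids is None:
        ids = np.arange(n)
    return SubjectTable(ids=np.asarray(ids), running=np.asarray(running, float),
                        z=z, y=np.asarray(y, float), covariates=cov)


@pytest.fixture
def k2_spec():
    return DesignSpec(K=2, compliance="two_sided", cutoff=0.0,
                      eligibility_direction="ge")


@pytest.fixture
def k3_spec():
    return DesignSpec(K=3, compliance="one_sided", cutoff=0.0,
                      eligibility_direction="ge")
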