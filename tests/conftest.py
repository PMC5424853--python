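import warnings

import numpy as np
import pandas as pd
import pytest

from survcea import paramsets, synthetic_data


@pytest.fixture(scope="session")
def partitioned_params():
    return paramsets.load_partitioned_params()


@pytest.fixture(scope="session")
def msm_spec():
    """(control-arm spec, treatment hazard-ratio map)."""
    return paramsets.load_multistate_spec()


@pytest.fixture(scope="session")
def markov_rules_raw():
    return paramsets.load_markov_rules()


@pytest.fixture(scope="session")
def trial_ipd(msm_spec):
    """One synthetic two-arm trial from the illness-death generating model."""
    spec, hrs = msm_spec
    design = synthetic_data.TrialDesign(spec=spec, treatment_hrs=hrs)
    return synthetic_data.simulate_trial(design, seed=11)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
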