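import warnings

import pytest

import certflux as cf


@pytest.fixture(scope="session")
def sds_model():
    return cf.build_model(cf.SDS)


@pytest.fixture(scope="session")
def ns_model():
    return cf.build_model(cf.NS)


@pytest.fixture(scope="session")
def sds_summary(sds_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", cf.GateWarning)
        return cf.structural_summary(sds_model)


@pytest.fixture(scope="session")
def ns_summary(ns_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", cf.GateWarning)
        return cf.structural_summary(ns_model)


@pytest.fixture(scope="session")
def weber_sds():
    return cf.weber_instance(cf.SDS)


@pytest.fixture(scope="session")
def weber_ns():
    return cf.weber_instance(cf.NS)


@pytest.fixture(scope="session")
def sds_empirical(weber_sds):
    return cf.simulated_influence_matrix(weber_sds, cf.FIG6_INITIAL_STATE)


@pytest.fixture(scope="session")
def ns_empirical(weber_ns):
    return cf.simulated_influence_matrix(weber_ns, cf.FIG7_INITIAL_STATE)
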