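import numpy as np
import pytest

import pkbound as pb


@pytest.fixture(scope="session")
def reference():
    """The shipped reference datasets (sample rows, rate sets, printed matrices)."""
    return pb.fixtures()


@pytest.fixture(scope="session")
def two_cpt_no_tenside(reference):
    p = reference["params_two_compartment_no_tenside"]
    return pb.build_two_compartment(p["ka"], p["ke1"], p["ke2"], dose=50.0)


@pytest.fixture(scope="session")
def two_cpt_tenside(reference):
    p = reference["params_two_compartment_tenside"]
    return pb.build_two_compartment(p["ka"], p["ke1"], p["ke2"], dose=50.0)


@pytest.fixture(scope="session")
def three_cpt_no_tenside(reference):
    p = reference["params_three_compartment_no_tenside"]
    return pb.build_three_compartment(p["ka"], p["ke1"], p["k23"], p["ke3"], dose=50.0, observed=3)


@pytest.fixture(scope="session")
def three_cpt_tenside(reference):
    p = reference["params_three_compartment_tenside"]
    return pb.build_three_compartment(p["ka"], p["ke1"], p["k23"], p["ke3"], dose=50.0, observed=3)


@pytest.fixture(scope="session")
def interval_no_tenside(two_cpt_no_tenside):
    return pb.expand_uncertainty(two_cpt_no_tenside, pb.UncertaintySpec(delta=0.1))


@pytest.fixture(scope="session")
def interval_tenside(two_cpt_tenside):
    return pb.expand_uncertainty(two_cpt_tenside, pb.UncertaintySpec(delta=0.1))


@pytest.fixture(scope="session")
def interval3_no_tenside(three_cpt_no_tenside):
    return pb.expand_uncertainty(three_cpt_no_tenside, pb.UncertaintySpec(delta=0.1))


@pytest.fixture(scope="session")
def interval3_tenside(three_cpt_tenside):
    return pb.expand_uncertainty(three_cpt_tenside, pb.UncertaintySpec(delta=0.1))
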