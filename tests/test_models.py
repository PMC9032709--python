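"""Model builders, uncertainty expansion and structural validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pkbound as pb

# agreement with a value printed to 4 decimal places (covers exact half-way roundings)
PRINTED_4DP = 5.05e-5


class TestBuilders:
    def test_two_compartment_matches_printed_no_tenside_matrix(self, two_cpt_no_tenside, reference):
        printed = reference["matrix_two_compartment_no_tenside"]["A"]
        np.testing.assert_allclose(two_cpt_no_tenside.A, printed, atol=PRINTED_4DP)
        np.testing.assert_array_equal(two_cpt_no_tenside.c, [0.0, 1.0])
        np.testing.assert_array_equal(two_cpt_no_tenside.x0, [50.0, 0.0])

    def test_two_compartment_tenside_lumped_diagonal(self, two_cpt_tenside):
        assert two_cpt_tenside.A[0, 0] == pytest.approx(-1.004856, abs=1e-9)

    def test_zero_dose_gives_zero_initial_state(self):
        m = pb.build_two_compartment(0.1, 0.2, 0.3, dose=0.0)
        np.testing.assert_array_equal(m.x0, [0.0, 0.0])

    @pytest.mark.parametrize("bad_rate", ["ka", "ke1", "ke2"])
    def test_nonpositive_rate_error_names_constant(self, bad_rate):
        rates = {"ka": 0.1, "ke1": 0.2, "ke2": 0.3, bad_rate: 0.0}
        with pytest.raises(ValueError, match=bad_rate):
            pb.build_two_compartment(**rates, dose=50)

    def test_three_compartment_matches_printed_matrices(
        self, three_cpt_no_tenside, three_cpt_tenside, reference
    ):
        printed = reference["matrix_three_compartment_no_tenside"]["A"]
        np.testing.assert_allclose(three_cpt_no_tenside.A, printed, atol=PRINTED_4DP)
        np.testing.assert_array_equal(three_cpt_no_tenside.c, [0.0, 0.0, 1.0])
        np.testing.assert_array_equal(three_cpt_no_tenside.x0, [50.0, 0.0, 0.0])
        printed_t = reference["matrix_three_compartment_tenside"]["A"]
        np.testing.assert_allclose(three_cpt_tenside.A, printed_t, atol=PRINTED_4DP)

    def test_three_compartment_observation_of_first_compartment(self):
        m = pb.build_three_compartment(0.037, 0.1214, 1.2725, 0.2171, 50, observed=1)
        np.testing.assert_array_equal(m.c, [1.0, 0.0, 0.0])

    def test_three_compartment_invalid_observed_index(self):
        with pytest.raises(ValueError, match="observed"):
            pb.build_three_compartment(0.1, 0.1, 0.1, 0.1, 50, observed=4)


class TestExpandUncertainty:
    def test_reproduces_printed_two_compartment_bounds(self, interval_no_tenside, reference):
        printed = reference["interval_two_compartment_no_tenside_delta10"]
        np.testing.assert_allclose(interval_no_tenside.A_hi, printed["A_hi"], atol=PRINTED_4DP)
        np.testing.assert_allclose(interval_no_tenside.A_lo, printed["A_lo"], atol=PRINTED_4DP)
        np.testing.assert_allclose(interval_no_tenside.c_hi, printed["c_hi"], atol=PRINTED_4DP)
        np.testing.assert_allclose(interval_no_tenside.c_lo, printed["c_lo"], atol=PRINTED_4DP)

    @pytest.mark.parametrize(
        "interval_fixture, key",
        [
            ("interval3_no_tenside", "interval_three_compartment_no_tenside_delta10"),
            ("interval3_tenside", "interval_three_compartment_tenside_delta10"),
        ],
    )
    def test_reproduces_printed_three_compartment_bounds(
        self, interval_fixture, key, reference, request
    ):
        interval = request.getfixturevalue(interval_fixture)
        printed = reference[key]
        np.testing.assert_allclose(interval.A_hi, printed["A_hi"], atol=PRINTED_4DP)
        np.testing.assert_allclose(interval.A_lo, printed["A_lo"], atol=PRINTED_4DP)

    def test_zero_delta_is_identity_embedding(self, two_cpt_no_tenside):
        iv = pb.expand_uncertainty(two_cpt_no_tenside, pb.UncertaintySpec(delta=0.0))
        np.testing.assert_array_equal(iv.A_lo, two_cpt_no_tenside.A)
        np.testing.assert_array_equal(iv.A_hi, two_cpt_no_tenside.A)
        np.testing.assert_array_equal(iv.c_lo, two_cpt_no_tenside.c)
        np.testing.assert_array_equal(iv.x0_hi, two_cpt_no_tenside.x0)

    @settings(deadline=None, derandomize=True)
    @given(
        d1=st.floats(0.0, 0.9),
        d2=st.floats(0.0, 0.9),
        ka=st.floats(0.001, 5.0),
        ke1=st.floats(0.001, 5.0),
        ke2=st.floats(0.001, 5.0),
    )
    def test_monotone_in_delta_and_nominal_contained(self, d1, d2, ka, ke1, ke2):
        lo_d, hi_d = sorted([d1, d2])
        m = pb.build_two_compartment(ka, ke1, ke2, dose=50)
        small = pb.expand_uncertainty(m, pb.UncertaintySpec(delta=lo_d))
        big = pb.expand_uncertainty(m, pb.UncertaintySpec(delta=hi_d))
        assert np.all(big.A_lo <= small.A_lo + 1e-15) and np.all(small.A_hi <= big.A_hi + 1e-15)
        # nominal lies within its own bounds, exactly
        assert np.all(small.A_lo <= m.A) and np.all(m.A <= small.A_hi)
        # structural zeros preserved
        zero_mask = m.A == 0
        assert np.all(big.A_lo[zero_mask] == 0) and np.all(big.A_hi[zero_mask] == 0)
        # both bounds stay Metzler
        assert big.is_valid()

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            pb.UncertaintySpec(delta=1.0)
        with pytest.raises(ValueError):
            pb.UncertaintySpec(delta=-0.1)


class TestValidate:
    def test_valid_model_has_no_violations(self, two_cpt_no_tenside):
        assert pb.validate(two_cpt_no_tenside) == []

    def test_negative_offdiagonal_reported_as_metzler_violation(self):
        m = pb.LinearCompartmentalModel(
            A=np.array([[-0.5, 0.0], [-0.01, -0.3]]),
            b=[0, 0], c=[0, 1], x0=[50, 0],
        )
        violations = pb.validate(m)
        assert len(violations) == 1
        assert "Metzler" in violations[0] and "[2,1]" in violations[0]

    def test_bound_ordering_violation_reported(self, two_cpt_no_tenside):
        iv = pb.expand_uncertainty(two_cpt_no_tenside, pb.UncertaintySpec(delta=0.1))
        broken = pb.IntervalModel(
            A_lo=iv.A_hi, A_hi=iv.A_lo,  # swapped on purpose
            c_lo=iv.c_lo, c_hi=iv.c_hi,
            x0_lo=iv.x0_lo, x0_hi=iv.x0_hi,
            nominal=iv.nominal,
        )
        assert any("ordering" in v for v in pb.validate(broken))
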