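import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igpepi import ParameterSet, rhs_eco, rhs_epi, totals
from igpepi.model_core import PARAM_FIELDS


class TestParameterSet:
    def test_derived_rates(self, params):
        assert params.r1 == params.b1 - params.d1
        assert params.r2 == params.b2 - params.d2
        assert params.alpha1 == pytest.approx(
            params.r1 * params.p / params.k1 - params.epsilon * params.a
        )
        assert params.alpha2 == pytest.approx(
            params.r2 * params.q / params.k2 + params.a
        )
        assert params.alpha2 > 0

    def test_rejects_non_growing_species(self, params):
        with pytest.raises(ValueError, match="logistic"):
            params.replace(d1=params.b1)
        with pytest.raises(ValueError, match="logistic"):
            params.replace(b2=0.1, d2=0.2)

    @pytest.mark.parametrize("field", ["k1", "b2"])
    def test_rejects_zero_capacity_or_birth(self, params, field):
        with pytest.raises(ValueError):
            params.replace(**{field: 0.0})

    def test_rejects_negative_and_nonfinite(self, params):
        with pytest.raises(ValueError):
            params.replace(a=-0.01)
        with pytest.raises(ValueError):
            params.replace(beta1=float("nan"))

    def test_dict_round_trip(self, params):
        assert ParameterSet.from_dict(params.to_dict()) == params
        assert tuple(params.to_dict()) == PARAM_FIELDS

    def test_unknown_key_rejected(self, params):
        mapping = params.to_dict()
        mapping["r1"] = 1.0  # derived quantities are never inputs
        with pytest.raises(ValueError, match="unknown parameter keys"):
            ParameterSet.from_dict(mapping)

    def test_missing_key_rejected(self, params):
        mapping = params.to_dict()
        del mapping["beta2"]
        with pytest.raises(ValueError, match="missing"):
            ParameterSet.from_dict(mapping)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        assert ParameterSet.from_yaml(path) == params


class TestRhs:
    def test_origin_and_carrying_capacity_are_fixed_points(self, params):
        np.testing.assert_array_equal(rhs_eco((0.0, 0.0), params), [0.0, 0.0])
        np.testing.assert_allclose(
            rhs_eco((params.k1, 0.0), params), [0.0, 0.0], atol=1e-12
        )
        np.testing.assert_array_equal(
            rhs_epi((0.0, 0.0, 0.0, 0.0), params), np.zeros(4)
        )

    def test_interior_point_against_hand_evaluation(self, params):
        # independent term-by-term arithmetic of the two polynomials
        n1 = n2 = 50.0
        growth1 = (params.b1 - params.d1) * n1 * (
            1.0 - (n1 + params.p * n2) / params.k1
        )
        predation_gain = params.epsilon * params.a * n1 * n2
        growth2 = (params.b2 - params.d2) * n2 * (
            1.0 - (n2 + params.q * n1) / params.k2
        )
        predation_loss = params.a * n1 * n2
        expected = (growth1 + predation_gain, growth2 - predation_loss)
        assert expected == (26.25, 7.5)  # frozen for the canonical scenario
        np.testing.assert_allclose(rhs_eco((n1, n2), params), expected, rtol=1e-14)

    def test_endemic_exclusion_state_is_a_root(self, params):
        # predator at carrying capacity with its disease endemic
        assert params.beta1 * params.k1 > params.b1
        s1 = params.b1 / params.beta1
        state = (s1, params.k1 - s1, 0.0, 0.0)
        np.testing.assert_allclose(rhs_epi(state, params), np.zeros(4), atol=1e-12)

    def test_rejects_invalid_states(self, params):
        with pytest.raises(ValueError, match="negative"):
            rhs_eco((-1.0, 5.0), params)
        with pytest.raises(ValueError, match="non-finite"):
            rhs_epi((np.inf, 0.0, 0.0, 0.0), params)
        with pytest.raises(ValueError, match="components"):
            rhs_eco((1.0, 2.0, 3.0), params)

    def test_prey_axis_invariance_and_pure_logistic(self, params):
        # no prey: prey derivative stays zero, predator follows its logistic
        n1 = 37.0
        d = rhs_eco((n1, 0.0), params)
        assert d[1] == 0.0
        assert d[0] == pytest.approx(params.r1 * n1 * (1 - n1 / params.k1))
        # no predator: prey follows its logistic
        n2 = 81.0
        d = rhs_eco((0.0, n2), params)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(params.r2 * n2 * (1 - n2 / params.k2))

    def test_decouples_into_independent_logistics(self, params):
        pr = params.replace(p=0.0, q=0.0, a=0.0)
        d = rhs_eco((30.0, 70.0), pr)
        assert d[0] == pytest.approx(pr.r1 * 30.0 * (1 - 30.0 / pr.k1))
        assert d[1] == pytest.approx(pr.r2 * 70.0 * (1 - 70.0 / pr.k2))


class TestTotals:
    @pytest.mark.parametrize(
        "state, expected",
        [((1, 2, 3, 4), (3, 7)), ((0, 0, 0, 0), (0, 0)), ((100, 0, 0, 100), (100, 100))],
    )
    def test_componentwise_sums(self, state, expected):
        assert tuple(totals(state)) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.tuples(*[st.floats(0.0, 400.0) for _ in range(4)]),
    st.integers(0, 2**31 - 1),
)
def test_summing_compartments_recovers_abundance_dynamics(state, param_seed):
    """dS_i + dI_i equals the abundance derivative at the totals, always."""
    rng = np.random.default_rng(param_seed)
    pr = ParameterSet(
        b1=rng.uniform(0.5, 2.0), d1=rng.uniform(0.05, 0.45),
        k1=rng.uniform(50, 500),
        b2=rng.uniform(0.5, 2.0), d2=rng.uniform(0.05, 0.45),
        k2=rng.uniform(50, 500),
        p=rng.uniform(0, 0.8), q=rng.uniform(0, 0.8),
        a=rng.uniform(0, 0.05), epsilon=rng.uniform(0.1, 0.9),
        beta1=rng.uniform(0, 0.1), beta2=rng.uniform(0, 0.1),
    )
    d_epi = rhs_epi(state, pr)
    d_eco = rhs_eco(totals(state), pr)
    scale = np.max(np.abs(d_eco)) + 1.0
    assert abs(d_epi[0] + d_epi[1] - d_eco[0]) <= 1e-12 * scale
    assert abs(d_epi[2] + d_epi[3] - d_eco[1]) <= 1e-12 * scale
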