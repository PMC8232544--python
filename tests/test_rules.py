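import numpy as np
import pytest

import lgca
from lgca.errors import CapabilityError, ConfigurationError
from lgca.operators import _outcome_kinematics
from lgca.rules import Neighbourhood, make_rule


def two_outcome_p_plus(rule, geom, nb):
    d = lgca.reorientation_probabilities([1, 0], nb, rule, geom)
    return d.probabilities[0]


class TestRandomWalk:
    def test_uniform_over_outcomes(self, geom_1d, geom_1d_rest):
        nb2 = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8))
        d = lgca.reorientation_probabilities([1, 0], nb2, lgca.random_walk_rule(), geom_1d)
        assert np.allclose(d.probabilities, 0.5)
        nb4 = Neighbourhood(configs=np.zeros((2, 4), dtype=np.uint8))
        d = lgca.reorientation_probabilities(
            [1, 1, 0, 0], nb4, lgca.random_walk_rule(), geom_1d_rest
        )
        assert np.allclose(d.probabilities, 1 / 6)

    def test_full_node_single_outcome(self, geom_1d):
        nb = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8))
        d = lgca.reorientation_probabilities([1, 1], nb, lgca.random_walk_rule(), geom_1d)
        assert d.probabilities.shape == (1,) and d.probabilities[0] == 1.0


class TestChemotaxis:
    def test_uniform_signal_is_random_walk(self, geom_1d):
        nb = Neighbourhood(
            configs=np.zeros((2, 2), dtype=np.uint8), signal=np.array([2.0, 2.0])
        )
        assert two_outcome_p_plus(lgca.chemotaxis_rule(3.0), geom_1d, nb) == pytest.approx(0.5)

    def test_up_gradient_bias(self, geom_1d):
        nb = Neighbourhood(
            configs=np.zeros((2, 2), dtype=np.uint8), signal=np.array([1.0, 0.0])
        )
        p = two_outcome_p_plus(lgca.chemotaxis_rule(1.0), geom_1d, nb)
        assert p == pytest.approx(np.exp(1) / (np.exp(1) + np.exp(-1)), abs=1e-12)

    def test_beta_sign_mirrors_distribution(self, geom_1d):
        nb = Neighbourhood(
            configs=np.zeros((2, 2), dtype=np.uint8), signal=np.array([1.0, 0.0])
        )
        p_fwd = two_outcome_p_plus(lgca.chemotaxis_rule(0.7), geom_1d, nb)
        p_rev = two_outcome_p_plus(lgca.chemotaxis_rule(-0.7), geom_1d, nb)
        assert p_fwd == pytest.approx(1 - p_rev, abs=1e-12)

    def test_missing_signal_field_rejected(self):
        state = lgca.create_lattice(1, [5])
        with pytest.raises(ConfigurationError):
            lgca.apply_reorientation(
                state, lgca.chemotaxis_rule(1.0), np.random.default_rng(0)
            )


class TestHaptotaxisAndGuidance:
    def test_haptotaxis_drift(self, geom_1d):
        nb = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8), field=np.array([1.0]))
        p = two_outcome_p_plus(lgca.haptotaxis_rule(1.0), geom_1d, nb)
        assert p == pytest.approx(np.exp(1) / (np.exp(1) + np.exp(-1)), abs=1e-12)

    def test_haptotaxis_zero_field_uniform(self, geom_1d):
        nb = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8), field=np.array([0.0]))
        assert two_outcome_p_plus(lgca.haptotaxis_rule(5.0), geom_1d, nb) == pytest.approx(0.5)

    def test_haptotaxis_reflection_equivariance(self, geom_1d):
        nbp = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8), field=np.array([0.9]))
        nbm = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8), field=np.array([-0.9]))
        p1 = two_outcome_p_plus(lgca.haptotaxis_rule(1.2), geom_1d, nbp)
        p2 = two_outcome_p_plus(lgca.haptotaxis_rule(1.2), geom_1d, nbm)
        assert p1 == pytest.approx(1 - p2, abs=1e-12)

    def test_contact_guidance_1d_symmetric(self, geom_1d):
        nb = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8), field=np.array([1.0]))
        assert two_outcome_p_plus(lgca.contact_guidance_rule(4.0), geom_1d, nb) == pytest.approx(0.5)

    def test_contact_guidance_2d_axis_bias(self, geom_2d):
        nb = Neighbourhood(
            configs=np.zeros((4, 4), dtype=np.uint8), field=np.array([1.0, 0.0])
        )
        d = lgca.reorientation_probabilities(
            [1, 0, 0, 0], nb, lgca.contact_guidance_rule(1.0), geom_2d
        )
        # channels: +x, +y, -x, -y — weights e, 1, e, 1
        expected = np.e / (2 * np.e + 2)
        assert d.probabilities[0] == pytest.approx(expected, abs=1e-12)
        assert d.probabilities[2] == pytest.approx(expected, abs=1e-12)
        assert d.probabilities[0] == pytest.approx(d.probabilities[2], abs=1e-14)

    def test_contact_guidance_invariant_under_field_flip(self, geom_2d):
        rule = lgca.contact_guidance_rule(1.3)
        nbp = Neighbourhood(configs=np.zeros((4, 4), dtype=np.uint8), field=np.array([0.6, 0.2]))
        nbm = Neighbourhood(configs=np.zeros((4, 4), dtype=np.uint8), field=np.array([-0.6, -0.2]))
        dp = lgca.reorientation_probabilities([1, 0, 0, 0], nbp, rule, geom_2d)
        dm = lgca.reorientation_probabilities([1, 0, 0, 0], nbm, rule, geom_2d)
        assert np.allclose(dp.probabilities, dm.probabilities, atol=1e-14)


class TestAlignment:
    def test_empty_neighbours_uniform(self, geom_1d):
        nb = Neighbourhood(configs=np.zeros((2, 2), dtype=np.uint8))
        assert two_outcome_p_plus(lgca.alignment_rule(2.0), geom_1d, nb) == pytest.approx(0.5)

    def test_neighbour_momentum_bias(self, geom_1d):
        nb = Neighbourhood(configs=np.array([[1, 0], [1, 0]]))  # D = +2
        p = two_outcome_p_plus(lgca.alignment_rule(1.0), geom_1d, nb)
        assert p == pytest.approx(np.exp(2) / (np.exp(2) + np.exp(-2)), abs=1e-12)

    def test_opposed_fluxes_cancel(self, geom_1d):
        nb = Neighbourhood(configs=np.array([[1, 0], [0, 1]]))  # D = 0
        assert two_outcome_p_plus(lgca.alignment_rule(3.0), geom_1d, nb) == pytest.approx(0.5)


class TestAdhesion:
    def test_balanced_neighbours_uniform(self, geom_1d):
        nb = Neighbourhood(configs=np.array([[1, 0], [0, 1]]))  # n = 1 both sides
        assert two_outcome_p_plus(lgca.adhesion_rule(2.0), geom_1d, nb) == pytest.approx(0.5)

    def test_density_gradient_bias(self, geom_1d_rest):
        nb = Neighbourhood(configs=np.array([[1, 1, 0, 0], [0, 0, 0, 0]]))  # G = +2
        d = lgca.reorientation_probabilities(
            [1, 0, 0, 0], nb, lgca.adhesion_rule(1.0), geom_1d_rest
        )
        p_move = d.probabilities[0] / (d.probabilities[0] + d.probabilities[1])
        assert p_move == pytest.approx(np.exp(2) / (np.exp(2) + np.exp(-2)), abs=1e-12)

    def test_reflection_equivariance(self, geom_1d_rest):
        rule = lgca.adhesion_rule(0.9)
        nb = Neighbourhood(configs=np.array([[1, 1, 1, 0], [0, 1, 0, 0]]))
        mirrored = Neighbourhood(
            configs=np.array([[0, 1, 0, 0], [1, 1, 1, 0]])[:, [1, 0, 2, 3]]
        )
        d = lgca.reorientation_probabilities([1, 0, 0, 0], nb, rule, geom_1d_rest)
        dm = lgca.reorientation_probabilities([0, 1, 0, 0], mirrored, rule, geom_1d_rest)
        # outcome (1,0,..) under the mirror corresponds to outcome (0,1,..)
        assert d.probabilities[0] == pytest.approx(dm.probabilities[1], abs=1e-12)
        assert d.probabilities[1] == pytest.approx(dm.probabilities[0], abs=1e-12)


class TestInvasion:
    def test_all_zero_sensitivities_random_walk(self, geom_1d_rest):
        nb = Neighbourhood(configs=np.array([[1, 0, 1, 0], [0, 1, 0, 0]]))
        rule = lgca.invasion_rule(0.0, 0.0, 0.0, 4.0)
        d = lgca.reorientation_probabilities([1, 0, 0, 0], nb, rule, geom_1d_rest)
        assert np.allclose(d.probabilities, 0.25)

    def test_logistic_gradient_value(self, geom_1d_rest):
        # right neighbour n=1, left empty, n_crit=2 -> g_agg = 0.5
        rule = lgca.invasion_rule(2.0, 0.0, 0.0, 2.0)
        nb = Neighbourhood(configs=np.array([[1, 0, 0, 0], [0, 0, 0, 0]]))
        fields = rule.neighbourhood_fields(nb, geom_1d_rest)
        assert fields["g_agg"] == pytest.approx(0.5)
        kin = _outcome_kinematics(geom_1d_rest, (1,))
        E = rule.outcome_energies(kin, {k: np.atleast_1d(v) for k, v in fields.items()})
        assert E[0][0] == pytest.approx(1.0)  # right-moving candidate

    def test_homeostatic_saturation(self, geom_1d_rest):
        # both neighbour densities equal n_crit -> logistic factor vanishes
        rule = lgca.invasion_rule(5.0, 0.0, 0.0, 2.0)
        nb = Neighbourhood(configs=np.array([[1, 1, 0, 0], [0, 1, 1, 0]]))
        fields = rule.neighbourhood_fields(nb, geom_1d_rest)
        assert fields["g_agg"] == pytest.approx(0.0)

    def test_reduces_to_adhesion_at_large_n_crit(self, geom_1d_rest):
        """With only the aggregation term and n_crit -> inf the invasion
        energy matches the plain adhesion energy on single-cell neighbourhoods."""
        beta = 1.7
        inv = lgca.invasion_rule(beta, 0.0, 0.0, 1e12)
        adh = lgca.adhesion_rule(beta)
        nb = Neighbourhood(configs=np.array([[1, 0, 0, 0], [0, 0, 0, 1]]))
        for s in ([1, 0, 0, 0], [1, 1, 0, 0], [1, 0, 1, 1]):
            di = lgca.reorientation_probabilities(s, nb, inv, geom_1d_rest)
            da = lgca.reorientation_probabilities(s, nb, adh, geom_1d_rest)
            assert np.abs(di.probabilities - da.probabilities).max() < 1e-9

    def test_requires_1d(self):
        state = lgca.create_lattice(2, [4, 4], a=1)
        with pytest.raises(CapabilityError):
            lgca.apply_reorientation(
                state, lgca.invasion_rule(1, 1, 1, 4.0), np.random.default_rng(0)
            )

    def test_n_crit_positive(self):
        with pytest.raises(ConfigurationError):
            lgca.invasion_rule(1, 1, 1, 0.0)


class TestFactory:
    @pytest.mark.parametrize(
        "name,params",
        [
            ("randomwalk", {}),
            ("chemotaxis", {"beta": 1.0}),
            ("haptotaxis", {"beta": 1.0}),
            ("contact_guidance", {"beta": 1.0}),
            ("alignment", {"beta": 1.0}),
            ("adhesion", {"beta": 1.0}),
            ("invasion", {"beta_agg": 1, "beta_align": 1, "beta_rest": 1, "n_crit": 4}),
        ],
    )
    def test_all_names_construct(self, name, params):
        assert make_rule(name, **params).name == name

    def test_unknown_name(self):
        with pytest.raises(ConfigurationError):
            make_rule("levitation")
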