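import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import chisquare

import lgca
from lgca.errors import CapabilityError, ConfigurationError
from lgca.operators import DemographicRates, _outcome_table
from lgca.rules import Neighbourhood


class TestEnumerateOutcomes:
    @pytest.mark.parametrize(
        "n,K,expected",
        [(1, 2, 2), (2, 4, 6), (0, 3, 1), (4, 4, 1), (3, 6, 20)],
    )
    def test_counts(self, n, K, expected):
        table = lgca.enumerate_outcomes(n, K)
        assert table.shape == (expected, K)
        assert np.all(table.sum(axis=1) == n)
        assert expected == comb(K, n)

    def test_multi_phenotype_product(self):
        table = lgca.enumerate_outcomes((1, 2), 3)
        assert table.shape == (3 * 3, 6)
        blocks = table.reshape(-1, 2, 3)
        assert np.all(blocks[:, 0].sum(axis=1) == 1)
        assert np.all(blocks[:, 1].sum(axis=1) == 2)

    def test_canonical_order_deterministic(self):
        t1 = lgca.enumerate_outcomes(2, 4)
        t2 = lgca.enumerate_outcomes(2, 4)
        assert np.array_equal(t1, t2)
        # lexicographic by occupied channel indices
        assert np.array_equal(t1[0], [1, 1, 0, 0])

    def test_enumeration_bound(self):
        with pytest.raises(CapabilityError):
            _outcome_table(17, (2,))


class TestReorientationProbabilities:
    def test_zero_sensitivity_uniform(self, geom_1d_rest):
        nb = Neighbourhood(configs=np.eye(4, dtype=np.uint8)[:2])
        d = lgca.reorientation_probabilities(
            [1, 0, 1, 0], nb, lgca.adhesion_rule(0.0), geom_1d_rest
        )
        assert np.allclose(d.probabilities, 1 / 6)

    def test_two_outcome_boltzmann_ratio(self, geom_1d):
        # signal 1 at the right neighbour: G_sig = +1, beta = 1
        nb = Neighbourhood(
            configs=np.zeros((2, 2), dtype=np.uint8), signal=np.array([1.0, 0.0])
        )
        d = lgca.reorientation_probabilities(
            [1, 0], nb, lgca.chemotaxis_rule(1.0), geom_1d
        )
        assert d.probabilities[0] == pytest.approx(
            np.exp(1) / (np.exp(1) + np.exp(-1)), abs=1e-12
        )

    def test_probabilities_normalised(self, geom_1d_rest):
        nb = Neighbourhood(configs=np.array([[1, 1, 1, 0], [0, 1, 0, 0]]))
        d = lgca.reorientation_probabilities(
            [1, 1, 0, 0], nb, lgca.adhesion_rule(2.5), geom_1d_rest
        )
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(d.probabilities >= 0)

    def test_beta_to_zero_limit_total_variation(self, geom_1d_rest):
        """Every rule collapses onto the uniform random walk as beta -> 0."""
        nb = Neighbourhood(
            configs=np.array([[1, 1, 1, 0], [0, 1, 0, 1]]),
            signal=np.array([2.0, 0.5]),
            field=np.array([0.8]),
        )
        rules = [
            lgca.chemotaxis_rule(1e-12),
            lgca.haptotaxis_rule(1e-12),
            lgca.contact_guidance_rule(1e-12),
            lgca.alignment_rule(1e-12),
            lgca.adhesion_rule(1e-12),
            lgca.invasion_rule(1e-12, 1e-12, 1e-12, 3.0),
        ]
        for rule in rules:
            d = lgca.reorientation_probabilities([1, 0, 1, 0], nb, rule, geom_1d_rest)
            tv = 0.5 * np.abs(d.probabilities - 1 / 6).sum()
            assert tv < 1e-9, rule.name


class TestApplyReorientation:
    def test_mass_conserved_exactly(self):
        state = lgca.create_lattice(1, [40], a=2)
        state = lgca.initialize_random(state, 1.5, 0)
        before = state.total_cells()
        out = lgca.apply_reorientation(
            state, lgca.adhesion_rule(3.0), np.random.default_rng(1)
        )
        assert out.total_cells() == before
        # per-node counts conserved too
        assert np.array_equal(out.density(), state.density())

    def test_empty_lattice_unchanged(self):
        state = lgca.create_lattice(1, [10], a=1)
        out = lgca.apply_reorientation(
            state, lgca.random_walk_rule(), np.random.default_rng(0)
        )
        assert out.total_cells() == 0

    def test_same_seed_identical(self):
        state = lgca.create_lattice(2, [6, 6], a=1)
        state = lgca.initialize_random(state, 1.0, 5)
        o1 = lgca.apply_reorientation(
            state, lgca.alignment_rule(1.0), np.random.default_rng(9)
        )
        o2 = lgca.apply_reorientation(
            state, lgca.alignment_rule(1.0), np.random.default_rng(9)
        )
        assert np.array_equal(o1.occupancy, o2.occupancy)

    def test_sampling_matches_enumeration_adhesion(self, geom_1d_rest):
        """Empirical outcome frequencies over many identical neighbourhoods,
        produced by the full synchronous update, match the enumerated
        Boltzmann distribution (chi-square)."""
        from conftest import tiled_1d_state

        s = [1, 1, 0, 0]
        s_left = [0, 0, 1, 0]
        s_right = [1, 1, 0, 1]
        state = tiled_1d_state(s, s_left, s_right, n_tiles=20_000, a=2)
        rule = lgca.adhesion_rule(0.8)
        out = lgca.apply_reorientation(state, rule, np.random.default_rng(17))
        nb = Neighbourhood(
            configs=np.array([s_right, s_left], dtype=np.uint8)  # order: +1, -1
        )
        dist = lgca.reorientation_probabilities(s, nb, rule, geom_1d_rest)
        key = {tuple(row): i for i, row in enumerate(dist.outcomes)}
        samples = out.occupancy[2::5]
        counts = np.zeros(len(key))
        for row in samples:
            counts[key[tuple(row)]] += 1
        res = chisquare(counts, dist.probabilities * samples.shape[0])
        assert res.pvalue > 0.01


class TestPropagation:
    def test_moving_cell_translocates(self):
        state = lgca.create_lattice(1, [3])
        state.occupancy[0, 0] = 1  # +1 channel at node 0
        out = lgca.apply_propagation(state)
        assert out.occupancy[1, 0] == 1 and out.occupancy[0, 0] == 0
        assert out.time_step == 1

    def test_resting_cell_stays(self):
        state = lgca.create_lattice(1, [3], a=1)
        state.occupancy[1, 2] = 1
        out = lgca.apply_propagation(state)
        assert out.occupancy[1, 2] == 1

    def test_total_momentum_conserved(self):
        state = lgca.create_lattice(2, [7, 7], a=1)
        state = lgca.initialize_random(state, 2.0, 3)
        before = state.flux().sum(axis=(0, 1))
        after = lgca.apply_propagation(state).flux().sum(axis=(0, 1))
        assert np.array_equal(before, after)


class TestBirthDeath:
    def test_zero_rates_identity(self):
        state = lgca.create_lattice(1, [10], a=1)
        state = lgca.initialize_random(state, 1.0, 0)
        out = lgca.apply_birth_death(
            state, DemographicRates(), np.random.default_rng(0)
        )
        assert np.array_equal(out.occupancy, state.occupancy)

    def test_certain_death_empties_lattice(self):
        state = lgca.create_lattice(1, [10], a=1)
        state = lgca.initialize_random(state, 2.0, 0)
        out = lgca.apply_birth_death(
            state, DemographicRates(death=1.0), np.random.default_rng(0)
        )
        assert out.total_cells() == 0

    def test_birth_blocked_at_capacity(self):
        state = lgca.create_lattice(1, [4], a=0)
        state.occupancy[:] = 1  # all nodes full
        out = lgca.apply_birth_death(
            state, DemographicRates(birth=1.0), np.random.default_rng(0)
        )
        assert out.total_cells() == state.total_cells()

    def test_invalid_rates(self):
        with pytest.raises(ConfigurationError):
            DemographicRates(birth=1.5)


class TestPhenotypeSwitch:
    def test_single_phenotype_noop(self):
        state = lgca.create_lattice(1, [5], a=1)
        state = lgca.initialize_random(state, 1.0, 0)
        out = lgca.apply_phenotype_switch(state, None, np.random.default_rng(0))
        assert np.array_equal(out.occupancy, state.occupancy)

    def test_identity_matrix_noop(self):
        state = lgca.create_lattice(1, [6], a=0, phenotypes=2)
        state = lgca.initialize_random(state, 1.0, 2)
        out = lgca.apply_phenotype_switch(
            state, np.zeros((2, 2)), np.random.default_rng(0)
        )
        assert np.array_equal(out.occupancy, state.occupancy)

    def test_certain_switch_exchanges_labels(self):
        state = lgca.create_lattice(1, [6], a=0, phenotypes=2)
        # phenotype 0 cells only -> all target channels free
        state.occupancy[:, 0] = 1
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = lgca.apply_phenotype_switch(state, m, np.random.default_rng(0))
        assert out.total_cells() == state.total_cells()
        occ = out.per_phenotype()
        assert occ[..., 0, :].sum() == 0 and occ[..., 1, :].sum() == 6

    def test_rows_over_one_rejected(self):
        state = lgca.create_lattice(1, [4], a=0, phenotypes=2)
        with pytest.raises(ConfigurationError):
            lgca.apply_phenotype_switch(
                state, np.array([[0.7, 0.7], [0.0, 0.0]]), np.random.default_rng(0)
            )


class TestRun:
    def test_zero_steps_trajectory(self):
        state = lgca.create_lattice(1, [8], a=0)
        traj = lgca.run(state, lgca.random_walk_rule(), 0, 1)
        assert traj.occupancy.shape[0] == 1

    def test_mass_conservation_long_run(self):
        state = lgca.create_lattice(1, [20], a=2)
        state = lgca.initialize_random(state, 1.2, 4)
        traj = lgca.run(state, lgca.adhesion_rule(2.0), 200, 11)
        counts = traj.density().sum(axis=1)
        assert np.all(counts == counts[0])

    def test_run_determinism(self):
        state = lgca.create_lattice(1, [15], a=1)
        state = lgca.initialize_random(state, 1.0, 8)
        t1 = lgca.run(state, lgca.alignment_rule(0.5), 20, 99)
        t2 = lgca.run(state, lgca.alignment_rule(0.5), 20, 99)
        assert np.array_equal(t1.occupancy, t2.occupancy)

    def test_single_cell_msd_diffusive(self):
        """Unbiased walkers show linearly growing mean-squared displacement.

        Independent single cells are spaced far enough apart on one lattice
        that they cannot meet within the run, giving many replicates of a
        single-cell random walk in one simulation.
        """
        n_walkers, spacing, steps = 1000, 700, 300
        L = n_walkers * spacing
        state = lgca.create_lattice(1, [L], a=0)
        starts = np.arange(n_walkers) * spacing + spacing // 2
        state.occupancy[starts, 0] = 1
        rng = np.random.default_rng(2)
        positions = np.empty((steps + 1, n_walkers), dtype=np.int64)
        positions[0] = starts
        current = state
        rule = lgca.random_walk_rule()
        for k in range(steps):
            current = lgca.step(current, rule, rng)
            pos = np.flatnonzero(current.density())
            positions[k + 1] = pos
        diffs = positions[1:] - positions[:-1]
        diffs = (diffs + L // 2) % L - L // 2  # minimal-image per-step moves
        assert set(np.unique(diffs)) <= {-1, 0, 1}
        disp = np.cumsum(diffs, axis=0)
        msd = (disp.astype(float) ** 2).mean(axis=1)
        t = np.arange(1, steps + 1)
        slope, intercept = np.polyfit(t, msd, 1)
        pred = slope * t + intercept
        r2 = 1 - np.sum((msd - pred) ** 2) / np.sum((msd - msd.mean()) ** 2)
        assert r2 > 0.99
        assert slope == pytest.approx(1.0, rel=0.1)
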