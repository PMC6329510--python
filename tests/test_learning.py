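"""The three learning phases, the plateau maps, and the orchestration contract."""

import copy
import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import cosmo
from cosmo.learning import (
    LearningSchedule,
    invert_motor,
    motor_step_communicative,
    motor_step_imitative,
    plateau,
    plateau_all,
    run_learning,
    sensorimotor_step,
    sensory_step,
)


class TestSensoryPhase:
    def test_repertoire_converges_to_master_sounds(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        rng = np.random.default_rng(2)
        for _ in range(7000):
            sensory_step(agent, master, rng)
        err = np.linalg.norm(agent.sensory.means - master.sensory_means, axis=1)
        assert np.all(err < 0.1)

    def test_vowel_draws_are_uniform(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        rng = np.random.default_rng(4)
        total = 7000
        for _ in range(total):
            sensory_step(agent, master, rng)
        counts = agent.sensory.counts - 1.0  # remove the prior pseudo-count
        assert np.all(np.abs(counts - total / 7) < 4 * np.sqrt(total))

    def test_noiseless_single_step_copies_the_sound(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        quiet = copy.deepcopy(master)
        quiet.sigma_env = 0.0
        quiet.motor_variance = 1e-30
        quiet.__post_init__()
        agent = cosmo.init_learner(
            motor_grid, sensory_grid, pseudo_count=0.0
        ).attach_forward(forward)
        rng = np.random.default_rng(0)
        seen = set()
        while len(seen) < 7:
            o = sensory_step(agent, quiet, rng)
            seen.add(o)
        for o in range(7):
            assert agent.sensory.means[o] == pytest.approx(
                forward(quiet.motor_means[o]), abs=1e-9
            )


class TestAccommodation:
    def test_inversion_weights_normalize(self, trained_agent):
        w = invert_motor(trained_agent, np.array([4.5, 11.0]))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= 0)

    def test_inversion_finds_preimage_after_training(self, forward, trained_agent):
        rng = np.random.default_rng(9)
        for m in rng.uniform(-0.8, 0.8, size=(20, 3)):
            s = forward(m)
            w = invert_motor(trained_agent, s)
            best = trained_agent.motor_grid.coords[int(np.argmax(w))]
            assert np.linalg.norm(forward(best) - s) < 0.5

    def test_visited_cells_learn_their_own_sound(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        rng = np.random.default_rng(6)
        steps = 5000
        for _ in range(steps):
            sensorimotor_step(agent, master, rng)
        prior_count = agent.sensorimotor.counts.min()  # untouched cells keep the prior
        visits = agent.sensorimotor.counts - prior_count
        assert visits.sum() == pytest.approx(steps)  # bookkeeping: one update per step
        well_visited = visits >= 20
        assert well_visited.sum() > 0
        err = np.linalg.norm(agent.sensorimotor.means - agent.grid_image, axis=1)
        assert np.mean(err[well_visited] < 0.2) >= 0.9

    def test_unvisited_cell_keeps_prior(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        before = agent.sensorimotor.means.copy()
        rng = np.random.default_rng(6)
        for _ in range(200):
            sensorimotor_step(agent, master, rng)
        untouched = agent.sensorimotor.counts == agent.sensorimotor.counts.min()
        assert untouched.any()
        assert np.array_equal(agent.sensorimotor.means[untouched], before[untouched])


def brute_force_plateau(agent, o):
    """Direct double loop over (motor cell, sensory cell) realizing the grid sum."""
    pts = agent.sensory_grid.points
    n_sens = pts.shape[0]
    dens = np.array(
        [
            [
                multivariate_normal.pdf(pts[p], agent.sensory.means[v], agent.sensory.cov(v))
                for v in range(7)
            ]
            for p in range(n_sens)
        ]
    )
    post_o = dens[:, o] / dens.sum(axis=1)
    A = np.empty(agent.motor_grid.n_cells)
    for c in range(agent.motor_grid.n_cells):
        pc = np.array(
            [
                multivariate_normal.pdf(pts[p], agent.sensorimotor.means[c], agent.sensorimotor.cov(c))
                for p in range(n_sens)
            ]
        )
        pc = pc / pc.sum()
        A[c] = pc @ post_o
    return A


@pytest.fixture(scope="module")
def tiny_trained_agent(forward):
    """A very small trained world for brute-force oracle comparisons."""
    motor_grid = cosmo.build_motor_grid(5)
    sensory_grid = cosmo.build_sensory_grid(forward, motor_grid, levels_f1=12, levels_f2=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        master = cosmo.fit_master(motor_grid, forward, calibration_draws=2000)
    agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
    rng = np.random.default_rng(13)
    run_learning(agent, master, LearningSchedule(2000, 2000, 0, "imitative"), rng)
    return agent, master


class TestPlateau:
    def test_bounded_between_zero_and_one(self, trained_agent):
        A = plateau_all(trained_agent)
        assert np.all(A >= 0.0) and np.all(A <= 1.0 + 1e-12)

    def test_matches_brute_force_on_reduced_grid(self, tiny_trained_agent):
        agent, _ = tiny_trained_agent
        for o in (0, 3, 6):
            assert plateau(agent, o) == pytest.approx(brute_force_plateau(agent, o), abs=1e-10)

    def test_high_plateau_cells_map_into_master_region(self, trained_agent, small_world):
        _, _, master = small_world
        A = plateau_all(trained_agent)
        for o in range(7):
            top = A[:, o] >= np.quantile(A[:, o], 0.9)
            labels = master.categorize(trained_agent.grid_image[top])
            # the top decile of acceptability should mostly be master-categorized as o
            assert np.mean(labels == o) > 0.5

    def test_riemann_sum_stability_under_grid_refinement(self, forward, small_world):
        # the default 59x73 grid resolves the sound kernels, so doubling the
        # resolution moves the acceptability map by less than 2%
        motor_grid, _, master = small_world
        grids = [
            cosmo.build_sensory_grid(forward, motor_grid, levels_f1=59, levels_f2=73),
            cosmo.build_sensory_grid(forward, motor_grid, levels_f1=118, levels_f2=146),
        ]
        A, A_fine = (
            plateau_all(cosmo.make_perfect_learner(master, motor_grid, g)) for g in grids
        )
        assert np.max(np.abs(A - A_fine)) < 0.02


class TestMotorPhase:
    def test_single_cell_grid_pins_the_repertoire(self, forward):
        motor_grid = cosmo.build_motor_grid(1)
        sensory_grid = cosmo.build_sensory_grid(
            cosmo.SurrogateForwardModel(), cosmo.build_motor_grid(5), levels_f1=12, levels_f2=15
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            master = cosmo.fit_master(
                cosmo.build_motor_grid(5), forward, calibration_draws=1000
            )
        agent = cosmo.init_learner(motor_grid, sensory_grid, pseudo_count=0.0).attach_forward(
            forward
        )
        rng = np.random.default_rng(1)
        for _ in range(50):
            motor_step_imitative(agent, master, rng)
        updated = agent.motor.counts > 0
        assert updated.any()
        assert np.allclose(agent.motor.means[updated], motor_grid.coords[0])

    def test_imitative_updates_are_uniform_over_vowels(self, forward, small_world, trained_agent):
        _, _, master = small_world
        agent = copy.deepcopy(trained_agent)
        before = agent.motor.counts.copy()
        rng = np.random.default_rng(17)
        steps = 1400
        for _ in range(steps):
            motor_step_imitative(agent, master, rng)
        counts = agent.motor.counts - before
        assert counts.sum() == pytest.approx(steps)
        assert np.all(np.abs(counts - steps / 7) < 4 * np.sqrt(steps))

    def test_communicative_draw_weights_match_brute_force(self, tiny_trained_agent):
        agent, master = tiny_trained_agent
        from cosmo.learning import _motor_log_density_at_cells, _normalize_log_weights

        A = plateau_all(agent)
        for o in (1, 5):
            with np.errstate(divide="ignore"):
                w = _normalize_log_weights(
                    _motor_log_density_at_cells(agent, o) + np.log(A[:, o])
                )
            dens = np.array(
                [
                    multivariate_normal.pdf(c, agent.motor.means[o], agent.motor.cov(o))
                    for c in agent.motor_grid.coords
                ]
            )
            expected = dens * A[:, o]
            expected = expected / expected.sum()
            assert w == pytest.approx(expected, abs=1e-10)

    def test_communicative_zero_plateau_falls_back_to_uniform(self, tiny_trained_agent):
        agent, master = tiny_trained_agent
        agent = copy.deepcopy(agent)
        plateaus = np.zeros((agent.motor_grid.n_cells, 7))
        rng = np.random.default_rng(3)
        # must not raise, and must still draw a valid cell
        o, k, accepted = motor_step_communicative(agent, master, rng, plateaus)
        assert 0 <= k < agent.motor_grid.n_cells

    def test_communicative_acceptance_rises(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        rng = np.random.default_rng(21)
        log = []
        run_learning(agent, master, LearningSchedule(4000, 4000, 4000, "communicative",
                                                     log_every=500), rng, progress=log)
        acc = [r["acceptance"] for r in log if r["phase"] == "motor_communicative"]
        assert np.mean(acc[-3:]) > np.mean(acc[:3])


class TestRunLearning:
    def test_same_seed_bit_identical(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        payloads = []
        for _ in range(2):
            agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
            rng = np.random.default_rng(31)
            run_learning(agent, master, LearningSchedule(500, 500, 500, "communicative"), rng)
            payloads.append(agent.to_json())
        assert payloads[0] == payloads[1]

    def test_different_seeds_differ_communicatively(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        means = []
        for seed in (1, 2):
            agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
            rng = np.random.default_rng(seed)
            run_learning(agent, master, LearningSchedule(1500, 1500, 1500, "communicative"), rng)
            means.append(agent.motor.means.copy())
        assert np.linalg.norm(means[0] - means[1]) > 0.0

    def test_missing_sensorimotor_phase_warns(self, forward, small_world):
        motor_grid, sensory_grid, master = small_world
        agent = cosmo.init_learner(motor_grid, sensory_grid).attach_forward(forward)
        with pytest.warns(UserWarning, match="prior-driven"):
            run_learning(
                agent, master, LearningSchedule(10, 0, 10, "imitative"),
                np.random.default_rng(0),
            )

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            LearningSchedule(motor_variant="telepathic")
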