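import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest, qmc

import srwpso.swarm as swarm
from srwpso.objectives import make_objective
from srwpso.swarm import (
    SwarmConfig,
    adaptive_weight,
    cauchy_sample,
    decay_factor,
    init_random_population,
    init_sobol_population,
    random_replacement,
    run_pso,
    run_srwpso,
    update_S,
    velocity_update,
    position_update,
)


def small_config(**kw):
    defaults = dict(dim=5, population_size=10, max_evaluations=2000, seed=0)
    defaults.update(kw)
    return SwarmConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(population_size=1),
            dict(max_evaluations=5, population_size=10),
            dict(v_max=0.0),
            dict(dim=0),
            dict(lower_bound=1.0, upper_bound=1.0),
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestInitialization:
    def test_random_population_in_bounds_and_seeded(self, rng):
        cfg = small_config()
        X = init_random_population(cfg, np.random.default_rng(3))
        assert X.shape == (10, 5)
        assert np.all((X >= -100) & (X <= 100))
        X2 = init_random_population(cfg, np.random.default_rng(3))
        assert np.array_equal(X, X2)

    def test_degenerate_box_collapses_to_lower_bound(self, rng):
        cfg = small_config(lower_bound=5.0, upper_bound=5.0 + 1e-12)
        X = init_random_population(cfg, rng)
        assert np.allclose(X, 5.0, atol=1e-10)

    @pytest.mark.filterwarnings("ignore:The balance properties")
    def test_sobol_affine_map(self):
        # bounds [0, 1]: rows are the raw unit-cube Sobol points, so the
        # same seed under any box must be the exact affine image
        cfg01 = small_config(lower_bound=0.0, upper_bound=1.0)
        raw = init_sobol_population(cfg01, np.random.default_rng(3))
        assert np.all((raw >= 0) & (raw <= 1))
        cfg = small_config()  # [-100, 100]
        X = init_sobol_population(cfg, np.random.default_rng(3))
        assert np.allclose(X, -100.0 + raw * 200.0)

    def test_sobol_lower_discrepancy_than_uniform(self):
        """Centered-L2 discrepancy of a 128x8 Sobol set beats the mean of
        50 uniform sets."""
        cfg = SwarmConfig(
            dim=8, population_size=128, max_evaluations=1000,
            lower_bound=0.0, upper_bound=1.0,
        )
        sob = init_sobol_population(cfg, np.random.default_rng(0))
        d_sob = qmc.discrepancy(sob, method="CD")
        gen = np.random.default_rng(42)
        d_unif = [
            qmc.discrepancy(gen.random((128, 8)), method="CD") for _ in range(50)
        ]
        assert d_sob < np.mean(d_unif)


class TestCauchy:
    def test_fixed_quantiles(self):
        class Fixed:
            def __init__(self, u):
                self.u = u

            def random(self, size=None):
                return self.u if size is None else np.full(size, self.u)

        assert cauchy_sample(Fixed(0.5)) == pytest.approx(0.0)
        assert cauchy_sample(Fixed(0.75)) == pytest.approx(1.0)

    def test_matches_closed_form_cdf(self, rng):
        draws = np.array([cauchy_sample(rng) for _ in range(100_000)])
        stat = kstest(draws, "cauchy").statistic
        assert stat < 0.01


class TestScalarUpdates:
    def test_decay_factor_endpoints_and_midpoint(self):
        assert decay_factor(0, 300_000) == 1.0
        assert decay_factor(300_000, 300_000) == 0.0
        assert decay_factor(150_000, 300_000) == 0.5
        with pytest.raises(ValueError):
            decay_factor(300_001, 300_000)

    def test_update_S(self):
        assert update_S(0.01, True) == pytest.approx(0.005)
        assert update_S(0.01, False) == pytest.approx(1.01)
        assert update_S(4.0, True) == pytest.approx(2.0)

    def test_adaptive_weight_guards(self, rng, monkeypatch):
        assert adaptive_weight(0, 100, 0.01, rng) == pytest.approx(1.0)
        assert adaptive_weight(100, 100, 0.01, rng) == 0.0
        # beta = 1 when the Cauchy draw is 0: pure linear decay
        monkeypatch.setattr(swarm, "cauchy_sample", lambda r: 0.0)
        assert adaptive_weight(30, 100, 5.0, rng) == pytest.approx(0.7)

    def test_adaptive_weight_capped(self, rng, monkeypatch):
        # a huge negative beta would overflow the power without the cap
        monkeypatch.setattr(swarm, "cauchy_sample", lambda r: 1e12)
        assert adaptive_weight(99, 100, 100.0, rng) == 10.0


class TestRandomReplacement:
    def test_identical_vectors_unchanged(self, rng):
        g = np.array([1.0, 2.0, 3.0])
        out = random_replacement(g.copy(), g, a=0.5, rng=rng)
        assert np.array_equal(out, g)

    def test_half_replacement_rate_at_zero_decay(self, rng):
        # P(Cauchy > 0) = 1/2, so a = 0 replaces half the coordinates
        n = 100_000
        pb = np.zeros(n)
        gb = np.ones(n)
        out = random_replacement(pb, gb, a=0.0, rng=rng)
        rate = out.mean()
        sigma = np.sqrt(0.25 / n)
        assert abs(rate - 0.5) < 3 * sigma

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            random_replacement(np.zeros(3), np.zeros(4), 0.5, rng)


class TestRowUpdates:
    def test_velocity_vanishing_attraction(self, rng):
        cfg = small_config()
        x = np.ones(5)
        v = np.full(5, 10.0)
        out = velocity_update(v, x, x, x, omega=1.0, config=cfg, rng=rng)
        assert np.allclose(out, 6.0)  # pure clamp of the inertia term
        out0 = velocity_update(v, x, x, x, omega=0.0, config=cfg, rng=rng)
        assert np.allclose(out0, 0.0)

    def test_position_update_clamps(self):
        cfg = small_config()
        assert position_update(np.array([1.0]), np.array([0.5]), cfg)[0] == 1.5
        assert position_update(np.array([99.0]), np.array([6.0]), cfg)[0] == 100.0
        x = np.array([2.0, -3.0])
        assert np.array_equal(position_update(x, np.zeros(2), cfg), x)


@pytest.mark.parametrize("runner", [run_pso, run_srwpso])
@pytest.mark.parametrize("name", ["sphere", "rastrigin"])
def test_optimizer_contracts(runner, name):
    """Budget, trace monotonicity, bound feasibility, seed determinism."""
    cfg = small_config(seed=11)
    spec = make_objective(name, 5)
    res = runner(spec, cfg)
    assert res.evaluations_used <= cfg.max_evaluations
    scores = [s for _, s in res.trace]
    assert all(b <= a for a, b in zip(scores, scores[1:]))
    assert res.trace[-1][1] == res.best_score
    assert np.all((res.best_position >= -100) & (res.best_position <= 100))
    res2 = runner(spec, cfg)
    assert res.trace == res2.trace
    assert np.array_equal(res.best_position, res2.best_position)


def test_pso_converges_on_2d_sphere():
    spec = make_objective("sphere", 2)
    finals = []
    for seed in range(10):
        cfg = SwarmConfig(dim=2, population_size=30, max_evaluations=5000, seed=seed)
        finals.append(run_pso(spec, cfg).best_score)
    assert np.median(finals) < 1e-2


def test_dim_mismatch_rejected():
    with pytest.raises(ValueError):
        run_pso(make_objective("sphere", 3), small_config(dim=5))


def test_srwpso_evaluation_schedule_with_rrs():
    """With the replacement pass on, each iteration spends 2N evaluations."""
    cfg = small_config(population_size=10, max_evaluations=210, use_rrs=True)
    spec = make_objective("sphere", 5)
    res = run_srwpso(spec, cfg)
    fes = [f for f, _ in res.trace]
    assert fes[0] == 10  # initial pass
    assert np.all(np.diff(fes) == 10)  # alternating RRS / move batches of N
    assert res.evaluations_used == 210


def test_srwpso_flags_off_equals_pso_step_for_step():
    """The ablation baseline reproduces canonical PSO exactly under a
    shared seed."""
    cfg = small_config(
        dim=5, max_evaluations=2000, seed=123,
        use_sobol=False, use_rrs=False, use_aws=False,
    )
    spec = make_objective("sphere", 5)
    a = run_pso(spec, cfg)
    b = run_srwpso(spec, cfg)
    assert a.trace == b.trace
    assert np.array_equal(a.best_position, b.best_position)
    assert a.best_score == b.best_score


def test_personal_best_can_degrade_but_global_best_cannot():
    """The replacement pass accepts worse personal bests (diversity
    injection); only the global best is monotone."""
    spec = make_objective("rastrigin", 5)
    cfg = small_config(seed=2, max_evaluations=3000)
    res = run_srwpso(spec, cfg)
    scores = [s for _, s in res.trace]
    assert all(b <= a for a, b in zip(scores, scores[1:]))


@given(st.integers(0, 1000), st.integers(1, 1000))
def test_decay_factor_in_unit_interval(fes, max_fes):
    if fes <= max_fes:
        assert 0.0 <= decay_factor(fes, max_fes) <= 1.0
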