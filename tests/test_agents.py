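"""Agent state, the four moves, observation error, and round resolution."""

import numpy as np
import pytest
from scipy import stats

from refinebandit.agents import (
    EXPLOIT,
    INNOVATE,
    OBSERVE,
    REFINE,
    Agent,
    ExploitRecord,
    ForfeitError,
    MoveDecision,
    StrategyView,
    apply_exploit,
    apply_innovate,
    apply_observe,
    apply_refine,
    build_model_info,
    resolve_round,
)
from refinebandit.config import SimulationConfig
from refinebandit.environment import RefinementConfig, increment_table
from refinebandit.strategies import Strategy, innovate_once, observe_exploit

from conftest import make_agent, make_env

INC100 = increment_table(RefinementConfig(r_max=100, p_max=125.0))


def exploiter_pool(env, specs):
    """Pool of ExploitRecords from (agent_id, behavior, payoff, level) specs."""
    pool = []
    for agent_id, behavior, payoff, level in specs:
        model = make_agent(agent_id, "model", repertoire={behavior: payoff}, levels={behavior: level})
        pool.append(ExploitRecord(model, behavior, float(payoff), level))
    return pool


class TestInnovate:
    def test_learns_the_single_missing_behavior(self, rng):
        env = make_env(np.arange(100))
        agent = make_agent(repertoire={b: 1.0 for b in range(100) if b != 42})
        assert apply_innovate(agent, env, rng) == 42
        assert agent.repertoire[42].recorded_payoff == 42.0
        assert agent.repertoire[42].refinement_level == 0

    def test_full_repertoire_gains_nothing(self, rng):
        env = make_env(np.arange(100))
        agent = make_agent(repertoire={b: 1.0 for b in range(100)})
        assert apply_innovate(agent, env, rng) is None
        assert len(agent.repertoire) == 100

    def test_choice_is_uniform_over_unknown(self, rng):
        env = make_env(np.ones(100, dtype=int))
        counts = np.zeros(100)
        for _ in range(20_000):
            agent = make_agent()
            counts[apply_innovate(agent, env, rng)] += 1
        assert stats.chisquare(counts).pvalue > 0.001

    def test_exact_payoff_at_level_zero(self, rng):
        env = make_env([17])
        agent = make_agent()
        apply_innovate(agent, env, rng)
        entry = agent.repertoire[0]
        assert entry.recorded_payoff == 17.0 and entry.refinement_level == 0


class TestExploit:
    def test_unrefined_payoff_equals_basic(self):
        env = make_env([9, 4])
        agent = make_agent(repertoire={1: 4.0})
        assert apply_exploit(agent, 1, env, INC100) == 4.0
        assert agent.total_exploit_payoff == 4.0

    def test_stale_record_corrected_by_exploiting(self):
        env = make_env([3])
        agent = make_agent(repertoire={0: 40.0})  # learned before the world changed
        payoff = apply_exploit(agent, 0, env, INC100)
        assert payoff == 3.0
        assert agent.repertoire[0].recorded_payoff == 3.0

    def test_repeat_exploit_in_static_world_is_identical(self):
        env = make_env([9])
        agent = make_agent(repertoire={0: 9.0}, levels={0: 7})
        assert apply_exploit(agent, 0, env, INC100) == apply_exploit(agent, 0, env, INC100)

    def test_refined_payoff_includes_increment(self):
        env = make_env([9])
        agent = make_agent(repertoire={0: 9.0}, levels={0: 10})
        assert apply_exploit(agent, 0, env, INC100) == pytest.approx(9.0 + INC100[10])


class TestRefine:
    def test_level_zero_to_one(self):
        env = make_env([5])
        agent = make_agent(repertoire={0: 5.0})
        payoff = apply_refine(agent, 0, env, INC100, r_max=100)
        assert agent.repertoire[0].refinement_level == 1
        assert payoff == pytest.approx(5.0 + INC100[1])

    def test_saturates_at_r_max(self):
        env = make_env([5])
        agent = make_agent(repertoire={0: 5.0}, levels={0: 100})
        payoff = apply_refine(agent, 0, env, INC100, r_max=100)
        assert agent.repertoire[0].refinement_level == 100
        assert payoff == pytest.approx(5.0 + 125.0)

    def test_r_max_refines_reach_basic_plus_p_max(self):
        env = make_env([5])
        agent = make_agent(repertoire={0: 5.0})
        for _ in range(100):
            payoff = apply_refine(agent, 0, env, INC100, r_max=100)
        assert payoff == pytest.approx(5.0 + 125.0, rel=1e-12)


class TestObserve:
    def setup_method(self):
        self.cfg = SimulationConfig(extension="none", n_observe=1, p_copyFail=0.0)
        self.strategy = observe_exploit()

    def test_copy_fail_one_learns_nothing(self, rng):
        cfg = SimulationConfig(extension="none", n_observe=5, p_copyFail=1.0)
        env = make_env([10])
        pool = exploiter_pool(env, [(1, 0, 10.0, 0)])
        agent = make_agent()
        learned = apply_observe(agent, pool, cfg, self.strategy, rng, rng)
        assert learned == [] and agent.repertoire == {}

    def test_zero_payoff_estimated_exactly(self, rng):
        env = make_env([0])
        pool = exploiter_pool(env, [(1, 0, 0.0, 0)])
        agent = make_agent()
        learned = apply_observe(agent, pool, self.cfg, self.strategy, rng, rng)
        assert learned == [(0, 0.0)]

    def test_estimates_are_poisson_about_truth(self, rng):
        env = make_env([40])
        estimates = []
        for _ in range(20_000):
            agent = make_agent()
            pool = exploiter_pool(env, [(1, 0, 40.0, 0)])
            apply_observe(agent, pool, self.cfg, self.strategy, rng, rng)
            estimates.append(agent.repertoire[0].recorded_payoff)
        estimates = np.asarray(estimates)
        se = np.sqrt(40.0 / len(estimates))
        assert abs(estimates.mean() - 40.0) < 3 * se
        assert estimates.var() == pytest.approx(40.0, rel=0.1)

    def test_copies_carry_the_models_refinement_level(self, rng):
        env = make_env([10])
        pool = exploiter_pool(env, [(1, 0, 10.0 + INC100[8], 8)])
        agent = make_agent()
        apply_observe(agent, pool, self.cfg, self.strategy, rng, rng)
        assert agent.repertoire[0].refinement_level == 8

    def test_samples_n_observe_distinct_models(self, rng):
        cfg = SimulationConfig(extension="none", n_observe=5, p_copyFail=0.0)
        env = make_env(np.arange(10) + 1)
        pool = exploiter_pool(env, [(i, i, float(i + 1), 0) for i in range(10)])
        agent = make_agent()
        learned = apply_observe(agent, pool, cfg, self.strategy, rng, rng)
        assert len(learned) == 5
        assert len({b for b, _ in learned}) == 5

    def test_small_pool_observes_everyone(self, rng):
        cfg = SimulationConfig(extension="none", n_observe=5, p_copyFail=0.0)
        env = make_env([1, 2])
        pool = exploiter_pool(env, [(0, 0, 1.0, 0), (1, 1, 2.0, 0)])
        agent = make_agent()
        assert len(apply_observe(agent, pool, cfg, self.strategy, rng, rng)) == 2

    def test_successful_copy_increments_times_observed(self, rng):
        env = make_env([10])
        pool = exploiter_pool(env, [(1, 0, 10.0, 0)])
        agent = make_agent()
        apply_observe(agent, pool, self.cfg, self.strategy, rng, rng)
        assert pool[0].agent.times_observed == 1


class TestModelInfo:
    def test_empty_pool(self, rng):
        assert build_model_info([], rng) == []

    def test_zero_truths_estimated_exactly(self, rng):
        model = make_agent(1)
        pool = [ExploitRecord(model, 0, 0.0, 0)]
        (info,) = build_model_info(pool, rng)
        assert (info.age_estimate, info.total_payoff_estimate) == (0, 0)

    def test_offspring_estimate_unbiased(self, rng):
        model = make_agent(1)
        model.n_offspring = 4
        pool = [ExploitRecord(model, 0, 1.0, 0)]
        draws = [build_model_info(pool, rng)[0].n_offspring_estimate for _ in range(5000)]
        se = np.sqrt(4.0 / len(draws))
        assert abs(np.mean(draws) - 4.0) < 3 * se


def run_one_round(population, env, cfg, strategies, rng, move_log=None):
    inc = increment_table(RefinementConfig(r_max=cfg.r_max, p_max=cfg.p_max))
    return resolve_round(
        population, env, cfg, strategies, inc, rng, rng, rng, move_log=move_log
    )


class TestResolveRound:
    def test_no_exploiters_means_no_models(self, rng, cfg):
        env = make_env(np.arange(100))
        pop = [Agent(0, "innovateOnce", 0), Agent(1, "observeExploit", 0)]
        strategies = {"innovateOnce": innovate_once(), "observeExploit": observe_exploit()}
        outcome = run_one_round(pop, env, cfg, strategies, rng)
        assert outcome.move_counts[INNOVATE] == 1 and outcome.move_counts[OBSERVE] == 1
        assert pop[1].repertoire == {}  # the lone observer learned nothing

    def test_single_exploiter_updates_record(self, rng, cfg):
        env = make_env([11] + [0] * 99)
        agent = make_agent(0, "innovateOnce", repertoire={0: 5.0})
        outcome = run_one_round([agent], env, cfg, {"innovateOnce": innovate_once()}, rng)
        assert agent.payoffs[-1] == 11.0 and agent.repertoire[0].recorded_payoff == 11.0
        assert outcome.mean_refinement_performed == 0.0

    def test_model_pool_is_same_deme_exploiters_only(self, rng):
        cfg = SimulationConfig(extension="spatial", n_demes=2, p_copyFail=0.0, n_observe=5)
        env = make_env([[7] * 100, [9] * 100])
        exploiter = make_agent(0, "innovateOnce", deme=0, repertoire={3: 7.0})
        near = Agent(1, "observeExploit", 0)
        far = Agent(2, "observeExploit", 1)
        strategies = {"innovateOnce": innovate_once(), "observeExploit": observe_exploit()}
        run_one_round([exploiter, near, far], env, cfg, strategies, rng)
        assert 3 in near.repertoire
        assert far.repertoire == {}

    def test_illegal_move_forfeits_round(self, rng, cfg):
        env = make_env(np.arange(100))
        bad = Strategy("bad", lambda v, r: MoveDecision(EXPLOIT, 0))  # exploits the unknown
        agent = Agent(0, "bad", 0)
        outcome = run_one_round([agent], env, cfg, {"bad": bad}, rng)
        assert outcome.forfeits and agent.moves == ["FORFEIT"]
        assert agent.total_exploit_payoff == 0.0 and agent.repertoire == {}
        assert agent.rounds_alive == 1  # the round still counts

    def test_strategy_exception_forfeits_or_aborts(self, rng, cfg):
        env = make_env(np.arange(100))

        def boom(view, r):
            raise RuntimeError("entry bug")

        agent = Agent(0, "boom", 0)
        outcome = run_one_round([agent], env, cfg, {"boom": Strategy("boom", boom)}, rng)
        assert agent.n_forfeits == 1 and "entry bug" in outcome.forfeits[0][1]

        strict = cfg.model_copy(update={"strict": True})
        with pytest.raises(ForfeitError):
            run_one_round([Agent(1, "boom", 0)], env, strict, {"boom": Strategy("boom", boom)}, rng)

    def test_refine_outside_cumulative_is_illegal(self, rng, cfg):
        env = make_env(np.arange(100))
        refiner = Strategy("r", lambda v, r: MoveDecision(REFINE, 0))
        agent = make_agent(0, "r", repertoire={0: 1.0})
        outcome = run_one_round([agent], env, cfg, {"r": refiner}, rng)
        assert outcome.forfeits

    def test_repertoires_never_shrink(self, rng):
        cfg = SimulationConfig(extension="cumulative", p_c=0.1, p_copyFail=0.2, n_observe=2)
        env = make_env(np.arange(100), change_prob=0.1)
        strategies = {"innovateOnce": innovate_once(), "observeExploit": observe_exploit()}
        pop = [Agent(i, "innovateOnce" if i % 2 else "observeExploit", 0) for i in range(10)]
        sizes = [0] * 10
        for _ in range(60):
            run_one_round(pop, env, cfg, strategies, rng)
            env.change_(rng)
            for i, a in enumerate(pop):
                assert len(a.repertoire) >= sizes[i]
                sizes[i] = len(a.repertoire)


class TestInformationHiding:
    def test_view_exposes_no_refinement_or_engine_state(self, cumulative_cfg):
        agent = make_agent(repertoire={0: 5.0, 3: 2.0}, levels={0: 9})
        view = StrategyView(agent, cumulative_cfg)
        assert view.repertoire == {0: 5.0, 3: 2.0}  # payoffs only, no levels
        assert set(StrategyView.__slots__) == {
            "rounds_alive",
            "moves",
            "behaviors",
            "payoffs",
            "demes",
            "migrations",
            "repertoire",
            "params",
        }

    def test_newborn_view_is_naive(self, cfg):
        view = StrategyView(Agent(0, "x", 0), cfg)
        assert view.rounds_alive == 0 and view.repertoire == {} and view.moves == []
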