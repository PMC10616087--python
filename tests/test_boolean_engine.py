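"""Continuous-time Boolean engine: parser, logic, propensities, Gillespie."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hybridboss.boolean_engine import (
    EngineSettings, InitialCondition, MutantSpec, NetworkState, ParseError,
    ensemble_run, evaluate_logic, gillespie_step, parse_network, propensities,
    run_interval, serialize_network,
)
from hybridboss.fixtures import CASCADE_BND, CASCADE_CFG


def make_state(network, **bits):
    arr = np.zeros(network.n_nodes)
    for name, value in bits.items():
        arr[network.index[name]] = float(value)
    return NetworkState(arr)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParser:
    def test_minimal_self_referential_node(self):
        bnd = "node A { logic = A; rate_up = @logic ? 1 : 0; rate_down = @logic ? 0 : 1; }"
        network, init = parse_network(bnd)
        assert [n.name for n in network.nodes] == ["A"]
        state = make_state(network, A=1)
        assert evaluate_logic(network, state, "A") is True

    def test_cfg_parameter_and_istate(self):
        bnd = "node A { logic = A; rate_up = $k; rate_down = 1; }"
        network, init = parse_network(bnd, "$k = 2.5; A.istate = 1;")
        assert network.parameters["k"] == 2.5
        assert init.probability("A") == 1.0

    def test_cfg_overrides_bnd_parameter_defaults(self):
        bnd = "node A { logic = A; rate_up = $k; rate_down = 1; }"
        network, _ = parse_network(bnd, "$k = 1.0;")
        network2, _ = parse_network(bnd, "$k = 7.0;")
        assert network.parameters["k"] == 1.0
        assert network2.parameters["k"] == 7.0

    def test_cascade_roundtrip_through_serialiser(self):
        network, init = parse_network(CASCADE_BND, CASCADE_CFG)
        assert network.n_nodes == 3
        assert network.input_nodes == ["Input"]
        assert network.output_nodes == ["Death"]
        bnd2, cfg2 = serialize_network(network, init)
        network2, init2 = parse_network(bnd2, cfg2)
        bnd3, cfg3 = serialize_network(network2, init2)
        assert (bnd2, cfg2) == (bnd3, cfg3)
        assert [n.name for n in network2.nodes] == [n.name for n in network.nodes]
        assert network2.parameters == network.parameters
        assert init2.probabilities == init.probabilities

    def test_undeclared_identifier_is_named(self):
        with pytest.raises(ParseError, match="Ghost"):
            parse_network("node A { logic = Ghost; rate_up = 1; rate_down = 1; }")

    def test_duplicate_node_rejected(self):
        bnd = ("node A { logic = A; rate_up = 1; rate_down = 1; }\n"
               "node A { logic = A; rate_up = 1; rate_down = 1; }")
        with pytest.raises(ParseError, match="duplicate"):
            parse_network(bnd)

    def test_negative_literal_rate_rejected(self):
        with pytest.raises(ParseError, match="negative"):
            parse_network("node A { logic = A; rate_up = -1; rate_down = 1; }")

    def test_unassigned_parameter_rejected(self):
        with pytest.raises(ParseError, match="never assigned"):
            parse_network("node A { logic = A; rate_up = $nope; rate_down = 1; }")


# ---------------------------------------------------------------------------
# Logic evaluation
# ---------------------------------------------------------------------------

class TestLogic:
    @pytest.mark.parametrize("a, b, expected", [(1, 0, True), (1, 1, False),
                                                (0, 0, False), (0, 1, False)])
    def test_and_not(self, a, b, expected):
        bnd = ("node A { logic = A; rate_up = 1; rate_down = 1; }\n"
               "node B { logic = B; rate_up = 1; rate_down = 1; }\n"
               "node C { logic = A AND NOT B; rate_up = 1; rate_down = 1; }")
        network, _ = parse_network(bnd)
        state = make_state(network, A=a, B=b)
        assert evaluate_logic(network, state, "C") is expected

    def test_random_expressions_against_truth_table(self):
        """Randomly composed 4-variable expressions agree with a direct
        Python-boolean oracle over all 16 assignments."""
        rng = np.random.default_rng(7)
        names = ["A", "B", "C", "D"]

        def gen(depth):
            if depth == 0 or rng.random() < 0.3:
                name = names[rng.integers(4)]
                return name, lambda env, n=name: env[n]
            op = rng.choice(["and", "or", "not"])
            if op == "not":
                text, fn = gen(depth - 1)
                return f"NOT ({text})", lambda env, f=fn: not f(env)
            lt, lf = gen(depth - 1)
            rt, rf = gen(depth - 1)
            if op == "and":
                return f"({lt}) AND ({rt})", lambda env, l=lf, r=rf: l(env) and r(env)
            return f"({lt}) OR ({rt})", lambda env, l=lf, r=rf: l(env) or r(env)

        for _ in range(25):
            text, oracle = gen(3)
            decls = "\n".join(
                f"node {n} {{ logic = {n}; rate_up = 1; rate_down = 1; }}" for n in names)
            bnd = decls + f"\nnode X {{ logic = {text}; rate_up = 1; rate_down = 1; }}"
            network, _ = parse_network(bnd)
            for values in itertools.product([0, 1], repeat=4):
                env = dict(zip(names, [bool(v) for v in values]))
                state = make_state(network, **dict(zip(names, values)))
                assert evaluate_logic(network, state, "X") == oracle(env), (text, values)


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

def _cascade_oracle_rates(bits):
    """Independent hand-coded flip rates of the 3-node cascade (unit rates)
    for state (Input, Mediator, Death)."""
    inp, med, death = bits
    r_input = 0.0
    r_med = (0.0 if med else 1.0) if inp else (1.0 if med else 0.0)
    r_death = 1.0 if (med and not death) else 0.0
    return [r_input, r_med, r_death]


class TestPropensities:
    def test_rate_up_follows_logic(self):
        bnd = ("node A { logic = A; rate_up = 0; rate_down = 0; }\n"
               "node B { logic = A; rate_up = @logic ? 1 : 0; rate_down = 0; }")
        network, _ = parse_network(bnd)
        rates = propensities(network, make_state(network, A=1, B=0))
        assert rates[network.index["B"]] == 1.0
        rates = propensities(network, make_state(network, A=0, B=0))
        assert rates[network.index["B"]] == 0.0

    def test_mutant_pins_rate_to_zero(self, cascade):
        state = make_state(cascade, Input=1, Mediator=0)
        rates = propensities(cascade, state, [MutantSpec("Mediator", True)])
        assert rates[cascade.index["Mediator"]] == 0.0

    def test_generator_matches_exhaustive_enumeration(self, cascade):
        """For every one of the 8 states, propensities() equals the
        hand-enumerated CTMC generator row of the cascade."""
        for bits in itertools.product([0, 1], repeat=3):
            state = make_state(cascade, Input=bits[0], Mediator=bits[1], Death=bits[2])
            got = propensities(cascade, state).tolist()
            assert got == _cascade_oracle_rates(bits), bits

    def test_fixed_points_match_enumeration(self, cascade):
        fixed = {bits for bits in itertools.product([0, 1], repeat=3)
                 if sum(_cascade_oracle_rates(bits)) == 0.0}
        got = set()
        for bits in itertools.product([0, 1], repeat=3):
            state = make_state(cascade, Input=bits[0], Mediator=bits[1], Death=bits[2])
            if propensities(cascade, state).sum() == 0.0:
                got.add(bits)
        assert got == fixed
        assert (0, 0, 0) in got  # all-off resting state is absorbing


# ---------------------------------------------------------------------------
# Gillespie dynamics
# ---------------------------------------------------------------------------

class TestGillespie:
    def test_fixed_point_returns_infinite_dwell(self, cascade, rng):
        state = make_state(cascade)  # all off: absorbing
        new, dwell = gillespie_step(cascade, state, [], rng)
        assert math.isinf(dwell)
        assert (new.bits == state.bits).all()

    def test_dwell_times_are_exponential(self, rng):
        k = 2.0
        bnd = f"node A {{ logic = A; rate_up = {k}; rate_down = {k}; }}"
        network, _ = parse_network(bnd)
        dwells = []
        state = make_state(network)
        for _ in range(10_000):
            state, dwell = gillespie_step(network, state, [], rng)
            dwells.append(dwell)
        res = stats.kstest(dwells, "expon", args=(0, 1.0 / k))
        assert res.pvalue > 0.01

    def test_node_choice_proportional_to_rates(self, rng):
        bnd = ("node A { logic = A; rate_up = 1; rate_down = 1; }\n"
               "node B { logic = B; rate_up = 3; rate_down = 3; }")
        network, _ = parse_network(bnd)
        flips_b = 0
        n = 10_000
        for _ in range(n):
            state = make_state(network)
            new, _ = gillespie_step(network, state, [], rng)
            if new.bits[network.index["B"]] != state.bits[network.index["B"]]:
                flips_b += 1
        assert abs(flips_b / n - 0.75) < 0.02

    def test_zero_interval_is_identity(self, cascade, rng):
        state = make_state(cascade, Input=1)
        out = run_interval(cascade, state, [], 0.0, rng)
        assert (out.bits == state.bits).all()
        assert out.boolean_time == state.boolean_time

    def test_single_node_relaxation_matches_closed_form(self, rng):
        """P(ON at t) for an OFF node activating at rate k matches
        1 - exp(-k t) within 3 standard errors at n = 10,000."""
        k, t = 0.7, 1.5
        bnd = f"node A {{ logic = A; rate_up = {k}; rate_down = 0; }}"
        network, _ = parse_network(bnd)
        n = 10_000
        on = 0
        for _ in range(n):
            state = run_interval(network, make_state(network), [], t, rng)
            on += int(state.bits[0])
        p = 1.0 - math.exp(-k * t)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(on / n - p) < 3 * se

    def test_mutant_pinned_network_never_moves(self, cascade, rng):
        mutants = [MutantSpec("Input", True), MutantSpec("Mediator", False),
                   MutantSpec("Death", False)]
        state = make_state(cascade)
        out = run_interval(cascade, state, mutants, 50.0, rng)
        assert out.bits.tolist() == [1.0, 0.0, 0.0]

    def test_forced_node_constant_along_trajectory(self, cascade, rng):
        mutants = [MutantSpec("Mediator", True)]
        state = make_state(cascade, Input=1)
        for _ in range(30):
            state = run_interval(cascade, state, mutants, 0.5, rng)
            assert state.bits[cascade.index["Mediator"]] == 1.0


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

class TestEnsemble:
    def test_unit_weight_empty_mutants_equals_plain(self, toggle):
        network, init = toggle
        a = ensemble_run(network, init, None, 500, 3.0, 1.0, seed=3)
        b = ensemble_run(network, init, [((), 1.0)], 500, 3.0, 1.0, seed=3)
        assert (a.values == b.values).all()

    def test_mixture_realises_70_30_split(self):
        """A node that is otherwise always ON, mixed 70% wild-type / 30%
        forced-OFF, shows P(ON) = 0.70 at every time point."""
        bnd = "node A { logic = A; rate_up = 5; rate_down = 0; }"
        network, _ = parse_network(bnd)
        init = InitialCondition({"A": 1.0})
        n = 4000
        df = ensemble_run(network, init,
                          [((), 0.7), ([MutantSpec("A", False)], 0.3)],
                          n, 4.0, 2.0, seed=9)
        se = math.sqrt(0.7 * 0.3 / n)
        for t in df.index:
            assert abs(df.loc[t, "A"] - 0.70) < 3.5 * se

    def test_symmetric_toggle_is_stationary_at_half(self, toggle):
        network, init = toggle
        n = 4000
        df = ensemble_run(network, init, None, n, 6.0, 3.0, seed=11)
        se = math.sqrt(0.25 / n)
        for t in df.index:
            assert abs(df.loc[t, "A"] - 0.5) < 3 * se

    def test_weights_must_sum_to_one(self, toggle):
        network, init = toggle
        with pytest.raises(ValueError, match="sum to 1"):
            ensemble_run(network, init, [((), 0.5), ((), 0.3)], 10, 1.0, 1.0)

    def test_fixed_seed_reproducibility(self, cascade, cascade_init):
        mix = [([MutantSpec("Input", True)], 1.0)]
        a = ensemble_run(cascade, cascade_init, mix, 200, 3.0, 1.0, seed=21)
        b = ensemble_run(cascade, cascade_init, mix, 200, 3.0, 1.0, seed=21)
        assert (a.values == b.values).all()


class TestEngineSettings:
    def test_boolean_interval_scaling(self):
        assert EngineSettings(time_step=12, scaling=2).boolean_interval() == 6.0

    def test_deterministic_schedule_without_stochasticity(self, rng):
        s = EngineSettings(time_step=12, time_stochasticity=0.0)
        assert [s.next_wall_interval(rng) for _ in range(3)] == [12.0, 12.0, 12.0]

    def test_jittered_schedule_preserves_mean(self, rng):
        s = EngineSettings(time_step=12, time_stochasticity=0.4)
        draws = [s.next_wall_interval(rng) for _ in range(20_000)]
        assert abs(np.mean(draws) - 12.0) < 0.15
        assert np.std(draws) > 1.0

    @pytest.mark.parametrize("kwargs", [dict(time_step=0), dict(scaling=0),
                                        dict(time_stochasticity=-1)])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EngineSettings(**kwargs)
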