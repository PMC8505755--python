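import itertools

import numpy as np
import pytest

import ventact.smc_abc as smc
from ventact.eikonal import ActivationMap, ConductionSpeeds, ParameterSet
from ventact.discrepancy import INFEASIBLE_COST, atm_rmse
from ventact.smc_abc import (
    COLLAPSED,
    CONTINUE,
    MATCHED,
    InferenceConfig,
    Population,
    build_forward_operator,
    check_stopping,
    evaluate_population,
    load_population_csv,
    mutate,
    replacement_step,
    run_inference,
    sample_prior_lhs,
    save_population_csv,
    select_replacement_set,
)

NORMAL = ConductionSpeeds(150.0, 50.0, 32.0, 29.0)


def toy_population(discrepancies, n_bits=12, n_unique=None):
    """Population with prescribed discrepancies; root patterns cycle over
    ``n_unique`` distinct configurations (all distinct when None)."""
    discrepancies = np.asarray(discrepancies, dtype=float)
    n = discrepancies.size
    n_unique = n if n_unique is None else n_unique
    patterns = list(itertools.combinations(range(n_bits), 7))
    members = []
    for i in range(n):
        bits = np.zeros(n_bits, bool)
        bits[list(patterns[i % n_unique])] = True
        members.append(ParameterSet(speeds=NORMAL, root_active=bits))
    return Population(members=members, discrepancies=discrepancies.copy())


class TestPriorSampling:
    def test_population_size(self, candidates_low):
        pop = sample_prior_lhs(candidates_low, 512, seed=0)
        assert pop.size == 512

    def test_bounds_ordering_counts(self, candidates_low):
        pop = sample_prior_lhs(candidates_low, 256, seed=1)
        for m in pop.members:
            s = m.speeds
            assert 100.0 <= s.endocardial <= 200.0
            for v in (s.fibre, s.sheet, s.sheet_normal):
                assert 25.0 <= v <= 90.0
            assert s.fibre >= s.sheet >= s.sheet_normal
            assert 6 <= m.n_active <= min(10, candidates_low.n_candidates)

    def test_latin_hypercube_stratification(self, candidates_low):
        n = 64
        pop = sample_prior_lhs(candidates_low, n, seed=3)
        endo = np.array([m.speeds.endocardial for m in pop.members])
        bins = np.floor((endo - 100.0) / 100.0 * n).astype(int)
        assert sorted(bins) == list(range(n))  # exactly one sample per stratum

    def test_deterministic(self, candidates_low):
        a = sample_prior_lhs(candidates_low, 32, seed=9)
        b = sample_prior_lhs(candidates_low, 32, seed=9)
        assert np.array_equal(a.member_matrix(), b.member_matrix())

    def test_too_few_candidates(self):
        from ventact.geometry import CandidateRootNodes

        tiny = CandidateRootNodes(
            node_ids=np.arange(4), ventricle=np.ones(4, np.int8), resolution="LOW"
        )
        with pytest.raises(smc.InferenceError):
            sample_prior_lhs(tiny, 8, seed=0)


class TestEvaluatePopulation:
    def test_truth_member_zero_discrepancy(self, mesh_small, candidates_low, graph_small):
        forward = build_forward_operator(mesh_small, candidates_low, "ATM", graph=graph_small)
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        truth = ParameterSet(speeds=NORMAL, root_active=active)
        target = forward(truth)
        pop = Population(members=[truth.copy()], discrepancies=np.array([np.nan]))
        out = evaluate_population(pop, forward, target, "ATM")
        assert out.discrepancies[0] == 0.0

    def test_order_independence(self, mesh_small, candidates_low, graph_small):
        forward = build_forward_operator(mesh_small, candidates_low, "ATM", graph=graph_small)
        pop = sample_prior_lhs(candidates_low, 6, seed=2)
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        target = forward(ParameterSet(speeds=NORMAL, root_active=active))
        out = evaluate_population(pop, forward, target, "ATM")
        shuffled = Population(
            members=[pop.members[i] for i in (3, 1, 5, 0, 4, 2)],
            discrepancies=np.full(6, np.nan),
        )
        out2 = evaluate_population(shuffled, forward, target, "ATM")
        assert sorted(out.discrepancies) == pytest.approx(sorted(out2.discrepancies))

    def test_matches_manual_evaluation(self, mesh_small, candidates_low, graph_small):
        forward = build_forward_operator(mesh_small, candidates_low, "ATM", graph=graph_small)
        pop = sample_prior_lhs(candidates_low, 4, seed=5)
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        target = forward(ParameterSet(speeds=NORMAL, root_active=active))
        out = evaluate_population(pop, forward, target, "ATM")
        for m, d in zip(pop.members, out.discrepancies):
            assert d == pytest.approx(float(atm_rmse(forward(m), target)), abs=1e-12)

    def test_failing_member_gets_sentinel(self, candidates_low):
        def forward(params):
            raise RuntimeError("boom")

        pop = sample_prior_lhs(candidates_low, 3, seed=0)
        out = evaluate_population(pop, forward, None, "ATM")
        assert np.all(out.discrepancies == INFEASIBLE_COST)


class TestSelectReplacementSet:
    def test_512_gives_64(self):
        pop = toy_population(np.arange(512, dtype=float))
        cutoff, worst = select_replacement_set(pop, 0.125)
        assert worst.size == 64
        assert np.array_equal(worst, np.arange(448, 512))
        assert cutoff == 447.0

    def test_all_equal_still_selects(self):
        pop = toy_population(np.full(16, 3.0))
        cutoff, worst = select_replacement_set(pop, 0.125)
        assert worst.size == 2
        assert cutoff == 3.0

    def test_worst_of_eight(self):
        pop = toy_population(np.arange(1.0, 9.0))
        cutoff, worst = select_replacement_set(pop, 0.125)
        assert list(worst) == [7]
        assert cutoff == 7.0

    def test_ceil_rule(self):
        pop = toy_population(np.arange(10, dtype=float))
        _, worst = select_replacement_set(pop, 0.125)
        assert worst.size == 2  # ceil(1.25)


class TestMutate:
    def _cand(self, mesh_small, candidates_low):
        return candidates_low, candidates_low.positions(mesh_small)

    def test_degenerate_kernel_is_identity(self, mesh_small, candidates_low):
        cand, pos = self._cand(mesh_small, candidates_low)
        cfg = InferenceConfig(
            speed_sigma_endo=0.0, speed_sigma_myo=0.0, root_move_probability=0.0
        )
        member = sample_prior_lhs(cand, 2, seed=0).members[0]
        out = mutate(member, cfg, cand, pos, np.random.default_rng(0))
        assert np.array_equal(out.as_vector(), member.as_vector())

    def test_closure_under_invariants(self, mesh_small, candidates_low):
        cand, pos = self._cand(mesh_small, candidates_low)
        cfg = InferenceConfig()
        rng = np.random.default_rng(4)
        member = sample_prior_lhs(cand, 2, seed=1).members[0]
        for _ in range(2000):
            member = mutate(member, cfg, cand, pos, rng)
            s = member.speeds
            assert 100.0 <= s.endocardial <= 200.0
            assert 25.0 <= s.sheet_normal <= s.sheet <= s.fibre <= 90.0
            assert 6 <= member.n_active <= min(10, cand.n_candidates)

    def test_empirical_kernel_width(self, mesh_small, candidates_low):
        cand, pos = self._cand(mesh_small, candidates_low)
        cfg = InferenceConfig(speed_sigma_endo=5.0, speed_sigma_myo=0.0,
                              root_move_probability=0.0)
        base = ParameterSet(speeds=NORMAL, root_active=sample_prior_lhs(cand, 2, seed=0).members[0].root_active)
        rng = np.random.default_rng(6)
        draws = np.array([
            mutate(base, cfg, cand, pos, rng).speeds.endocardial for _ in range(10_000)
        ])
        # centre 150, bounds [100, 200]: truncation effect is negligible
        assert np.std(draws - 150.0) == pytest.approx(5.0, rel=0.05)


class TestReplacementStep:
    def _setup(self, mesh_small, candidates_low, graph_small, n=16, seed=0):
        forward = build_forward_operator(mesh_small, candidates_low, "ATM", graph=graph_small)
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        target = forward(ParameterSet(speeds=NORMAL, root_active=active))
        pop = sample_prior_lhs(candidates_low, n, seed=seed)
        pop = evaluate_population(pop, forward, target, "ATM")
        return forward, target, pop

    def test_size_constant_and_max_bounded_by_cutoff(
        self, mesh_small, candidates_low, graph_small
    ):
        forward, target, pop = self._setup(mesh_small, candidates_low, graph_small)
        cfg = InferenceConfig(population_size=16)
        cutoff, worst = select_replacement_set(pop, cfg.replacement_fraction)
        out = replacement_step(
            pop, forward, target, "ATM", cfg, candidates_low,
            candidates_low.positions(mesh_small), np.random.default_rng(1),
        )
        assert out.size == pop.size
        assert out.discrepancies.max() <= cutoff + 1e-12

    def test_survivors_unmodified(self, mesh_small, candidates_low, graph_small):
        forward, target, pop = self._setup(mesh_small, candidates_low, graph_small)
        cfg = InferenceConfig(population_size=16)
        _, worst = select_replacement_set(pop, cfg.replacement_fraction)
        out = replacement_step(
            pop, forward, target, "ATM", cfg, candidates_low,
            candidates_low.positions(mesh_small), np.random.default_rng(2),
        )
        survivors = np.setdiff1d(np.arange(pop.size), worst)
        for i in survivors:
            assert np.array_equal(out.members[i].as_vector(), pop.members[i].as_vector())
            assert out.discrepancies[i] == pop.discrepancies[i]

    def test_all_rejected_yields_survivor_copies(
        self, mesh_small, candidates_low, graph_small, monkeypatch
    ):
        forward, target, pop = self._setup(mesh_small, candidates_low, graph_small)
        cfg = InferenceConfig(population_size=16)
        monkeypatch.setattr(smc, "_evaluate_member", lambda *a: INFEASIBLE_COST)
        before_dup = pop.duplicate_count()
        _, worst = select_replacement_set(pop, cfg.replacement_fraction)
        out = replacement_step(
            pop, forward, target, "ATM", cfg, candidates_low,
            candidates_low.positions(mesh_small), np.random.default_rng(3),
        )
        survivor_vecs = {pop.members[i].as_vector().tobytes()
                         for i in np.setdiff1d(np.arange(pop.size), worst)}
        for slot in worst:
            assert out.members[slot].as_vector().tobytes() in survivor_vecs
        assert out.duplicate_count() >= before_dup + worst.size

    def test_accepted_mutants_beat_cutoff(self, mesh_small, candidates_low, graph_small):
        forward, target, pop = self._setup(mesh_small, candidates_low, graph_small, seed=4)
        cfg = InferenceConfig(population_size=16)
        cutoff, worst = select_replacement_set(pop, cfg.replacement_fraction)
        out = replacement_step(
            pop, forward, target, "ATM", cfg, candidates_low,
            candidates_low.positions(mesh_small), np.random.default_rng(5),
        )
        for slot in worst:
            assert out.discrepancies[slot] <= cutoff


class TestCheckStopping:
    def test_collapsed_at_257_of_512(self):
        pop = toy_population(np.full(512, 10.0), n_unique=255)
        # 255 unique configurations over 512 members -> 257 duplicates
        assert pop.duplicate_count() == 257
        cfg = InferenceConfig(tolerance=1.0)
        assert check_stopping(pop, cfg) == COLLAPSED

    def test_boundary_256_continues(self):
        pop = toy_population(np.full(512, 10.0), n_unique=256)
        assert pop.duplicate_count() == 256
        cfg = InferenceConfig(tolerance=1.0)
        assert check_stopping(pop, cfg) == CONTINUE

    def test_matched(self):
        pop = toy_population(np.zeros(16))
        assert check_stopping(pop, InferenceConfig(tolerance=0.5)) == MATCHED

    def test_matched_takes_precedence(self):
        pop = toy_population(np.zeros(16), n_unique=2)
        assert pop.duplicate_fraction() > 0.5
        assert check_stopping(pop, InferenceConfig(tolerance=0.5)) == MATCHED


class TestRunInference:
    def _target(self, mesh_small, candidates_low, graph_small):
        forward = build_forward_operator(mesh_small, candidates_low, "ATM", graph=graph_small)
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        return forward(ParameterSet(speeds=NORMAL, root_active=active))

    def test_seed_reproducibility(self, mesh_small, candidates_low, graph_small):
        target = self._target(mesh_small, candidates_low, graph_small)
        cfg = InferenceConfig(population_size=24, tolerance=1.0, max_iterations=4, seed=11)
        a_pop, a_trace, a_status = run_inference(
            mesh_small, candidates_low, target, "ATM", cfg, graph=graph_small
        )
        b_pop, b_trace, b_status = run_inference(
            mesh_small, candidates_low, target, "ATM", cfg, graph=graph_small
        )
        assert a_status == b_status
        assert a_trace == b_trace
        assert np.array_equal(a_pop.member_matrix(), b_pop.member_matrix())
        assert np.array_equal(a_pop.discrepancies, b_pop.discrepancies)

    def test_max_discrepancy_non_increasing(self, mesh_small, candidates_low, graph_small):
        target = self._target(mesh_small, candidates_low, graph_small)
        cfg = InferenceConfig(population_size=24, tolerance=0.5, max_iterations=6, seed=2)
        pop, trace, _ = run_inference(
            mesh_small, candidates_low, target, "ATM", cfg, graph=graph_small
        )
        maxes = [row["max_discrepancy"] for row in trace]
        assert all(b <= a + 1e-12 for a, b in zip(maxes, maxes[1:]))
        assert pop.size == 24

    def test_one_dimensional_recovery_vs_grid_oracle(self, mesh_small, candidates_low):
        # identifiable 1-D toy: activation times depend only on the
        # endocardial speed; target generated at 150 cm/s
        rng = np.random.default_rng(0)
        dists = rng.uniform(1.0, 10.0, size=50)
        node_ids = np.arange(50)

        def forward(params):
            return ActivationMap(
                times_ms=1000.0 * dists / params.speeds.endocardial, node_ids=node_ids
            )

        truth_speed = 150.0
        target = ActivationMap(times_ms=1000.0 * dists / truth_speed, node_ids=node_ids)

        # dense grid-search oracle over the 1-D parameter
        grid = np.linspace(100.0, 200.0, 2001)
        rmse = [np.sqrt(np.mean((1000.0 * dists / g - target.times_ms) ** 2)) for g in grid]
        assert grid[int(np.argmin(rmse))] == pytest.approx(truth_speed, abs=0.05)

        cfg = InferenceConfig(population_size=48, tolerance=0.0, max_iterations=30, seed=3)
        pop = sample_prior_lhs(candidates_low, cfg.population_size, seed=cfg.seed)
        pop = evaluate_population(pop, forward, target, "ATM")
        positions = candidates_low.positions(mesh_small)
        loop_rng = np.random.default_rng(7)
        for _ in range(cfg.max_iterations):
            pop = replacement_step(
                pop, forward, target, "ATM", cfg, candidates_low, positions, loop_rng
            )
        median_endo = np.median([m.speeds.endocardial for m in pop.members])
        assert abs(median_endo - truth_speed) / truth_speed <= 0.05


class TestPopulationIO:
    def test_round_trip(self, candidates_low, tmp_path):
        pop = sample_prior_lhs(candidates_low, 8, seed=0)
        pop.discrepancies = np.arange(8.0)
        path = tmp_path / "pop.csv"
        save_population_csv(pop, path)
        back = load_population_csv(path)
        assert np.array_equal(back.member_matrix(), pop.member_matrix())
        assert np.array_equal(back.discrepancies, pop.discrepancies)
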