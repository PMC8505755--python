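import numpy as np
import pytest

from ventact.eikonal import ConductionSpeeds, ParameterSet
from ventact.geometry import V_LV, V_RV
from ventact.smc_abc import Population, sample_prior_lhs
from ventact.aggregation import (
    AggregationError,
    aggregate,
    aggregate_root_nodes,
    aggregate_speeds,
    modal_configuration,
    pearson_correlation,
    root_node_errors,
    save_centroids_csv,
    speed_error_percent,
)

NORMAL = ConductionSpeeds(150.0, 50.0, 32.0, 29.0)


def _pop(members):
    return Population(members=members, discrepancies=np.zeros(len(members)))


class TestAggregateSpeeds:
    def test_unanimous(self):
        m = ParameterSet(speeds=NORMAL, root_active=np.ones(7, bool))
        out = aggregate_speeds(_pop([m.copy() for _ in range(5)]))
        assert out.as_array() == pytest.approx(NORMAL.as_array())

    def test_median_of_endocardial_values(self):
        speeds = [ConductionSpeeds(v, 50, 32, 29) for v in (120.0, 150.0, 179.0)]
        members = [ParameterSet(speeds=s, root_active=np.ones(7, bool)) for s in speeds]
        out = aggregate_speeds(_pop(members))
        assert out.endocardial == 150.0

    def test_matches_sort_and_pick_oracle(self, candidates_low):
        pop = sample_prior_lhs(candidates_low, 17, seed=0)
        out = aggregate_speeds(pop)
        for i, name in enumerate(("endocardial", "fibre", "sheet", "sheet_normal")):
            vals = sorted(getattr(m.speeds, name) for m in pop.members)
            assert getattr(out, name) == pytest.approx(vals[8])  # middle of 17

    def test_ordering_preserved(self, candidates_low):
        pop = sample_prior_lhs(candidates_low, 33, seed=5)
        out = aggregate_speeds(pop)
        assert out.fibre >= out.sheet >= out.sheet_normal

    def test_empty_population(self):
        with pytest.raises(AggregationError):
            aggregate_speeds(_pop([]))


class TestAggregateRootNodes:
    def test_unanimous_population_exact(self, mesh_small, candidates_low):
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        members = [ParameterSet(speeds=NORMAL, root_active=active.copy()) for _ in range(6)]
        centroids, vent = aggregate_root_nodes(_pop(members), candidates_low, mesh_small)
        expected = candidates_low.positions(mesh_small)[active]
        assert centroids.shape == (7, 3)
        assert np.allclose(np.sort(centroids, axis=0), np.sort(expected, axis=0))

    def test_modal_configuration(self, candidates_low):
        a = np.zeros(candidates_low.n_candidates, bool)
        a[:7] = True
        b = np.zeros(candidates_low.n_candidates, bool)
        b[1:8] = True
        members = [ParameterSet(speeds=NORMAL, root_active=v.copy())
                   for v in (a, a, a, b, b)]
        modal, count = modal_configuration(_pop(members))
        assert count == 3
        assert np.array_equal(modal, a)

    def test_all_unique_fallback(self, mesh_small, candidates_low):
        pop = sample_prior_lhs(candidates_low, 8, seed=2)
        pop.discrepancies = np.arange(8.0)
        modal, count = modal_configuration(pop)
        if modal is None:
            centroids, vent = aggregate_root_nodes(pop, candidates_low, mesh_small)
            counts = [m.n_active for m in pop.members]
            assert centroids.shape[0] == np.bincount(counts).argmax()

    def test_two_separated_clusters(self):
        # synthetic: two unanimous clusters of equal size -> centroids = means
        from ventact.aggregation import _lloyd

        rng = np.random.default_rng(0)
        c1 = rng.normal(0.0, 0.1, size=(20, 3))
        c2 = rng.normal(10.0, 0.1, size=(20, 3))
        pts = np.vstack([c1, c2])
        out = _lloyd(pts, np.array([[0.5, 0, 0], [9.5, 10, 10]]))
        assert np.allclose(np.sort(out[:, 0]), np.sort([c1.mean(0)[0], c2.mean(0)[0]]), atol=1e-9)
        assert np.allclose(out.min(axis=0), c1.mean(axis=0), atol=1e-9)
        assert np.allclose(out.max(axis=0), c2.mean(axis=0), atol=1e-9)

    def test_matches_multi_restart_oracle(self, mesh_small, candidates_low):
        # clustered population: Lloyd from the modal init reaches the same
        # WCSS as the best of 20 random restarts
        active = np.zeros(candidates_low.n_candidates, bool)
        active[:7] = True
        members = [ParameterSet(speeds=NORMAL, root_active=active.copy()) for _ in range(4)]
        other = active.copy()
        other[0] = False
        other[7 % candidates_low.n_candidates] = True
        members.append(ParameterSet(speeds=NORMAL, root_active=other))
        pop = _pop(members)
        centroids, _ = aggregate_root_nodes(pop, candidates_low, mesh_small)

        pooled = np.concatenate([
            candidates_low.positions(mesh_small)[m.root_active] for m in pop.members
        ])

        def wcss(cents):
            d2 = ((pooled[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
            return d2.min(axis=1).sum()

        from ventact.aggregation import _lloyd

        rng = np.random.default_rng(1)
        best = np.inf
        for _ in range(20):
            init = pooled[rng.choice(pooled.shape[0], centroids.shape[0], replace=False)]
            best = min(best, wcss(_lloyd(pooled, init.copy())))
        assert wcss(centroids) <= best + 1e-6


class TestSpeedError:
    def test_exact(self):
        assert speed_error_percent(50.0, 50.0) == 0.0

    def test_plus_ten_percent(self):
        assert speed_error_percent(55.0, 50.0) == pytest.approx(10.0)

    def test_minus_ten_percent(self):
        err = speed_error_percent(45.0, 50.0)
        assert err == pytest.approx(-10.0)
        assert abs(err) == pytest.approx(10.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(AggregationError):
            speed_error_percent(50.0, 0.0)


class TestRootNodeErrors:
    def test_exact_match(self):
        truth = np.array([[0.0, 0, 0], [1, 0, 0], [5, 5, 5]])
        vent = np.array([V_LV, V_LV, V_RV], np.int8)
        out = root_node_errors(truth.copy(), vent.copy(), truth, vent)
        assert out["LV"]["mean_cm"] == 0.0
        assert out["RV"]["mean_cm"] == 0.0
        assert out["LV"]["count_error"] == 0
        assert out["RV"]["count_error"] == 0

    def test_extra_centroid_changes_count_only(self):
        truth = np.array([[0.0, 0, 0], [1, 0, 0]])
        vent = np.array([V_LV, V_LV], np.int8)
        cents = np.vstack([truth, [[100.0, 100, 100]]])
        cvent = np.array([V_LV, V_LV, V_LV], np.int8)
        out = root_node_errors(cents, cvent, truth, vent)
        assert np.allclose(out["LV"]["distances_cm"], 0.0)
        assert out["LV"]["count_error"] == 1

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(size=(6, 3))
        tv = np.array([V_LV] * 3 + [V_RV] * 3, np.int8)
        cents = rng.uniform(size=(5, 3))
        cv = np.array([V_LV] * 2 + [V_RV] * 3, np.int8)
        out = root_node_errors(cents, cv, truth, tv)
        for vcode, name in ((V_LV, "LV"), (V_RV, "RV")):
            t = truth[tv == vcode]
            c = cents[cv == vcode]
            expected = np.array([min(np.linalg.norm(ti - cj) for cj in c) for ti in t])
            assert out[name]["distances_cm"] == pytest.approx(expected)


class TestPearson:
    def test_identity(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=50), rng.normal(size=50)
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert pearson_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(AggregationError):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestSolutionIO:
    def test_centroids_csv(self, mesh_small, candidates_low, tmp_path):
        pop = sample_prior_lhs(candidates_low, 5, seed=1)
        pop.discrepancies = np.zeros(5)
        sol = aggregate(pop, candidates_low, mesh_small)
        path = tmp_path / "centroids.csv"
        save_centroids_csv(sol, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "x,y,z,ventricle"
        assert len(lines) == sol.k + 1
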