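"""Objectives, penalty, parameter transform, Pareto ranking, ensemble search."""

import numpy as np
import pytest

from txtlkit.circuits import builtin_circuit
from txtlkit.estimation import (CorrectionParameter, DirectParameter, FitOptions,
                                MeasurementSeries, MeasurementSet, ParameterTransform,
                                PenaltySpec, apply_parameter_transform, fit_ensemble,
                                objective_error, overshoot_penalty, pareto_rank,
                                read_measurements_csv, transform_from_reference,
                                write_measurements_csv)
from txtlkit.simulation import Trajectory, simulate
from txtlkit.synthetic import generate_measurements


def _flat_trajectory(value, species="x", t_end=10.0):
    t = np.linspace(0, t_end, 101)
    return Trajectory(times=t, data={species: np.full_like(t, value)})


class TestObjectiveError:
    def test_exact_match_scores_zero(self):
        traj = _flat_trajectory(5.0)
        s = MeasurementSeries("x", [1.0, 4.0], [5.0, 5.0], [0.0, 0.0])
        assert objective_error(traj, s) == 0.0

    def test_sum_of_squared_residuals(self):
        traj = _flat_trajectory(0.0)
        s = MeasurementSeries("x", [1.0, 2.0], [1.0, 2.0], [0.0, 0.0])
        assert objective_error(traj, s) == pytest.approx(5.0)

    def test_matching_point_does_not_change_error(self):
        traj = _flat_trajectory(3.0)
        s1 = MeasurementSeries("x", [1.0, 2.0], [1.0, 2.0], [0.0, 0.0])
        s2 = MeasurementSeries("x", [1.0, 2.0, 5.0], [1.0, 2.0, 3.0],
                               [0.0, 0.0, 0.0])
        assert objective_error(traj, s1) == pytest.approx(
            objective_error(traj, s2))

    def test_species_absent_from_trajectory(self):
        traj = _flat_trajectory(1.0)
        s = MeasurementSeries("ghost", [1.0], [1.0], [0.0])
        with pytest.raises(KeyError):
            objective_error(traj, s)


class TestOvershootPenalty:
    def test_below_bound_costs_nothing(self):
        traj = _flat_trajectory(99_000.0, species="cI_ssrA")
        assert overshoot_penalty(traj, PenaltySpec()) == 0.0

    def test_one_micromolar_overshoot(self):
        traj = _flat_trajectory(101_000.0, species="cI_ssrA")
        assert overshoot_penalty(traj, PenaltySpec()) == pytest.approx(1e5)

    def test_penalty_is_linear_in_overshoot(self):
        traj = _flat_trajectory(100_500.0, species="cI_ssrA")
        assert overshoot_penalty(traj, PenaltySpec()) == pytest.approx(5e4)

    def test_uninhibited_reporter_circuit_never_pays(self, c1):
        # C1's deGFP tops out far below the 100 uM bound
        spec, _ = c1
        traj = simulate(spec, t_end=16.0, u_override={"deGFP": 0.95})
        assert overshoot_penalty(traj, PenaltySpec(species="deGFP")) == 0.0


class TestParameterTransform:
    def _transform(self):
        return ParameterTransform(
            direct=[DirectParameter("K_L", 1e4, 1e6)],
            corrections=[CorrectionParameter("theta_m_deGFP", 3.75, 0.1, 10.0)])

    def test_unit_multipliers_reproduce_characteristic_values(self):
        ps = apply_parameter_transform([5e4, 1.0], self._transform())
        assert ps["theta_m_deGFP"] == pytest.approx(3.75)

    def test_multiplier_scales_characteristic_value(self):
        ps = apply_parameter_transform([5e4, 2.0], self._transform())
        assert ps["theta_m_deGFP"] == pytest.approx(7.5)

    def test_bound_violation_names_the_parameter(self):
        with pytest.raises(ValueError, match="K_L"):
            apply_parameter_transform([1e7, 1.0], self._transform())

    def test_reference_bracket_layout(self, c1):
        _, params = c1
        tr = transform_from_reference(params, fold=10)
        assert len(tr) == len(params)
        assert set(tr.names()) == set(params.names())
        # time constants and degradation rates are corrections, energies direct
        corr = {p.name for p in tr.corrections}
        assert "theta_m_deGFP" in corr and "tau_X_deGFP" in corr
        direct = {p.name for p in tr.direct}
        assert "dG_deGFP_sigma70" in direct and "K_L" in direct
        # midpoint multipliers reproduce the reference
        lo, hi = tr.bounds()
        logm = tr.log_mask()
        mid = np.where(logm, np.sqrt(np.clip(lo * hi, 0.0, None)),
                       (lo + hi) / 2)
        ps = apply_parameter_transform(mid, tr)
        for name, v in params.values.items():
            assert ps[name] == pytest.approx(v, rel=1e-9)


def _brute_force_ranks(vectors):
    """Peel non-dominated fronts by exhaustive pairwise comparison."""
    vectors = [np.asarray(v) for v in vectors]
    n = len(vectors)
    ranks = [None] * n
    alive = set(range(n))
    rank = 0
    while alive:
        front = []
        for i in alive:
            dominated = any(
                np.all(vectors[j] <= vectors[i]) and np.any(vectors[j] < vectors[i])
                for j in alive if j != i)
            if not dominated:
                front.append(i)
        for i in front:
            ranks[i] = rank
            alive.discard(i)
        rank += 1
    return ranks


class TestParetoRank:
    def test_single_vector_is_rank_zero(self):
        assert pareto_rank([[1.0, 2.0]]) == [0]

    def test_mutually_non_dominating_pair(self):
        assert pareto_rank([[1, 2], [2, 1]]) == [0, 0]

    def test_nested_fronts(self):
        assert pareto_rank([[1, 1], [2, 2], [3, 3]]) == [0, 1, 2]

    def test_duplicates_share_a_front(self):
        assert pareto_rank([[1, 1], [1, 1], [2, 0]]) == [0, 0, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pareto_rank([])

    def test_agrees_with_exhaustive_domination_oracle(self, rng):
        vectors = rng.uniform(0, 1, size=(200, 4))
        assert pareto_rank(vectors) == _brute_force_ranks(vectors)


@pytest.fixture(scope="module")
def c1_zero_noise():
    spec, truth = builtin_circuit("C1")
    data = generate_measurements(spec, truth, noise_cv=0.0)
    return spec, truth, data


class TestFitEnsemble:
    def test_zero_generations_returns_ranked_initial_guesses(self, c1_zero_noise):
        spec, truth, data = c1_zero_noise
        tr = transform_from_reference(truth)
        ens = fit_ensemble(spec, tr, data,
                           options=FitOptions(generations=0), seed=11)
        assert len(ens) >= 1
        assert all(m.rank <= 2 and m.generation == 0 for m in ens.members)

    def test_identical_seeds_identical_ensembles(self, c1_zero_noise):
        spec, truth, data = c1_zero_noise
        tr = transform_from_reference(truth)
        opts = FitOptions(generations=2, steps_per_generation=8,
                          hybrid_period=0)
        a = fit_ensemble(spec, tr, data, options=opts, seed=7)
        b = fit_ensemble(spec, tr, data, options=opts, seed=7)
        assert len(a) == len(b)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.raw, mb.raw)
            assert np.array_equal(ma.objectives, mb.objectives)

    def test_archive_respects_rank_cutoff(self, c1_zero_noise):
        spec, truth, data = c1_zero_noise
        tr = transform_from_reference(truth)
        ens = fit_ensemble(spec, tr, data,
                           options=FitOptions(generations=3,
                                              steps_per_generation=10,
                                              hybrid_period=0), seed=5)
        re_ranked = pareto_rank([m.objectives for m in ens.members])
        assert all(r <= 2 for r in re_ranked)

    def test_requires_measurements(self, c1_zero_noise):
        spec, truth, _ = c1_zero_noise
        tr = transform_from_reference(truth)
        with pytest.raises(ValueError):
            fit_ensemble(spec, tr, MeasurementSet([]), seed=1)

    def test_noisier_data_raises_expected_error_of_truth(self, c1_zero_noise):
        # E_j(truth) grows with measurement noise: Monte-Carlo over 100 draws
        spec, truth, _ = c1_zero_noise
        traj = simulate(spec, truth, t_end=16.0)
        totals = {}
        for cv in (0.05, 0.2):
            errs = []
            for s in range(100):
                ms = generate_measurements(spec, truth, noise_cv=cv,
                                           seed=1000 + s)
                errs.append(sum(objective_error(traj, se) for se in ms.series))
            totals[cv] = np.mean(errs)
        assert totals[0.2] > totals[0.05]


class TestMeasurementsCSV:
    def test_round_trip(self, tmp_path, c1):
        spec, truth = c1
        ms = generate_measurements(spec, truth, noise_cv=0.1, seed=3)
        path = tmp_path / "m.csv"
        write_measurements_csv(ms, path)
        back = read_measurements_csv(path)
        assert back.species() == ms.species()
        for a, b in zip(ms.series, back.series):
            assert np.allclose(a.means, b.means)
            assert np.allclose(a.ci95, b.ci95)

    def test_micromolar_units_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "species,time_h,mean_nM,ci95_nM,n_replicates,units\n"
            "deGFP,1.0,12.0,0.5,3,uM\n"
            "deGFP,2.0,14.0,0.5,3,uM\n")
        ms = read_measurements_csv(path)
        assert np.allclose(ms.series[0].means, [12000.0, 14000.0])

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("species,time_h\n" "x,1.0\n")
        with pytest.raises(ValueError, match="mean_nM"):
            read_measurements_csv(path)

    def test_malformed_row_reported_with_location(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "species,time_h,mean_nM,ci95_nM,n_replicates\n"
            "x,1.0,5.0,0.1,3\n"
            "x,,4.0,0.1,3\n")
        with pytest.raises(ValueError, match="row 3"):
            read_measurements_csv(path)
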