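"""Objective function, interpolation, and the two-stage fit."""

import numpy as np
import pytest

from qsdyn import (
    DEConfig,
    GrowthParams,
    Series,
    TimeSeriesDataset,
    Trajectory,
    fit_growth,
    fit_qs,
    interpolate_to_grid,
    simulate,
    sswr,
)
from qsdyn.estimation import equalize_l_series


class TestInterpolation:
    def test_node_identity(self):
        t = np.array([0.0, 1.0, 2.5, 4.0])
        v = np.array([1.0, -2.0, 0.5, 3.0])
        assert np.array_equal(interpolate_to_grid(t, v, t), v)

    def test_midpoint(self):
        assert interpolate_to_grid([0, 2], [1, 3], [1.0]) == pytest.approx([2.0])

    def test_extrapolation_refused(self):
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_to_grid([0, 2], [1, 3], [2.5])

    def test_needs_two_nodes(self):
        with pytest.raises(ValueError):
            interpolate_to_grid([1.0], [2.0], [1.0])


def _toy_pair():
    """Dataset/trajectory pair for hand-checked SSWR values."""
    data = TimeSeriesDataset({
        "X": Series([0.0, 1.0], [1.0, 2.0]),
        "A": Series([0.0, 1.0], [3.0, 4.0]),
    })
    traj = Trajectory(times=np.array([0.0, 1.0]),
                      X=np.array([1.0, 1.0]),
                      A=np.array([3.0, 2.0]),
                      L=np.zeros(2))
    return data, traj


class TestSSWR:
    def test_identity_fit_is_zero(self):
        data, _ = _toy_pair()
        traj = Trajectory(times=np.array([0.0, 1.0]),
                          X=np.array([1.0, 2.0]),
                          A=np.array([3.0, 4.0]), L=np.zeros(2))
        assert sswr(data, traj) == 0.0

    def test_hand_computed_value(self):
        # X residuals (0, 1)/2, A residuals (0, 2)/4 -> 0.25 + 0.25
        data, traj = _toy_pair()
        assert sswr(data, traj) == pytest.approx(0.5, rel=1e-14)

    def test_weight_linearity(self):
        data, traj = _toy_pair()
        doubled = TimeSeriesDataset({
            v: data[v].with_weights(2.0 * np.ones(len(data[v])))
            for v in data.variables})
        assert sswr(doubled, traj) == pytest.approx(2 * sswr(data, traj))

    def test_scale_invariance_per_variable(self):
        # rescaling one variable's data AND model leaves its term unchanged
        data, traj = _toy_pair()
        scaled_data = data.replace_series(
            "A", Series(data["A"].times, 100.0 * data["A"].values))
        scaled_traj = Trajectory(times=traj.times, X=traj.X,
                                 A=100.0 * traj.A, L=traj.L)
        assert sswr(scaled_data, scaled_traj) == pytest.approx(sswr(data, traj))

    def test_zero_normalizer_rejected(self):
        data = TimeSeriesDataset({"A": Series([0.0, 1.0], [0.0, 0.0])})
        traj = Trajectory(times=np.array([0.0, 1.0]), X=np.ones(2),
                          A=np.ones(2), L=np.zeros(2))
        with pytest.raises(ValueError, match="normalizer"):
            sswr(data, traj)

    def test_uncovered_times_rejected(self):
        data, traj = _toy_pair()
        short = Trajectory(times=np.array([0.0]), X=np.ones(1),
                           A=np.ones(1), L=np.zeros(1))
        with pytest.raises(ValueError, match="union grid"):
            sswr(data, short)

    def test_matches_naive_double_loop(self, truth):
        """Vectorised SSWR equals the definition on random pairs."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = {v: rng.integers(3, 12) for v in ("X", "A", "L")}
            times = {v: np.sort(rng.uniform(0, 10, n[v])) for v in n}
            grid = np.unique(np.concatenate(list(times.values())))
            data = TimeSeriesDataset({
                v: Series(times[v], rng.uniform(0.1, 5.0, n[v]),
                          rng.uniform(0.5, 2.0, n[v]))
                for v in n})
            traj = Trajectory(times=grid, X=rng.uniform(0.1, 5, grid.size),
                              A=rng.uniform(0, 5, grid.size),
                              L=rng.uniform(0, 5, grid.size))
            expected = 0.0
            for v in ("X", "A", "L"):
                s = data[v]
                norm = max(abs(x) for x in s.values)
                for t, y, w in zip(s.times, s.values, s.weights):
                    yhat = traj.values(v)[list(grid).index(t)]
                    expected += w * ((y - yhat) / norm) ** 2
            assert sswr(data, traj) == pytest.approx(expected, rel=1e-12)


class TestEqualize:
    def test_l_series_lands_on_reference_grid(self, clean_dataset):
        eq = equalize_l_series(clean_dataset)
        a_times = set(clean_dataset["A"].times)
        assert set(eq["L"].times) <= a_times
        assert len(eq["L"]) > len(clean_dataset["L"])
        # exact at the original nodes
        orig = dict(zip(clean_dataset["L"].times, clean_dataset["L"].values))
        for t, v in zip(eq["L"].times, eq["L"].values):
            if t in orig:
                assert v == pytest.approx(orig[t])


class TestFitGrowth:
    def test_noiseless_recovery(self, truth, clean_dataset):
        gp, _ = truth
        res = fit_growth(clean_dataset, cfg=DEConfig(max_gen=200, seed=5))
        for name, target in gp.to_dict().items():
            assert res.params[name] == pytest.approx(target, rel=0.01)

    def test_noisy_recovery(self, truth):
        from qsdyn import DesignSpec, generate_dataset
        gp, qp = truth
        data = generate_dataset(gp, qp, DesignSpec(cv=0.05, seed=3))
        res = fit_growth(data, cfg=DEConfig(max_gen=200, seed=5))
        for name, target in gp.to_dict().items():
            assert res.params[name] == pytest.approx(target, rel=0.10)

    def test_constant_data_warns(self):
        # a flat curve at a level X0 alone can explain leaves no work
        # for the sigmoid: C collapses to its lower bound
        data = TimeSeriesDataset({"X": Series(np.arange(6.0),
                                              np.full(6, 0.5))})
        with pytest.warns(UserWarning, match="growth signal"):
            fit_growth(data, cfg=DEConfig(max_gen=120, seed=1))

    def test_insufficient_data_rejected(self):
        data = TimeSeriesDataset({"X": Series([0.0, 1.0], [1.0, 2.0])})
        with pytest.raises(ValueError, match=">= 5"):
            fit_growth(data)


class TestFitQS:
    def test_truth_beats_doubled_parameters(self, truth, clean_dataset):
        """Noiseless SSWR at the generating kinetics undercuts 2x
        perturbations of each identifiable rate."""
        gp, qp = truth
        grid = clean_dataset.union_times(("A", "L"))
        base = sswr(clean_dataset, simulate(gp, qp, grid),
                    variables=("A", "L"))
        for name in ("kA", "kXA", "kR", "kL"):
            pert = qp.replace(**{name: 2 * qp.to_dict()[name]})
            cost = sswr(clean_dataset, simulate(gp, pert, grid),
                        variables=("A", "L"))
            assert cost > base

    def test_missing_a_series_rejected(self, truth):
        gp, _ = truth
        data = TimeSeriesDataset({"X": Series(np.arange(6.0),
                                              np.arange(1.0, 7.0))})
        with pytest.raises(ValueError, match="A series"):
            fit_qs(data, gp)

    def test_unknown_fixed_rejected(self, truth, clean_dataset):
        gp, _ = truth
        with pytest.raises(ValueError, match="unknown fixed"):
            fit_qs(clean_dataset, gp, fixed={"bogus": 1.0})

    def test_short_fit_runs_and_respects_bounds(self, truth, clean_dataset):
        gp, _ = truth
        res = fit_qs(clean_dataset, gp,
                     cfg=DEConfig(pop_size=12, max_gen=5, seed=0))
        for k, v in res.params.items():
            lo, hi = res.bounds[k]
            assert lo <= v <= hi
        assert res.cost >= 0
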