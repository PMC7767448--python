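import math

import numpy as np
import pytest

import erpsnn
from erpsnn.encoding import SpikeTrainSet
from erpsnn.reservoir import (
    FiringLog,
    LIFConfig,
    NeuronGrid,
    Reservoir,
    ReservoirError,
    STDPConfig,
    SWCConfig,
    build_reservoir,
    run_stdp,
    snapshot_activity,
)

from conftest import toy_montage


def make_reservoir(coords, edges, input_labels, input_neurons, weights):
    coords = np.asarray(coords, dtype=float)
    pre = np.array([e[0] for e in edges], dtype=np.int64)
    post = np.array([e[1] for e in edges], dtype=np.int64)
    return Reservoir(
        coords=coords,
        input_channels=tuple(input_labels),
        input_neurons=np.asarray(input_neurons, dtype=np.int64),
        pre=pre,
        post=post,
        weights=np.asarray(weights, dtype=float),
        inhibitory=np.zeros(len(coords), dtype=bool),
        swc=SWCConfig(),
    )


def spikes_from(matrix, labels):
    return SpikeTrainSet(spikes=np.asarray(matrix, dtype=np.int8),
                         channels=tuple(labels),
                         source_len=np.asarray(matrix).shape[1])


# --------------------------------------------------------------------------
# independent straight-line re-simulation (the oracle)
# --------------------------------------------------------------------------

def simulate_oracle(n, edges, weights, input_neurons, spikes, lif, stdp):
    """Plain-python replica of the LIF/STDP semantics, written independently
    of the vectorised kernel: explicit per-step loops over dicts."""
    w = {i: float(weights[i]) for i in range(len(edges))}
    u = [0.0] * n
    refr = [0] * n
    last = {}
    fired_prev = set()
    log = []
    T = len(spikes[0]) if spikes else 0

    def bump(val, delta, potentiate):
        mag = abs(val)
        mag = mag + delta if potentiate else mag - delta
        mag = min(max(mag, 0.0), stdp.w_max)
        return mag if val >= 0 else -mag

    for t in range(T):
        drive = [0.0] * n
        for ei, (p, q) in enumerate(edges):
            if p in fired_prev:
                drive[q] += w[ei]
        for c, neuron in enumerate(input_neurons):
            if spikes[c][t]:
                drive[neuron] += spikes[c][t]
        fired = []
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                u[i] = 0.0
                continue
            u[i] = u[i] * lif.leak + drive[i]
            if u[i] > lif.fire_threshold:
                fired.append(i)
        for j in fired:
            for ei, (p, q) in enumerate(edges):
                if q == j and p in last and last[p] < t:
                    w[ei] = bump(w[ei], stdp.a_plus
                                 * math.exp(-(t - last[p]) / stdp.tau_ms), True)
                if p == j and q in last and last[q] < t:
                    w[ei] = bump(w[ei], stdp.a_minus
                                 * math.exp(-(t - last[q]) / stdp.tau_ms), False)
            log.append((j, t, 1 if drive[j] >= 0 else -1))
            u[j] = 0.0
            refr[j] = lif.refractory_steps
        for j in fired:
            last[j] = t
        fired_prev = set(fired)
    return w, log


class TestGridAndBuild:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ReservoirError):
            NeuronGrid(coords=np.zeros((3, 3)))

    def test_subsample_preserves_sites(self, grid_full):
        sub = grid_full.subsample(100, seed=1)
        assert len(sub) == 100
        full_set = {tuple(r) for r in grid_full.coords}
        assert all(tuple(r) in full_set for r in sub.coords)

    def test_full_fixture_build(self, grid_full, montage):
        res = build_reservoir(grid_full, montage)
        assert res.n_neurons == 1471
        assert len(res.input_neurons) == 62
        assert len(np.unique(res.input_neurons)) == 62
        assert res.n_edges > 0
        assert not np.any(res.pre == res.post)
        assert np.max(res.edge_lengths()) <= res.swc.radius_mm + 1e-9
        w = np.abs(res.weights)
        assert (w > 0).all() and (w <= res.swc.init_weight_scale).all()

    def test_zero_radius_yields_no_connections(self, montage, grid_small):
        res = build_reservoir(grid_small, montage,
                              SWCConfig(radius_mm=0.0, base_prob=0.5))
        assert res.n_edges == 0

    def test_three_collinear_neurons_form_complete_digraph(self):
        grid = NeuronGrid(coords=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        mont = toy_montage([[0.0, 0, 0]])
        res = build_reservoir(grid, mont,
                              SWCConfig(radius_mm=1e6, base_prob=1.0,
                                        inhibitory_fraction=0.0))
        assert res.n_edges == 6
        assert set(zip(res.pre, res.post)) == {(0, 1), (0, 2), (1, 0), (1, 2),
                                               (2, 0), (2, 1)}

    def test_connection_probability_decreases_with_distance(self, grid_full, montage):
        res = build_reservoir(grid_full, montage,
                              SWCConfig(radius_mm=30.0, base_prob=1.0))
        coords = grid_full.coords
        lengths = res.edge_lengths()
        # empirical P(edge | distance bin) for 10/20/30 mm lattice shells
        diff = coords[:, None, :] - coords[None, :, :]
        alld = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        probs = []
        for lo, hi in [(5, 15), (15, 25), (25, 30.01)]:
            pairs = ((alld > lo) & (alld < hi)).sum()
            made = ((lengths > lo) & (lengths < hi)).sum()
            probs.append(made / pairs)
        assert probs[0] > probs[1] > probs[2]

    def test_inhibitory_fraction_sets_negative_outgoing_weights(self, montage, grid_small):
        res = build_reservoir(grid_small, montage,
                              SWCConfig(radius_mm=40, base_prob=0.5,
                                        inhibitory_fraction=0.3))
        assert res.inhibitory.sum() == round(0.3 * 200)
        neg = res.weights < 0
        np.testing.assert_array_equal(neg, res.inhibitory[res.pre])

    def test_grid_smaller_than_montage_rejected(self, montage):
        tiny = NeuronGrid(coords=np.arange(30.0).reshape(10, 3))
        with pytest.raises(ReservoirError):
            build_reservoir(tiny, montage)

    def test_build_deterministic_given_seed(self, montage, grid_small):
        a = build_reservoir(grid_small, montage, SWCConfig(seed=3))
        b = build_reservoir(grid_small, montage, SWCConfig(seed=3))
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestDynamics:
    LIF = LIFConfig(fire_threshold=0.5, leak=0.9, refractory_steps=5)
    STDP = STDPConfig(a_plus=0.05, a_minus=0.03, tau_ms=10.0, w_max=2.0)

    def test_zero_input_changes_nothing(self):
        res = make_reservoir([[0, 0, 0], [10, 0, 0]], [(0, 1)], ["A"], [0], [1.0])
        trained, log = run_stdp(res, spikes_from(np.zeros((1, 20)), ["A"]),
                                self.LIF, self.STDP)
        np.testing.assert_array_equal(trained.weights, res.weights)
        assert len(log) == 0

    def test_two_neuron_chain_potentiates(self):
        res = make_reservoir([[0, 0, 0], [10, 0, 0]], [(0, 1)], ["A"], [0], [1.0])
        mat = np.zeros((1, 10), dtype=np.int8)
        mat[0, 5] = 1
        trained, log = run_stdp(res, spikes_from(mat, ["A"]), self.LIF, self.STDP)
        events = list(zip(log.neuron, log.t))
        assert (0, 5) in events and (1, 6) in events
        expected = 1.0 + 0.05 * np.exp(-1.0 / 10.0)
        assert trained.weights[0] == pytest.approx(expected)

    def test_post_before_pre_depresses(self):
        res = make_reservoir([[0, 0, 0], [10, 0, 0]], [(0, 1)],
                             ["A", "B"], [0, 1], [0.3])
        mat = np.zeros((2, 10), dtype=np.int8)
        mat[1, 3] = 1  # post fires first
        mat[0, 5] = 1  # then pre
        trained, log = run_stdp(res, spikes_from(mat, ["A", "B"]),
                                self.LIF, self.STDP)
        expected = 0.3 - 0.03 * np.exp(-2.0 / 10.0)
        assert trained.weights[0] == pytest.approx(expected)

    def test_zero_rates_preserve_weights_for_any_input(self, montage, grid_small, swc_small):
        res = build_reservoir(grid_small, montage, swc_small)
        rng = np.random.default_rng(5)
        mat = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(62, 200),
                         p=[0.15, 0.7, 0.15])
        frozen = STDPConfig(a_plus=0.0, a_minus=0.0, tau_ms=10.0, w_max=2.0)
        trained, log = run_stdp(res, spikes_from(mat, montage.channels),
                                LIFConfig(), frozen)
        np.testing.assert_array_equal(trained.weights, res.weights)
        assert len(log) > 0

    def test_unmapped_channel_rejected(self):
        res = make_reservoir([[0, 0, 0], [10, 0, 0]], [(0, 1)], ["A"], [0], [1.0])
        with pytest.raises(ReservoirError):
            run_stdp(res, spikes_from(np.zeros((1, 5)), ["Z"]), self.LIF, self.STDP)

    def test_run_deterministic(self, montage, grid_small, swc_small):
        res = build_reservoir(grid_small, montage, swc_small)
        rng = np.random.default_rng(6)
        mat = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(62, 300),
                         p=[0.1, 0.8, 0.1])
        ss = spikes_from(mat, montage.channels)
        t1, l1 = run_stdp(res, ss)
        t2, l2 = run_stdp(res, ss)
        np.testing.assert_array_equal(t1.weights, t2.weights)
        np.testing.assert_array_equal(l1.neuron, l2.neuron)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_independent_resimulation(self, trial):
        """Kernel vs straight-line oracle on random <=5-neuron problems."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 6))
        T = int(rng.integers(5, 21))
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        k = int(rng.integers(1, len(pairs) + 1))
        edges = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
        weights = rng.uniform(0.2, 1.2, size=k) * rng.choice([-1.0, 1.0], size=k)
        n_inp = int(rng.integers(1, n + 1))
        input_neurons = rng.choice(n, size=n_inp, replace=False)
        labels = [f"c{i}" for i in range(n_inp)]
        mat = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(n_inp, T),
                         p=[0.2, 0.5, 0.3])
        lif = LIFConfig(fire_threshold=float(rng.uniform(0.3, 1.2)),
                        leak=float(rng.uniform(0.0, 0.95)),
                        refractory_steps=int(rng.integers(0, 4)))
        stdp = STDPConfig(a_plus=0.05, a_minus=0.03,
                          tau_ms=float(rng.uniform(2, 15)), w_max=1.5)
        coords = rng.normal(0, 20, size=(n, 3))
        res = make_reservoir(coords, edges, labels, input_neurons, weights)
        trained, log = run_stdp(res, spikes_from(mat, labels), lif, stdp)
        w_or, log_or = simulate_oracle(n, edges, weights, input_neurons,
                                       mat.tolist(), lif, stdp)
        np.testing.assert_allclose(
            trained.weights, [w_or[i] for i in range(k)], rtol=0, atol=1e-12)
        assert list(zip(log.neuron, log.t, log.polarity)) == log_or


class TestSnapshot:
    def _log(self, events, n=10, steps=600):
        ev = np.array(events, dtype=np.int64).reshape(-1, 3)
        return FiringLog(neuron=ev[:, 0], t=ev[:, 1],
                         polarity=ev[:, 2].astype(np.int8),
                         n_neurons=n, n_steps=steps)

    def test_empty_log_counts_zero(self):
        pos, neg = snapshot_activity(self._log([]), 253, 10)
        assert pos.sum() == 0 and neg.sum() == 0

    def test_single_event_counted(self):
        pos, neg = snapshot_activity(self._log([(7, 253, 1)]), 253, 10)
        assert pos[7] == 1 and pos.sum() == 1 and neg.sum() == 0

    def test_disjoint_windows_are_additive(self):
        rng = np.random.default_rng(7)
        events = [(int(rng.integers(0, 10)), int(rng.integers(0, 600)),
                   int(rng.choice([-1, 1]))) for _ in range(200)]
        log = self._log(events)
        p1, n1 = snapshot_activity(log, 100, 100)   # [50, 150]
        p2, n2 = snapshot_activity(log, 201, 100)   # [151, 251]
        pu, nu = snapshot_activity(log, 150.5, 201)  # [50, 251]
        np.testing.assert_array_equal(p1 + p2, pu)
        np.testing.assert_array_equal(n1 + n2, nu)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            snapshot_activity(self._log([]), 5, 20)
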