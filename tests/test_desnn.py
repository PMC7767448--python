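import numpy as np
import pandas as pd
import pytest

import erpsnn
from erpsnn.desnn import (
    ClassificationReport,
    DeSNNConfig,
    LoocvSettings,
    OutputNeuron,
    TrainedClassifier,
    TrainingError,
    classify,
    rank_order_weights,
    run_baselines,
    run_loocv,
    train_desnn,
)
from erpsnn.reservoir import FiringLog
from erpsnn.simulate import CohortSpec, generate_cohort


def make_log(events, n_neurons, n_steps=50):
    ev = np.array(events, dtype=np.int64).reshape(-1, 2)
    return FiringLog(neuron=ev[:, 0], t=ev[:, 1],
                     polarity=np.ones(len(ev), dtype=np.int8),
                     n_neurons=n_neurons, n_steps=n_steps)


class TestRankOrder:
    def test_mod_power_of_first_firing_order(self):
        # first firings: n2 at t=1, n0 at t=3, n1 at t=7
        log = make_log([(2, 1), (0, 3), (1, 7)], n_neurons=3)
        w = rank_order_weights(log, DeSNNConfig(mod=0.9, drift=0.0))
        np.testing.assert_allclose(w, [0.9, 0.81, 1.0])

    def test_never_firing_neuron_gets_zero(self):
        log = make_log([(0, 1)], n_neurons=3)
        w = rank_order_weights(log, DeSNNConfig(mod=0.9, drift=0.0))
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])

    def test_drift_counts_subsequent_firings(self):
        log = make_log([(0, 1), (0, 5), (0, 9), (1, 2)], n_neurons=2)
        w = rank_order_weights(log, DeSNNConfig(mod=0.5, drift=0.25))
        np.testing.assert_allclose(w, [1.0 + 2 * 0.25, 0.5])

    def test_weights_non_increasing_in_firing_order(self):
        rng = np.random.default_rng(0)
        times = rng.choice(100, size=20, replace=False)
        log = make_log(list(zip(range(20), times)), n_neurons=20)
        w = rank_order_weights(log, DeSNNConfig(mod=0.8, drift=0.0))
        order = np.argsort(times)
        assert (np.diff(w[order]) <= 0).all()

    def test_mod_one_gives_binary_fired_weights(self):
        log = make_log([(0, 1), (2, 5)], n_neurons=4)
        w = rank_order_weights(log, DeSNNConfig(mod=1.0, drift=0.0))
        np.testing.assert_allclose(w, [1.0, 0.0, 1.0, 0.0])

    def test_simultaneous_first_firings_ranked_by_neuron_index(self):
        log = make_log([(3, 2), (1, 2)], n_neurons=4)
        w = rank_order_weights(log, DeSNNConfig(mod=0.9, drift=0.0))
        assert w[1] == pytest.approx(1.0) and w[3] == pytest.approx(0.9)


class TestTrainClassify:
    def test_one_neuron_per_training_sample(self):
        logs = [make_log([(0, t + 1)], n_neurons=3) for t in range(12)]
        clf = train_desnn(logs, ["A", "B"] * 6)
        assert len(clf.neurons) == 12

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            train_desnn([], [])

    def test_empty_log_keeps_zero_vector_with_label(self):
        clf = train_desnn([make_log([], n_neurons=4),
                           make_log([(0, 1)], n_neurons=4)], ["A", "B"])
        np.testing.assert_array_equal(clf.neurons[0].weights, np.zeros(4))
        assert clf.neurons[0].label == "A"

    def _clf(self, vecs, labels, k=1):
        neurons = tuple(OutputNeuron(np.asarray(v, dtype=float), lab, f"s{i}")
                        for i, (v, lab) in enumerate(zip(vecs, labels)))
        return TrainedClassifier(neurons=neurons,
                                 config=DeSNNConfig(k_neighbors=k),
                                 n_reservoir=len(vecs[0]))

    def test_nearest_neighbour_label(self):
        # trained vectors (1,0)->A and (0,1)->B; a test log whose rank-order
        # vector is (1, 0.9) lies nearer to A
        clf = self._clf([[1.0, 0.0], [0.0, 1.0]], ["A", "B"], k=1)
        test = make_log([(0, 1), (1, 5)], n_neurons=2)
        label, report = classify(test, clf)
        assert label == "A"
        assert report.iloc[0]["label"] == "A"
        assert report["is_neighbor"].sum() == 1

    def test_unanimous_training_labels_always_win(self):
        clf = self._clf([[1.0, 0.0], [0.0, 1.0], [1, 1]], ["A", "A", "A"], k=3)
        label, _ = classify(make_log([(1, 2)], n_neurons=2), clf)
        assert label == "A"

    def test_vote_tie_broken_by_mean_distance(self):
        # k=2: one A and one B among neighbours; B is closer on average
        clf = self._clf([[1.0, 0.0], [0.88, 0.02], [-5, -5]], ["A", "B", "C"], k=2)
        test = make_log([(0, 1), (1, 40)], n_neurons=2)  # vector ~(1, small)
        label, _ = classify(test, clf)
        # distances: B slightly closer than A -> B wins the 1-1 tie
        w = rank_order_weights(make_log([(0, 1), (1, 40)], 2), clf.config)
        dA = np.linalg.norm(w - [1.0, 0.0])
        dB = np.linalg.norm(w - [0.88, 0.02])
        assert label == ("B" if dB < dA else "A")

    def test_exact_distance_tie_broken_by_class_order(self):
        clf = self._clf([[1.0, 1.0], [-1.0, -1.0]], ["B", "A"], k=2)
        label, _ = classify(make_log([], n_neurons=2), clf)  # test vector (0,0)
        assert label == "A"

    def test_k_exceeding_training_size_rejected(self):
        clf = self._clf([[1.0, 0.0]], ["A"], k=3)
        with pytest.raises(ValueError):
            classify(make_log([], n_neurons=2), clf)


class TestReportArithmetic:
    def _report(self, true, pred):
        classes = sorted(set(true) | set(pred))
        preds = pd.DataFrame({"sample_id": range(len(true)),
                              "true": true, "predicted": pred})
        conf = pd.crosstab(preds["true"], preds["predicted"]).reindex(
            index=classes, columns=classes, fill_value=0)
        return ClassificationReport(confusion=conf, predictions=preds)

    def test_report_matches_sklearn(self):
        from sklearn.metrics import accuracy_score, f1_score

        rng = np.random.default_rng(1)
        true = list(rng.choice(["A", "B", "C"], size=60))
        pred = list(rng.choice(["A", "B", "C"], size=60))
        rep = self._report(true, pred)
        assert rep.total_accuracy == pytest.approx(accuracy_score(true, pred))
        assert rep.macro_f1 == pytest.approx(
            f1_score(true, pred, average="macro"))
        for cls in "ABC":
            sel = [p for t, p in zip(true, pred) if t == cls]
            assert rep.per_class_accuracy[cls] == pytest.approx(
                np.mean([p == cls for p in sel]))

    def test_confusion_row_sums_are_class_counts(self):
        rep = self._report(["A"] * 4 + ["B"] * 6,
                           ["A", "B", "A", "A", "B", "B", "A", "B", "B", "B"])
        assert rep.confusion.sum(axis=1).tolist() == [4, 6]


@pytest.fixture(scope="module")
def tiny_cohort(montage):
    """30 samples (3 time points x 10 participants), short epochs, for fast
    leave-one-out runs."""
    spec = CohortSpec(n_per_group=5, time_points=("T1", "T2", "T3"),
                      stimuli=("target",), epoch_len=300, seed=11)
    samples, _ = generate_cohort(spec, montage)
    labels = [s.time_point for s in samples]
    return samples, labels


@pytest.fixture(scope="module")
def tiny_settings(montage, grid_full):
    return LoocvSettings(grid=grid_full.subsample(80, seed=2), montage=montage,
                         swc=erpsnn.SWCConfig(radius_mm=50.0, base_prob=0.4),
                         base_seed=3)


class TestLoocv:
    def test_thirty_samples_give_thirty_folds(self, tiny_cohort, tiny_settings):
        samples, labels = tiny_cohort
        rep = run_loocv(samples, labels, tiny_settings)
        assert len(rep.predictions) == 30
        assert rep.confusion.to_numpy().sum() == 30
        assert rep.confusion.sum(axis=1).tolist() == [10, 10, 10]

    def test_sample_order_does_not_change_confusion(self, tiny_cohort, tiny_settings):
        samples, labels = tiny_cohort
        rep1 = run_loocv(samples, labels, tiny_settings)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(samples))
        rep2 = run_loocv([samples[i] for i in perm], [labels[i] for i in perm],
                         tiny_settings)
        pd.testing.assert_frame_equal(rep1.confusion, rep2.confusion)

    def test_separable_zero_noise_classes_classify_perfectly(self, montage, tiny_settings):
        spec = CohortSpec(n_per_group=4, groups=("experimental",),
                          time_points=("T1", "T2"), stimuli=("target",),
                          epoch_len=300, noise_sd_uv=0.0, rf_gain_sd=0.0,
                          frontal_gain_delta=1.0, seed=2)
        samples, _ = generate_cohort(spec, montage)
        labels = [s.time_point for s in samples]
        rep = run_loocv(samples, labels, tiny_settings)
        assert rep.total_accuracy == 1.0

    def test_single_sample_class_warns_but_runs(self, tiny_cohort, tiny_settings):
        samples, labels = tiny_cohort
        t3 = [s for s in samples if s.time_point == "T3"]
        sub = [s for s in samples if s.time_point != "T3"][:10] + t3[:1]
        sub_labels = [s.time_point for s in sub]
        assert sub_labels.count("T3") == 1
        with pytest.warns(UserWarning, match="single sample"):
            rep = run_loocv(sub, sub_labels, tiny_settings)
        assert len(rep.predictions) == 11

    def test_fewer_than_two_classes_rejected(self, tiny_cohort, tiny_settings):
        samples, _ = tiny_cohort
        with pytest.raises(TrainingError):
            run_loocv(samples[:5], ["A"] * 5, tiny_settings)


class TestBaselines:
    def _blobs(self, montage, sep=10.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        samples, labels = [], []
        for i in range(n):
            cls = "A" if i % 2 == 0 else "B"
            mu = 0.0 if cls == "A" else sep
            data = rng.normal(mu, 1.0, size=(4, 50))
            samples.append(erpsnn.ERPSample(f"p{i}", "experimental", "T1",
                                            "target", data,
                                            ("c1", "c2", "c3", "c4")))
            labels.append(cls)
        return samples, labels

    def test_separable_blobs_svm_perfect(self, montage):
        samples, labels = self._blobs(montage)
        acc = run_baselines(samples, labels, methods=("svm",))
        assert acc == {"svm": 1.0}

    def test_all_requested_methods_reported(self, montage):
        samples, labels = self._blobs(montage)
        acc = run_baselines(samples, labels, methods=("svm", "mlr", "mlp"),
                            mlp_max_iter=200)
        assert set(acc) == {"svm", "mlr", "mlp"}
        assert acc["mlr"] == 1.0

    def test_unknown_method_rejected(self, montage):
        samples, labels = self._blobs(montage)
        with pytest.raises(ValueError, match="unknown"):
            run_baselines(samples, labels, methods=("forest",))


def test_loo_plan_requires_unique_holdouts():
    from erpsnn.desnn import LOOPlan

    plan = LOOPlan(held_out=("a", "b", "c"))
    assert plan.n == 3
    with pytest.raises(TrainingError):
        LOOPlan(held_out=("a", "a"))
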