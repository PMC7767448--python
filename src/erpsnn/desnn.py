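"""Dynamic evolving SNN (deSNN) output layer, LOOCV evaluation, and
conventional baselines.

For every training sample one output neuron is created, fully connected to
the reservoir.  Its weight to reservoir neuron ``r`` is initialised by the
rank-order rule ``w_r = mod ** order(r)`` where ``order(r)`` is the rank of
``r``'s first firing (0 for the earliest; never-firing neurons get weight 0),
then incremented by ``drift`` for each of ``r``'s subsequent firings.  A test
sample is turned into an output neuron by the same rule and labelled by the
majority class among its k nearest trained neurons (Euclidean distance on
weight vectors); ties are broken by the smaller mean distance, then by class
order.

Leave-one-out evaluation follows the train-from-scratch protocol: for each
fold a fresh reservoir is initialised (seeded by the held-out sample's id, so
fold results do not depend on sample ordering), STDP-trained on the n-1
training samples, and the held-out sample is classified once.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncoderConfig, encode_sample
from .reservoir import (
    LIFConfig,
    NeuronGrid,
    Reservoir,
    STDPConfig,
    SWCConfig,
    build_reservoir,
    run_stdp,
)

__all__ = [
    "DeSNNConfig",
    "OutputNeuron",
    "TrainedClassifier",
    "ClassificationReport",
    "LOOPlan",
    "rank_order_weights",
    "train_desnn",
    "classify",
    "run_loocv",
    "run_baselines",
    "sample_key",
    "fold_seed",
]

_NO_STDP = STDPConfig(a_plus=0.0, a_minus=0.0, tau_ms=1.0, w_max=1.0)


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class DeSNNConfig:
    mod: float = 0.9
    drift: float = 0.25
    k_neighbors: int = 1

    def __post_init__(self):
        if not 0 < self.mod <= 1:
            raise ValueError("mod must lie in (0, 1]")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class OutputNeuron:
    weights: np.ndarray
    label: str
    source_id: str


@dataclass(frozen=True)
class TrainedClassifier:
    neurons: tuple
    config: DeSNNConfig
    n_reservoir: int

    @property
    def labels(self) -> tuple:
        return tuple(sorted({n.label for n in self.neurons}))

    def weight_matrix(self) -> np.ndarray:
        return np.vstack([n.weights for n in self.neurons])


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix (true class rows x predicted class columns) with the
    derived per-class accuracy, total accuracy and macro F-score."""

    confusion: pd.DataFrame
    predictions: pd.DataFrame  # sample_id, true, predicted

    @property
    def classes(self) -> tuple:
        return tuple(self.confusion.index)

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion), index=self.confusion.index)
        return diag / self.confusion.sum(axis=1)

    @property
    def total_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.to_numpy().sum())

    @property
    def macro_f1(self) -> float:
        cm = self.confusion.to_numpy(dtype=float)
        f1s = []
        for i in range(cm.shape[0]):
            tp = cm[i, i]
            prec = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
            rec = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        return float(np.mean(f1s))


@dataclass(frozen=True)
class LOOPlan:
    """Fold index -> held-out sample id; exactly one fold per sample."""

    held_out: tuple

    def __post_init__(self):
        if len(set(self.held_out)) != len(self.held_out):
            raise TrainingError("each sample must be held out exactly once")

    @property
    def n(self) -> int:
        return len(self.held_out)


def sample_key(sample) -> str:
    return f"{sample.participant_id}|{sample.time_point}|{sample.stimulus}"


def fold_seed(base_seed: int, key: str) -> int:
    """Stable 31-bit seed keyed to (base seed, sample id)."""
    return int((zlib.crc32(key.encode()) ^ (base_seed * 0x9E3779B1)) % (2**31))


# --------------------------------------------------------------------------
# deSNN core
# --------------------------------------------------------------------------

def rank_order_weights(log, config: DeSNNConfig) -> np.ndarray:
    """Weight vector for one firing log: mod**rank init plus drift updates."""
    first = log.first_spike_times()
    counts = log.spike_counts()
    w = np.zeros(log.n_neurons, dtype=float)
    fired = np.flatnonzero(first >= 0)
    if fired.size:
        order = fired[np.lexsort((fired, first[fired]))]
        w[order] = config.mod ** np.arange(order.size)
        w[fired] += config.drift * (counts[fired] - 1)
    return w


def train_desnn(firing_logs, labels, config: DeSNNConfig = DeSNNConfig(),
                sample_ids=None) -> TrainedClassifier:
    """Create one labelled output neuron per training sample."""
    logs = list(firing_logs)
    labels = [str(x) for x in labels]
    if not logs:
        raise TrainingError("empty training set")
    if len(logs) != len(labels):
        raise TrainingError("number of firing logs and labels differ")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(len(logs))]
    n_res = logs[0].n_neurons
    neurons = tuple(
        OutputNeuron(rank_order_weights(log, config), lab, sid)
        for log, lab, sid in zip(logs, labels, sample_ids)
    )
    return TrainedClassifier(neurons=neurons, config=config, n_reservoir=n_res)


def classify(test_log, classifier: TrainedClassifier):
    """Label a test firing log by kNN over deSNN weight vectors.

    Returns the predicted label and a neighbour report (one row per trained
    neuron, nearest first, with the k nearest flagged).
    """
    cfg = classifier.config
    k = cfg.k_neighbors
    if k > len(classifier.neurons):
        raise ValueError(
            f"k_neighbors={k} exceeds number of trained neurons "
            f"({len(classifier.neurons)})"
        )
    test_w = rank_order_weights(test_log, cfg)
    mat = classifier.weight_matrix()
    dists = np.linalg.norm(mat - test_w[None, :], axis=1)
    order = np.argsort(dists, kind="stable")
    report = pd.DataFrame(
        {
            "source_id": [classifier.neurons[i].source_id for i in order],
            "label": [classifier.neurons[i].label for i in order],
            "distance": dists[order],
            "is_neighbor": [i < k for i in range(len(order))],
        }
    )
    top = order[:k]
    votes: dict = {}
    for i in top:
        lab = classifier.neurons[i].label
        votes.setdefault(lab, []).append(dists[i])
    max_votes = max(len(v) for v in votes.values())
    tied = sorted(lab for lab, v in votes.items() if len(v) == max_votes)
    if len(tied) > 1:
        tied.sort(key=lambda lab: (float(np.mean(votes[lab])), lab))
    return tied[0], report


# --------------------------------------------------------------------------
# leave-one-out over the full pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LoocvSettings:
    """Everything the per-fold pipeline needs besides the samples."""

    grid: NeuronGrid
    montage: object
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    swc: SWCConfig = field(default_factory=SWCConfig)
    lif: LIFConfig = field(default_factory=LIFConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    desnn: DeSNNConfig = field(default_factory=DeSNNConfig)
    stdp_passes: int = 1
    base_seed: int = 0


def _fold_reservoir(settings: LoocvSettings, key: str) -> Reservoir:
    from dataclasses import replace as dc_replace

    swc = dc_replace(settings.swc, seed=fold_seed(settings.base_seed, key))
    return build_reservoir(settings.grid, settings.montage, swc)


def run_loocv(samples, labels, settings: LoocvSettings) -> ClassificationReport:
    """Leave-one-out evaluation of the full encode/train/classify pipeline.

    For each fold the reservoir is re-initialised with a seed keyed to the
    held-out sample's id, STDP-trained on the remaining samples (in
    canonical id order, so shuffling the input does not change results),
    and the held-out sample is classified with the deSNN layer.
    """
    samples = list(samples)
    labels = [str(x) for x in labels]
    if len(samples) < 2:
        raise TrainingError("need at least 2 samples for leave-one-out")
    if len(set(labels)) < 2:
        raise TrainingError("need at least 2 classes")
    keys = [sample_key(s) for s in samples]
    if len(set(keys)) != len(keys):
        raise TrainingError("sample ids are not unique")
    from collections import Counter

    for lab, cnt in Counter(labels).items():
        if cnt == 1:
            import warnings

            warnings.warn(f"class {lab!r} has a single sample; its fold will "
                          "train without that class", stacklevel=2)
    spike_sets = {k: encode_sample(s, settings.encoder) for k, s in zip(keys, samples)}
    order = np.argsort(keys, kind="stable")
    plan = LOOPlan(held_out=tuple(keys))
    rows = []
    for held in range(plan.n):
        res = _fold_reservoir(settings, keys[held])
        train_idx = [i for i in order if i != held]
        for i in train_idx:
            res, _ = run_stdp(res, spike_sets[keys[i]], settings.lif,
                              settings.stdp, passes=settings.stdp_passes,
                              record=False)
        logs = []
        for i in train_idx:
            _, log = run_stdp(res, spike_sets[keys[i]], settings.lif,
                              _NO_STDP, record=True)
            logs.append(log)
        clf = train_desnn(logs, [labels[i] for i in train_idx],
                          settings.desnn, [keys[i] for i in train_idx])
        _, test_log = run_stdp(res, spike_sets[keys[held]], settings.lif,
                               _NO_STDP, record=True)
        pred, _ = classify(test_log, clf)
        rows.append({"sample_id": keys[held], "true": labels[held], "predicted": pred})
    preds = pd.DataFrame(rows)
    classes = sorted(set(labels))
    confusion = pd.crosstab(preds["true"], preds["predicted"]).reindex(
        index=classes, columns=classes, fill_value=0
    )
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    return ClassificationReport(confusion=confusion, predictions=preds)


# --------------------------------------------------------------------------
# conventional baselines
# --------------------------------------------------------------------------

def run_baselines(samples, labels, methods=("mlp", "svm", "mlr"),
                  seed: int = 0, mlp_max_iter: int = 500) -> dict:
    """LOOCV accuracy of conventional classifiers on flattened samples.

    Each sample's channel x time matrix becomes one feature vector.  Methods:
    ``mlp`` (one hidden layer of 20), ``svm`` (RBF kernel, default
    regularisation), ``mlr`` (one-vs-rest linear regression with argmax
    labelling).  These are comparison plumbing with fixed hyperparameters.
    """
    from sklearn.linear_model import LinearRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    known = {"mlp", "svm", "mlr"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown baseline methods {sorted(unknown)}; known: {sorted(known)}")
    X = np.vstack([s.data.ravel() for s in samples])
    y = np.array([str(x) for x in labels])
    classes = np.array(sorted(set(y)))
    out = {}
    for method in methods:
        correct = 0
        for held in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[held] = False
            scaler = StandardScaler().fit(X[mask])
            Xtr, Xte = scaler.transform(X[mask]), scaler.transform(X[held][None, :])
            ytr = y[mask]
            if method == "svm":
                pred = SVC(kernel="rbf").fit(Xtr, ytr).predict(Xte)[0]
            elif method == "mlp":
                clf = MLPClassifier(hidden_layer_sizes=(20,), max_iter=mlp_max_iter,
                                    random_state=seed)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pred = clf.fit(Xtr, ytr).predict(Xte)[0]
            else:  # mlr: one-vs-rest linear regression, argmax labelling
                Y = (ytr[:, None] == classes[None, :]).astype(float)
                reg = LinearRegression().fit(Xtr, Y)
                pred = classes[int(np.argmax(reg.predict(Xte)[0]))]
            correct += pred == y[held]
        out[method] = correct / len(y)
    return out
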