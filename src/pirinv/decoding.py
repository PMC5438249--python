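"""Linear decoding of odor identity from single-trial population vectors.

Classifiers: linear discriminant analysis on the principal components
capturing 95% of training-fold variance (default, refit inside every fold so
no test information leaks into the basis), or a one-vs-all linear SVM on the
raw responses.  All accuracies come from leave-one-out cross-validation: the
assessed trial is excluded from the fit.  Besides plain identity decoding
this module implements time-resolved decoding on a five-frame sliding
window, train-at-one-timepoint/test-over-time generalization, and the
7-group concentration-generalization task in which the tested odorant is
represented in the training set only by its most distant concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import LinearSVC

from .core import ResponseTable, TrialTensor

METHODS = ("lda-on-pcs", "linear-svm-ova")


@dataclass
class DecodingResult:
    """Confusion matrix and accuracy of one decoding task."""

    confusion: np.ndarray                # true x predicted counts
    accuracy: float                      # %
    chance: float                        # %
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _fit_predict(method: str, x_train: np.ndarray, y_train: np.ndarray,
                 x_test: np.ndarray, pca_variance: float = 0.95
                 ) -> np.ndarray:
    if x_train.std() == 0:
        # degenerate (constant) training data carries no information;
        # deterministic tie-break: lowest class index
        return np.full(len(x_test), np.min(y_train))
    if method == "lda-on-pcs":
        pca = PCA(n_components=pca_variance, svd_solver="full")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xt = pca.fit_transform(x_train)
            # uniform priors: LOO folds unbalance class counts by one trial,
            # and empirical priors would bias predictions away from the
            # held-out trial's class
            k = len(np.unique(y_train))
            clf = LinearDiscriminantAnalysis(priors=np.full(k, 1.0 / k))
            clf.fit(xt, y_train)
            return clf.predict(pca.transform(x_test))
    elif method == "linear-svm-ova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LinearSVC(C=1.0)
            clf.fit(x_train, y_train)
            return clf.predict(x_test)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _loo_masks(y: np.ndarray, balanced: bool):
    """Training mask per fold; balanced folds equalize class counts.

    Plain LOO leaves the tested trial's class with one fewer training trial
    than every other class, so its centroid is estimated with higher
    variance and, on pure noise, sits systematically farther from the test
    point — accuracy on label-permuted data then falls below chance.  With
    ``balanced=True`` (and equal class counts) each fold also drops the
    same-position trial of every other class, which removes that bias.
    """
    n = len(y)
    counts = np.bincount(y)
    # balancing needs equal counts and >= 2 training trials per class
    use_balanced = balanced and counts.min() == counts.max() \
        and counts.min() >= 3
    # within-class position of every trial, in storage order
    position = np.empty(n, dtype=int)
    for k in range(counts.size):
        idx = np.flatnonzero(y == k)
        position[idx] = np.arange(len(idx))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        if use_balanced:
            mask[position == position[i]] = False
        else:
            mask[i] = False
        yield i, mask


def classify_loo(vectors: np.ndarray, labels: np.ndarray,
                 method: str = "lda-on-pcs",
                 balanced: bool = True) -> DecodingResult:
    """Leave-one-out classification of trial vectors (n_trials, n_cells)."""
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 distinct labels")
    counts = np.bincount(y)
    if counts.min() < 2:
        bad = classes[counts < 2]
        raise ValueError(f"labels with a single trial cannot be "
                         f"cross-validated: {bad.tolist()}")
    n = len(y)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    correct = 0
    for i, mask in _loo_masks(y, balanced):
        pred = _fit_predict(method, vectors[mask], y[mask], vectors[i:i + 1])
        confusion[y[i], pred[0]] += 1
        correct += int(pred[0] == y[i])
    return DecodingResult(confusion=confusion,
                          accuracy=100.0 * correct / n,
                          chance=100.0 / classes.size,
                          row_labels=classes.tolist(),
                          col_labels=classes.tolist())


def _window_vectors(tensor: TrialTensor, start: int, width: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated signal per trial over [start, start+width) frames."""
    n_cells, n_stim, n_trials, n_frames = tensor.data.shape
    if start + width > n_frames:
        raise ValueError("window extends past the end of the trace")
    w = tensor.data[..., start:start + width].sum(axis=-1)
    vectors = w.reshape(n_cells, n_stim * n_trials).T
    labels = np.repeat(np.arange(n_stim), n_trials)
    return vectors, labels


def time_resolved_decoding(tensor: TrialTensor, window_frames: int = 5,
                           step: int = 1, method: str = "lda-on-pcs"
                           ) -> pd.DataFrame:
    """LOO accuracy of a sliding accumulation window across the trial."""
    n_frames = tensor.data.shape[-1]
    if window_frames > n_frames:
        raise ValueError("window longer than the trace")
    starts = np.arange(0, n_frames - window_frames + 1, step)
    rows = []
    for s in starts:
        vectors, labels = _window_vectors(tensor, int(s), window_frames)
        res = classify_loo(vectors, labels, method)
        rows.append({"start_frame": int(s),
                     "time_s": (s + window_frames / 2) / tensor.frame_rate,
                     "accuracy": res.accuracy, "chance": res.chance})
    return pd.DataFrame(rows)


def train_at_timepoint(tensor: TrialTensor, t_train_s: list[float],
                       window_frames: int = 5, step: int = 1,
                       method: str = "lda-on-pcs") -> pd.DataFrame:
    """Train at fixed post-onset times, test across the whole trial.

    For every training time and every LOO fold, the classifier is fitted on
    the training trials' window at t_train and evaluated on the held-out
    trial's window at every test time (train/test trials stay disjoint).
    """
    n_frames = tensor.data.shape[-1]
    onset = tensor.onset_frame
    starts = np.arange(0, n_frames - window_frames + 1, step)
    _, labels = _window_vectors(tensor, 0, window_frames)
    n = len(labels)
    rows = []
    for t_tr in t_train_s:
        tr_start = onset + int(round(t_tr * tensor.frame_rate))
        if tr_start + window_frames > n_frames:
            raise ValueError(f"training time {t_tr} s is past the trace end")
        x_tr_full, _ = _window_vectors(tensor, tr_start, window_frames)
        test_vectors = {int(s): _window_vectors(tensor, int(s),
                                                window_frames)[0]
                        for s in starts}
        correct = {int(s): 0 for s in starts}
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            for s in starts:
                pred = _fit_predict(method, x_tr_full[mask], labels[mask],
                                    test_vectors[int(s)][i:i + 1])
                correct[int(s)] += int(pred[0] == labels[i])
        for s in starts:
            rows.append({"t_train_s": t_tr, "start_frame": int(s),
                         "time_s": (s + window_frames / 2)
                         / tensor.frame_rate,
                         "accuracy": 100.0 * correct[int(s)] / n,
                         "chance": 100.0 / len(np.unique(labels))})
    return pd.DataFrame(rows)


def generalization_training_groups(odorants: list[str],
                                   dilutions: list[float],
                                   test_odorant: str,
                                   test_dilution: float
                                   ) -> list[tuple[str, float]]:
    """The seven training (odorant, dilution) groups for one test stimulus.

    The tested odorant contributes a single group at its most distant
    dilution (for the middle dilution, the lower one); the two other
    odorants contribute one group per dilution.  The first entry is always
    the tested odorant's group.
    """
    odorants = sorted(odorants)
    dilutions = sorted(dilutions)
    far_of = {0: 2, 1: 0, 2: 0}
    far_d = dilutions[far_of[dilutions.index(test_dilution)]]
    others = [o for o in odorants if o != test_odorant]
    return [(test_odorant, far_d)] + [(o, d) for o in others
                                      for d in dilutions]


def concentration_generalization(table: ResponseTable,
                                 method: str = "lda-on-pcs"
                                 ) -> DecodingResult:
    """7-group odor-identity decoding across concentrations.

    For a test trial of odorant o at dilution d, the classifier trains on o
    at the single most distant dilution (for the middle dilution, the lower
    one) plus the two other odorants at all three dilutions — seven training
    groups.  A prediction is correct iff the trial is assigned to o's group
    (chance 1/7 = 14%).  The confusion matrix has one row per tested
    (odorant, dilution) and columns [own odorant, other stimuli...];
    ``extras`` carries per-test-stimulus accuracy and the accuracy restricted
    to the 100-fold (lowest/highest dilution) tests.
    """
    stimuli = table.stimuli
    odorants = sorted({o for o, _ in stimuli})
    dilutions = sorted({d for _, d in stimuli})
    if len(odorants) != 3 or len(dilutions) != 3 or len(stimuli) != 9:
        raise ValueError("task requires exactly 3 odorants x 3 dilutions")
    responses = table.array()                      # cells x 9 x trials
    if np.isnan(responses).any():
        raise ValueError("missing responses for some stimulus cells")
    n_trials = responses.shape[2]
    stim_index = {s: k for k, s in enumerate(stimuli)}

    n_test = len(stimuli) * n_trials
    confusion = np.zeros((9, 7), dtype=int)
    per_stim_correct = np.zeros(9)
    for si, (o, d) in enumerate(stimuli):
        train_groups = generalization_training_groups(odorants, dilutions,
                                                      o, d)
        x_parts, y_parts = [], []
        for g, (oo, dd) in enumerate(train_groups):
            resp = responses[:, stim_index[(oo, dd)], :]
            x_parts.append(resp.T)
            y_parts.append(np.full(n_trials, g))
        x_train = np.vstack(x_parts)
        y_train = np.concatenate(y_parts)
        x_test = responses[:, si, :].T
        pred = _fit_predict(method, x_train, y_train, x_test)
        for p in pred:
            confusion[si, p] += 1
        per_stim_correct[si] = (pred == 0).mean()

    accuracy = 100.0 * confusion[:, 0].sum() / n_test
    hundredfold = [si for si, (_, d) in enumerate(stimuli)
                   if dilutions.index(d) in (0, 2)]
    acc_100 = 100.0 * float(np.mean(per_stim_correct[hundredfold]))
    per_stim = pd.DataFrame({
        "odorant": [o for o, _ in stimuli],
        "dilution": [d for _, d in stimuli],
        "accuracy": per_stim_correct * 100.0,
    })
    return DecodingResult(
        confusion=confusion, accuracy=accuracy, chance=100.0 / 7,
        row_labels=list(stimuli),
        col_labels=["own_odorant"] + [f"other_{g}" for g in range(1, 7)],
        extras={"per_stimulus": per_stim, "accuracy_100fold": acc_100})
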