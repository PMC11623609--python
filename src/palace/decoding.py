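"""Leave-one-participant-out template decoding and network selection.

Classifiers are multinomial logistic models trained on the (N-1) other
participants' GLM templates (one row per condition per participant) and
applied to every timepoint of the held-out participant's runs, yielding a
per-TR probability distribution over the 23 condition classes ("evidence").
Training across participants breaks the within-participant room-object
confound: every participant has their own random pairing, so any room
information bleeding into object templates is unrelated across people.

Networks (ROCN / POCN / RRCN) are the top-k units by the z-score of true
classification accuracy against a temporal-contiguity-preserving label
permutation null, averaged across participants and runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .events import NO_LABEL, EventMatrix

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "NetworkMask",
    "train_classifier",
    "predict_evidence",
    "score_accuracy",
    "contiguity_null",
    "select_network",
    "reinstatement_scores",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """L2-penalized multinomial logistic settings, fixed across folds."""

    n_classes: int = 23
    regularization_strength: float = 1.0  # sklearn C (inverse penalty)
    max_iter: int = 200
    tol: float = 1e-3
    feature_standardization: bool = True


@dataclass
class TrainedClassifier:
    model: LogisticRegression
    spec: ClassifierSpec
    feature_mean: Optional[np.ndarray]
    feature_sd: Optional[np.ndarray]

    @property
    def n_features(self) -> int:
        return self.model.coef_.shape[1]

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_sd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self._transform(x))


@dataclass
class NetworkMask:
    """Top-k classifier units (searchlights and/or ROIs) with their z-scores."""

    name: str  # "rocn" | "pocn" | "rrcn" | ...
    members: np.ndarray
    zscores: np.ndarray  # selection z per candidate unit (full pool)

    @property
    def k(self) -> int:
        return len(self.members)


def train_classifier(
    template_sets: Sequence,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the multinomial classifier on stacked (N-1)-participant templates."""
    if len(template_sets) < 2:
        raise ValueError("need templates from at least 2 training participants")
    xs, ys = [], []
    for ts in template_sets:
        patterns = np.asarray(getattr(ts, "patterns", ts), float)
        ids = np.asarray(
            getattr(ts, "condition_ids", np.arange(patterns.shape[0])), int
        )
        xs.append(patterns)
        ys.append(ids)
    X = np.vstack(xs)
    y = np.concatenate(ys)
    present = np.unique(y)
    if len(present) < spec.n_classes:
        missing = sorted(set(range(spec.n_classes)) - set(present.tolist()))
        raise ValueError(f"classes missing from training set: {missing}")
    mean = sd = None
    if spec.feature_standardization:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        X = (X - mean) / sd
    model = LogisticRegression(
        C=spec.regularization_strength,
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return TrainedClassifier(model=model, spec=spec, feature_mean=mean,
                             feature_sd=sd)


def predict_evidence(
    classifier: TrainedClassifier,
    timeseries: np.ndarray,
    hrf_shift_tr: int = 4,
) -> np.ndarray:
    """Per-event-TR class probabilities, hemodynamically aligned.

    The probability reported for event TR ``t`` is computed from the signal
    at TR ``t + hrf_shift_tr`` (the label sequence is shifted forward onto
    the delayed BOLD response); the trailing ``hrf_shift_tr`` event TRs have
    no shifted signal and are dropped.
    """
    data = np.asarray(getattr(timeseries, "data", timeseries), float)
    if data.ndim == 1:
        data = data[None, :]
    n_tr = data.shape[0]
    if n_tr <= hrf_shift_tr:
        raise ValueError(
            f"timeseries has {n_tr} TRs, shorter than shift {hrf_shift_tr}"
        )
    return classifier.predict_proba(data[hrf_shift_tr:])


def _labels_of(events) -> np.ndarray:
    return np.asarray(getattr(events, "labels", events), int)


def score_accuracy(evidence: np.ndarray, events) -> float:
    """Fraction of labeled event TRs whose argmax class matches the label.

    Only the first ``len(evidence)`` event TRs are scored (the rest were
    dropped by the shift); argmax ties resolve to the lowest class id.
    """
    P = np.asarray(evidence, float)
    labels = _labels_of(events)[: len(P)]
    mask = labels != NO_LABEL
    if not mask.any():
        return float("nan")
    pred = np.argmax(P[mask], axis=1)
    return float(np.mean(pred == labels[mask]))


def _segments_of_labels(labels: np.ndarray) -> list:
    """Maximal contiguous labeled stretches as (start, stop, label)."""
    segs = []
    n = len(labels)
    t = 0
    while t < n:
        if labels[t] == NO_LABEL:
            t += 1
            continue
        start = t
        while t < n and labels[t] == labels[start]:
            t += 1
        segs.append((start, t, int(labels[start])))
    return segs


def contiguity_null(
    events,
    evidence: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Label-permutation null that preserves temporal contiguity.

    The label sequence is decomposed into maximal contiguous segments; each
    permutation shuffles the segment labels across segments (uniformly,
    without replacement), keeping boundaries and lengths fixed, and the
    accuracy is recomputed. Returns the n_perm null accuracies.
    """
    P = np.asarray(evidence, float)
    labels = _labels_of(events)[: len(P)]
    segs = _segments_of_labels(labels)
    if len(segs) < 2:
        raise ValueError("need >= 2 contiguous label segments for the null")
    pred = np.argmax(P, axis=1)
    n_classes = P.shape[1]
    n_labeled = sum(stop - start for start, stop, _ in segs)
    # counts[s, c] = # TRs in segment s predicted as class c
    counts = np.zeros((len(segs), n_classes))
    for k, (start, stop, _) in enumerate(segs):
        idx, cnt = np.unique(pred[start:stop], return_counts=True)
        counts[k, idx] = cnt
    seg_labels = np.array([lab for _, _, lab in segs])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(segs))
        null[i] = counts[np.arange(len(segs)), seg_labels[perm]].sum() / n_labeled
    return null


def select_network(
    true_accuracy: np.ndarray,
    null_accuracy: np.ndarray,
    k: int = 50,
    name: str = "rocn",
    unit_ids: Optional[np.ndarray] = None,
) -> NetworkMask:
    """Top-k candidate units by accuracy z-score against their null.

    ``true_accuracy`` (n_units,) and ``null_accuracy`` (n_units, n_perm)
    must be averaged across participants and runs the same way. z = (true -
    null mean) / null sd; zero-sd units are excluded (z = -inf) with a
    warning; ties break toward the lowest unit id.
    """
    true_accuracy = np.asarray(true_accuracy, float)
    null_accuracy = np.asarray(null_accuracy, float)
    n_units = len(true_accuracy)
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    if k > n_units:
        raise ValueError(f"k={k} exceeds {n_units} candidate units")
    mu = null_accuracy.mean(axis=1)
    sd = null_accuracy.std(axis=1, ddof=1)
    z = np.full(n_units, -np.inf)
    ok = sd > 1e-12
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} unit(s) with zero null sd excluded")
    z[ok] = (true_accuracy[ok] - mu[ok]) / sd[ok]
    # stable sort on (-z, unit index): ties -> lowest id
    order = np.lexsort((np.arange(n_units), -z))
    members = np.sort(unit_ids[order[:k]])
    return NetworkMask(name=name, members=members, zscores=z)


def reinstatement_scores(
    evidence_runs: Sequence[np.ndarray],
    label_runs: Sequence[np.ndarray],
    n_classes: int,
) -> np.ndarray:
    """Mean class evidence over the pooled TRs where each class was recalled.

    ``evidence_runs[i]`` is a (T_i, n_classes) network-averaged evidence
    matrix and ``label_runs[i]`` the matching per-TR recall labels (-1 for
    none). TRs are pooled across runs (a TR-pooled mean, not a mean of
    per-run means). Classes never recalled get NaN.
    """
    if len(evidence_runs) != len(label_runs):
        raise ValueError("need one label array per evidence run")
    total = np.zeros(n_classes)
    count = np.zeros(n_classes)
    for P, labels in zip(evidence_runs, label_runs):
        P = np.asarray(P, float)
        labels = np.asarray(labels, int)[: len(P)]
        for c in range(n_classes):
            mask = labels == c
            if mask.any():
                total[c] += P[mask, c].sum()
                count[c] += mask.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)
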