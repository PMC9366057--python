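"""Generative two-network classifier and its shuffle-split evaluation.

One linear-Gaussian network is learned and fitted per diagnostic group; a
new profile is assigned to the group under whose network it is more
probable.  With group proportions fixed by the matched design, the decision
statistic is the log likelihood ratio

    score(x) = log p(x | healthy net) - log p(x | schizophrenia net)
               + log prior odds,

positive favouring healthy.  Evaluation follows a repeated random
shuffle-split protocol (stratified 80/20 by default) with accuracy, F1
(schizophrenia positive) and rank-based AUC aggregated over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort
from .errors import FittingError, MmpiBnError
from .gbn import GaussianNetwork, fit_parameters, log_density
from .structure import learn_structure

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "fit_classifier",
    "score_profile",
    "classify_profile",
    "compute_metrics",
    "evaluate_rsscv",
    "baseline_scale278",
]

HEALTHY, SCHIZOPHRENIA = 0, 1
BASELINE_SCALES = ("D", "Pt", "Sc")  # clinical scales 2, 7 and 8


@dataclass(frozen=True)
class ClassifierModel:
    """Two fitted group networks plus the log prior odds (healthy : schiz)."""

    net_healthy: GaussianNetwork
    net_schiz: GaussianNetwork
    log_prior_odds: float = 0.0

    def __post_init__(self) -> None:
        if self.net_healthy.nodes != self.net_schiz.nodes:
            raise ValueError("both networks must share the same node order")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.net_healthy.nodes


@dataclass(frozen=True)
class EvalReport:
    accuracy_mean: float
    accuracy_sd: float
    f1_mean: float
    f1_sd: float
    auc_mean: float
    auc_sd: float
    iterations: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy_mean": self.accuracy_mean, "accuracy_sd": self.accuracy_sd,
            "f1_mean": self.f1_mean, "f1_sd": self.f1_sd,
            "auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
            "iterations": self.iterations,
        }


def fit_classifier(train: Cohort, alpha: float = 0.05) -> ClassifierModel:
    """Learn structure and fit parameters independently per diagnosis stratum.

    ``log_prior_odds`` is ln(n_healthy / n_schiz) of the training split,
    hence 0 under a matched balanced design.
    """
    nets = {}
    counts = {}
    for label, name in ((HEALTHY, "healthy"), (SCHIZOPHRENIA, "schizophrenia")):
        stratum = train.stratum(label)
        counts[name] = len(stratum)
        if len(stratum) < 20:
            raise FittingError(
                f"{name} stratum too small to fit a network (n={len(stratum)})")
        dag = learn_structure(stratum.profiles, alpha=alpha)
        nets[name] = fit_parameters(dag, stratum.profiles)
    return ClassifierModel(nets["healthy"], nets["schizophrenia"],
                           float(np.log(counts["healthy"] / counts["schizophrenia"])))


def score_profile(model: ClassifierModel, profile) -> float:
    """Log likelihood ratio (+ log prior odds); positive favours healthy."""
    return (log_density(model.net_healthy, profile)
            - log_density(model.net_schiz, profile)
            + model.log_prior_odds)


def classify_profile(model: ClassifierModel, profile, threshold: float = 0.0) -> int:
    """0 (healthy) iff the score is >= threshold (exact ties go healthy)."""
    return HEALTHY if score_profile(model, profile) >= threshold else SCHIZOPHRENIA


def _rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC with ties credited 0.5 (scores oriented to class 1)."""
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n0 == 0 or n1 == 0:
        raise MmpiBnError("AUC undefined: only one class present in truth")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def compute_metrics(predicted, scores, truth) -> tuple[float, float, float]:
    """(accuracy, F1, AUC); schizophrenia (label 1) is the positive class.

    ``scores`` must be oriented so larger values favour schizophrenia (the
    evaluation protocols pass the negated likelihood-ratio score).
    """
    predicted = np.asarray(predicted, dtype=int)
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not predicted.shape == scores.shape == truth.shape:
        raise ValueError("predicted, scores and truth must have equal length")
    accuracy = float(np.mean(predicted == truth))
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return accuracy, f1, _rank_auc(scores, truth)


def _stratified_splits(labels: np.ndarray, iterations: int, train_frac: float,
                       seed: int):
    """Yield (train_idx, test_idx) per iteration, reproducible from seed."""
    children = np.random.SeedSequence(seed).spawn(iterations)
    strata = [np.flatnonzero(labels == v) for v in (0, 1)]
    for child in children:
        rng = np.random.default_rng(child)
        train, test = [], []
        for idx in strata:
            perm = rng.permutation(idx)
            cut = int(round(train_frac * idx.size))
            train.append(perm[:cut])
            test.append(perm[cut:])
        yield np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _aggregate(rows: list[tuple[float, float, float]]) -> EvalReport:
    arr = np.asarray(rows, dtype=float)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(3)
    mean = arr.mean(axis=0)
    return EvalReport(mean[0], sd[0], mean[1], sd[1], mean[2], sd[2],
                      arr.shape[0])


def evaluate_rsscv(cohort: Cohort, iterations: int = 100,
                   train_frac: float = 0.8, alpha: float = 0.05,
                   seed: int = 0) -> EvalReport:
    """Repeated stratified shuffle-split evaluation of the dual-network model.

    Structure is re-learned inside every iteration, so no information leaks
    from test to train.  Fully reproducible from ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if len(np.unique(cohort.labels)) < 2:
        raise MmpiBnError("cohort must contain both classes")
    rows = []
    for i, (train_idx, test_idx) in enumerate(
            _stratified_splits(cohort.labels, iterations, train_frac, seed)):
        try:
            model = fit_classifier(cohort.subset(train_idx), alpha=alpha)
            test = cohort.subset(test_idx)
            x = test.profiles.to_numpy(dtype=float)
            scores = np.array([score_profile(model, row) for row in x])
            predicted = np.where(scores >= 0, HEALTHY, SCHIZOPHRENIA)
            rows.append(compute_metrics(predicted, -scores, test.labels))
        except MmpiBnError as exc:
            raise MmpiBnError(f"iteration {i} failed: {exc}") from exc
    return _aggregate(rows)


def baseline_scale278(cohort: Cohort, iterations: int = 100,
                      train_frac: float = 0.8, seed: int = 0) -> EvalReport:
    """Logistic-regression comparison model on clinical scales 2, 7 and 8
    (D, Pt, Sc), evaluated under the identical split protocol."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    x_all = cohort.profiles.loc[:, list(BASELINE_SCALES)].to_numpy(dtype=float)
    rows = []
    for train_idx, test_idx in _stratified_splits(cohort.labels, iterations,
                                                  train_frac, seed):
        clf = LogisticRegression(C=np.inf, max_iter=1000)  # plain MLE, no penalty
        clf.fit(x_all[train_idx], cohort.labels[train_idx])
        proba = clf.predict_proba(x_all[test_idx])[:, 1]
        predicted = (proba >= 0.5).astype(int)
        rows.append(compute_metrics(predicted, proba, cohort.labels[test_idx]))
    return _aggregate(rows)
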