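"""Propensity-score matching of the two diagnostic groups on demographics.

A main-effects logistic model of diagnosis on age, gender, education and
marital status supplies the propensity scores; greedy nearest-neighbour 1:1
matching without replacement on the logit scale (caliper expressed in SDs of
the logit) balances the groups.  Balance is assessed by standardized mean
differences (SMDs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort
from .errors import MatchingError
from .scales import DEMOGRAPHIC_COLUMNS

__all__ = [
    "MatchResult",
    "estimate_propensity",
    "match_cohort",
    "standardized_mean_differences",
    "match_study",
]

_SATURATION = 1e-10


@dataclass(frozen=True)
class MatchResult:
    """1:1 matching outcome: matched index pairs, scores, leftovers."""

    pairs: tuple[tuple[int, int], ...]  # (group-0 index, group-1 index)
    propensity: np.ndarray
    unmatched: tuple[int, ...]

    def matched_indices(self) -> np.ndarray:
        """All matched row indices (both groups), sorted."""
        flat = [i for pair in self.pairs for i in pair]
        return np.array(sorted(flat), dtype=int)


def estimate_propensity(demographics: pd.DataFrame, labels) -> np.ndarray:
    """Per-row probability of diagnosis 1 from a main-effects logistic model."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise MatchingError("both classes required to estimate propensity")
    x = demographics.loc[:, list(DEMOGRAPHIC_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise MatchingError("missing or non-finite covariates")
    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels, design).fit(disp=0, maxiter=200)
        scores = np.asarray(fit.predict(design), dtype=float)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise MatchingError(
            "perfect separation in the propensity model; consider exact "
            "matching without a caliper") from exc
    if np.any(scores <= _SATURATION) or np.any(scores >= 1 - _SATURATION):
        raise MatchingError(
            "propensity scores saturated at 0/1 (quasi-separation); consider "
            "exact matching without a caliper")
    return scores


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def match_cohort(scores, labels, caliper: float = 0.2) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching without replacement.

    Distances are on the logit of the propensity; ``caliper`` is in SDs of
    the logit over all rows.  Treated rows (label 1) are processed in
    descending score order, each taking the closest still-available control
    within the caliper; distance ties go to the lowest control index.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if np.any((scores <= 0) | (scores >= 1)):
        raise MatchingError("scores must lie strictly in (0, 1)")
    treated = np.flatnonzero(labels == 1)
    control = np.flatnonzero(labels == 0)
    if treated.size == 0 or control.size == 0:
        raise MatchingError("both classes required for matching")
    logits = _logit(scores)
    sd = float(np.std(logits, ddof=1)) if logits.size > 1 else 0.0
    max_dist = caliper * sd
    # descending score; ties broken by row index for determinism
    order = treated[np.lexsort((treated, -scores[treated]))]
    available = list(control[np.argsort(logits[control], kind="stable")])
    avail_logits = [logits[c] for c in available]
    pairs: list[tuple[int, int]] = []
    for t in order:
        if not available:
            break
        j = int(np.searchsorted(avail_logits, logits[t]))
        best_j, best_d = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(available):
                d = abs(avail_logits[k] - logits[t])
                # strict < keeps the left (lower-logit) candidate on ties;
                # among equal logits the available list is index-sorted
                if d < best_d:
                    best_d, best_j = d, k
        if best_j is not None and best_d <= max_dist:
            pairs.append((int(available[best_j]), int(t)))
            del available[best_j]
            del avail_logits[best_j]
    matched = {i for pair in pairs for i in pair}
    unmatched = tuple(int(i) for i in range(labels.size) if i not in matched)
    return MatchResult(tuple(pairs), scores, unmatched)


def standardized_mean_differences(demographics: pd.DataFrame, labels) -> dict[str, float]:
    """SMD per covariate: (mean1 - mean0) / sqrt((var1 + var0) / 2)."""
    labels = np.asarray(labels, dtype=int)
    out: dict[str, float] = {}
    for col in DEMOGRAPHIC_COLUMNS:
        x = demographics[col].to_numpy(dtype=float)
        x0, x1 = x[labels == 0], x[labels == 1]
        pooled = np.sqrt((x0.var(ddof=1) + x1.var(ddof=1)) / 2.0)
        if pooled == 0:
            out[col] = 0.0 if x1.mean() == x0.mean() else float("inf")
        else:
            out[col] = float((x1.mean() - x0.mean()) / pooled)
    return out


def match_study(cohort: Cohort, caliper: float = 0.2
                ) -> tuple[Cohort, MatchResult, dict[str, dict[str, float]]]:
    """Full matching stage: propensity, matching, pre/post balance report."""
    scores = estimate_propensity(cohort.demographics, cohort.labels)
    result = match_cohort(scores, cohort.labels, caliper=caliper)
    pre = standardized_mean_differences(cohort.demographics, cohort.labels)
    matched = cohort.subset(result.matched_indices())
    post = standardized_mean_differences(matched.demographics, matched.labels)
    return matched, result, {"pre": pre, "post": post}
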