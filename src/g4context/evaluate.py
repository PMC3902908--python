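"""Threshold classification, ROC/AUC machinery, group comparison, and the
in-line probing folding call.

The ROC construction follows the calibration procedure used to set the
published cG/cC thresholds: candidate thresholds are the values midway
between consecutive distinct scores (plus one below the minimum and one above
the maximum so the curve reaches both corners); sensitivity is the fraction
of folding candidates *strictly above* a threshold and specificity the
fraction of non-folding candidates *strictly below* it.  With midpoint
thresholds the strict inequalities never meet a data value, and the
trapezoidal AUC equals the normalized pairwise-concordance (rank-sum)
statistic on tie-free data.

Metrics that predict folding when *low* (total loop length, by stability
arguments) are handled by an explicit ``lower_is_folding`` flag that negates
scores before applying the definitions; Mfe is used as higher-is-folding
(a less negative minimum free energy means weaker Watson-Crick competition).
The direction is always an explicit setting, never inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import G4DataError

#: Calibrated cG/cC decision thresholds.
THRESHOLD_SENSITIVE = 2.05
THRESHOLD_SPECIFIC = 3.05

FOLDING = "folding"
NON_FOLDING = "non-folding"


@dataclass(frozen=True)
class EvalCandidate:
    """One candidate with a single predictive score and its true fold label."""

    id: str
    score: float
    label: bool  # True = folding (the experimental ground truth)


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


def midpoint_thresholds(scores: Sequence[float]) -> list[float]:
    """Thresholds midway between consecutive distinct scores, plus one flank
    below the minimum and one above the maximum."""
    finite = [s for s in scores if math.isfinite(s)]
    if len(finite) < 2:
        raise G4DataError("need at least two finite scores for thresholds")
    distinct = sorted(set(finite))
    mids = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    return [distinct[0] - 1.0, *mids, distinct[-1] + 1.0]


def _adjusted(candidates: Sequence[EvalCandidate], lower_is_folding: bool) -> list[EvalCandidate]:
    if not lower_is_folding:
        return list(candidates)
    return [EvalCandidate(c.id, -c.score, c.label) for c in candidates]


def sens_spec(
    candidates: Sequence[EvalCandidate],
    threshold: float,
    lower_is_folding: bool = False,
) -> tuple[float, float]:
    """Sensitivity and specificity at a threshold, with strict inequalities.

    Sensitivity is the fraction of folding candidates scoring strictly above
    the threshold; specificity the fraction of non-folding candidates scoring
    strictly below it.  A score exactly at the threshold counts in neither
    numerator.
    """
    cands = _adjusted(candidates, lower_is_folding)
    t = -threshold if lower_is_folding else threshold
    fold = [c.score for c in cands if c.label]
    nonfold = [c.score for c in cands if not c.label]
    if not fold or not nonfold:
        raise G4DataError("sens_spec needs at least one candidate in each class")
    sensitivity = sum(s > t for s in fold) / len(fold)
    specificity = sum(s < t for s in nonfold) / len(nonfold)
    return sensitivity, specificity


def roc_curve(
    candidates: Sequence[EvalCandidate], lower_is_folding: bool = False
) -> list[RocPoint]:
    """One :class:`RocPoint` per midpoint threshold, ordered by threshold.

    Thresholds are reported on the adjusted (higher-is-folding) scale.
    Non-finite scores are excluded (they are sentinel cases, counted
    separately by the caller).
    """
    cands = [c for c in _adjusted(candidates, lower_is_folding) if math.isfinite(c.score)]
    points = []
    for t in midpoint_thresholds([c.score for c in cands]):
        sens, spec = sens_spec(cands, t)
        points.append(RocPoint(t, sens, spec))
    return points


def auc(roc: Sequence[RocPoint]) -> float:
    """Trapezoidal area under sensitivity vs (1 - specificity)."""
    pts = sorted(roc, key=lambda p: p.threshold)
    x = np.array([1.0 - p.specificity for p in pts])
    y = np.array([p.sensitivity for p in pts])
    # x runs from 1 (low threshold) down to 0 (high threshold)
    return float(np.trapezoid(y[::-1], x[::-1]))


def classify(ratio: float, threshold: float = THRESHOLD_SENSITIVE) -> str:
    """Fold call for a cG/cC ratio: folding iff ratio > threshold (strict).

    The infinity sentinel (cC = 0) classifies as folding; the undefined 0/0
    sentinel raises, since no call can be made without any G or C content.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if math.isnan(ratio):
        raise G4DataError(
            "cG/cC ratio is undefined (sequence has neither G nor C); "
            "no folding call can be made for this candidate"
        )
    if math.isinf(ratio):
        return FOLDING
    return FOLDING if ratio > threshold else NON_FOLDING


def confusion_counts(
    candidates: Sequence[EvalCandidate],
    threshold: float,
    lower_is_folding: bool = False,
) -> dict[str, int]:
    """TP/FP/TN/FN at a threshold (predicted folding iff score > threshold,
    on the adjusted scale; infinite scores predict folding)."""
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    t = -threshold if lower_is_folding else threshold
    for c in _adjusted(candidates, lower_is_folding):
        if math.isnan(c.score):
            raise G4DataError(f"candidate {c.id!r}: undefined score")
        predicted = c.score > t
        if predicted and c.label:
            counts["TP"] += 1
        elif predicted and not c.label:
            counts["FP"] += 1
        elif not predicted and not c.label:
            counts["TN"] += 1
        else:
            counts["FN"] += 1
    return counts


def compare_groups(
    folding_scores: Sequence[float],
    nonfolding_scores: Sequence[float],
    exact_max_n: int = 20,
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U comparing score distributions between groups.

    Returns ``(U, p, method)`` where U counts (folding, non-folding) pairs
    with the folding score larger (ties count 1/2).  The exact null
    distribution is used for combined n <= ``exact_max_n`` without ties;
    otherwise the normal approximation with tie correction.
    """
    if not len(folding_scores) or not len(nonfolding_scores):
        raise G4DataError("compare_groups needs at least one value per group")
    pooled = list(folding_scores) + list(nonfolding_scores)
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        folding_scores, nonfolding_scores, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue), method


@dataclass(frozen=True)
class ProbingProfile:
    """Per-nucleotide K+/Li+ in-line cleavage intensity ratios for one
    replicate experiment."""

    ratios: Mapping[int, float]  # position -> K+/Li+ intensity ratio
    replicate: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.ratios.values()):
            raise G4DataError("K+/Li+ ratios must be non-negative")


def probing_call(
    profiles: Sequence[ProbingProfile],
    loop_mask: Iterable[int],
    ratio_threshold: float = 2.0,
    min_positions: int = 2,
    min_replicates: int = 2,
) -> Literal["folding", "non-folding"]:
    """In-line probing fold call.

    A candidate is positive for G4 folding when, reproducibly in at least
    ``min_replicates`` replicates, at least ``min_positions`` nucleotides
    predicted in loops or immediately adjacent to the first/last G-track show
    a K+/Li+ cleavage ratio >= ``ratio_threshold``.
    """
    if len(profiles) < min_replicates:
        raise G4DataError(
            f"need >= {min_replicates} replicate profiles, got {len(profiles)}"
        )
    positions = set(profiles[0].ratios)
    for p in profiles[1:]:
        if set(p.ratios) != positions:
            raise G4DataError("probing profiles cover mismatched position sets")
    mask = set(loop_mask)
    if not mask <= positions:
        raise G4DataError("loop_mask contains positions absent from the profiles")
    qualifying = sum(
        1
        for p in profiles
        if sum(p.ratios[pos] >= ratio_threshold for pos in mask) >= min_positions
    )
    return FOLDING if qualifying >= min_replicates else NON_FOLDING
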