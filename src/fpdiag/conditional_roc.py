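"""Conditional ROC curves and the FPR-normalised conditional AUC.

Detection of a fixed point needs two sequential criteria: the condition
criterion (CC, all three pairwise BFs must exceed it) and the fixed-point
criterion (FPC, the ANOVA BF must exceed it).  Sweeping the FPC at a fixed
CC traces a *conditional* ROC: replicates rejected by the screen count as
non-detections at every FPC, so the curve tops out at ``fpr_max`` — the
screened fraction of negatives — which can fall below 1.  The conditional
AUC (cAUC) is the trapezoid area over the defined region [0, fpr_max]
divided by ``fpr_max``.

Chance performance under this normalisation is 25% when CC > 0 (two
independent sources of classification; the 25% figure corresponds to a
screen pass-rate of one half under exchangeable polarities) and 50% when
CC = 0, where the situation reduces to an ordinary unconditional ROC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .scenario_resampler import ClassificationOutcome

__all__ = [
    "ConditionalROC",
    "CAUCEstimate",
    "classify",
    "conditional_roc",
    "conditional_auc",
    "cauc_ci",
    "chance_level",
]


@dataclass(frozen=True)
class ConditionalROC:
    """One conditional ROC curve: FPC sweep at a fixed condition criterion."""

    condition_criterion: float
    thresholds: np.ndarray  # decreasing FPC values, +inf first, 0 last
    tpr: np.ndarray
    fpr: np.ndarray

    @property
    def fpr_max(self) -> float:
        """FPR at the most lenient fixed-point criterion (0)."""
        return float(self.fpr[-1])

    @property
    def tpr_max(self) -> float:
        return float(self.tpr[-1])


@dataclass(frozen=True)
class CAUCEstimate:
    """Bootstrap summary of the conditional AUC."""

    cauc: float
    ci_low: float
    ci_high: float
    n_resamples: int
    chance: float


def classify(outcome: ClassificationOutcome, condition_criterion: float, fixed_point_criterion: float) -> bool:
    """Dual-criterion decision for one replicate.

    Detected iff all three pairwise BFs strictly exceed the condition
    criterion *and* the fixed-point BF strictly exceeds the fixed-point
    criterion.  Failed replicates are never detections.
    """
    if condition_criterion < 0 or fixed_point_criterion < 0:
        raise ValidationError("criteria must be nonnegative")
    if not outcome.screen_passes(condition_criterion):
        return False
    if outcome.fixed_point_log_bf is None:
        return False
    if fixed_point_criterion == 0.0:
        return True  # BFs are strictly positive
    return outcome.fixed_point_log_bf > math.log(fixed_point_criterion)


def _split_screened(
    outcomes: Sequence[ClassificationOutcome], condition_criterion: float
) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Per polarity: total replicate count and fixed-point log-BFs of screened ones."""
    totals = {"positive": 0, "negative": 0}
    screened: dict[str, list[float]] = {"positive": [], "negative": []}
    for o in outcomes:
        totals[o.polarity] += 1
        if o.screen_passes(condition_criterion) and o.fixed_point_log_bf is not None:
            screened[o.polarity].append(o.fixed_point_log_bf)
    return totals, {k: np.array(v) for k, v in screened.items()}


def conditional_roc(outcomes: Sequence[ClassificationOutcome], condition_criterion: float) -> ConditionalROC:
    """Build the conditional ROC curve from bootstrap outcomes.

    Thresholds sweep from +inf (nothing detected) through every distinct
    fixed-point BF among screened replicates down to 0 (every screened
    replicate detected).  TPR and FPR denominators are *all* positives and
    negatives, so screen failures depress the curve exactly as the
    sequential decision rule dictates.
    """
    totals, screened = _split_screened(outcomes, condition_criterion)
    if totals["positive"] == 0 or totals["negative"] == 0:
        raise ValidationError("outcomes must contain both polarities")
    all_log_bfs = np.concatenate([screened["positive"], screened["negative"]])
    # strict '>' with threshold 0 admits every screened BF, since BFs are positive
    log_thresholds = np.concatenate([[np.inf], np.sort(np.unique(all_log_bfs))[::-1], [-np.inf]])
    tpr = np.array(
        [(screened["positive"] > thr).sum() / totals["positive"] for thr in log_thresholds]
    )
    fpr = np.array(
        [(screened["negative"] > thr).sum() / totals["negative"] for thr in log_thresholds]
    )
    thresholds = np.exp(log_thresholds)
    thresholds[-1] = 0.0
    return ConditionalROC(
        condition_criterion=condition_criterion, thresholds=thresholds, tpr=tpr, fpr=fpr
    )


def conditional_auc(roc: ConditionalROC) -> float:
    """FPR-normalised conditional AUC.

    Trapezoid area of TPR against FPR over the defined region [0, fpr_max],
    divided by fpr_max; by convention 0 when the screen admits no negatives
    (fpr_max = 0), where the curve has no defined region at all.
    """
    if roc.fpr_max == 0.0:
        return 0.0
    area = float(np.trapezoid(roc.tpr, roc.fpr))
    return area / roc.fpr_max


def cauc_ci(
    outcomes: Sequence[ClassificationOutcome],
    condition_criterion: float,
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CAUCEstimate:
    """Percentile-bootstrap mean and 95% CI of the conditional AUC.

    The outcome set is resampled with replacement *within* polarity (keeping
    both group sizes fixed), the cAUC recomputed each time, and the mean and
    2.5/97.5 percentiles reported.
    """
    if n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pos = [o for o in outcomes if o.polarity == "positive"]
    neg = [o for o in outcomes if o.polarity == "negative"]
    if not pos or not neg:
        raise ValidationError("outcomes must contain both polarities")
    values = np.empty(n_resamples)
    for b in range(n_resamples):
        sample = [pos[i] for i in rng.integers(0, len(pos), len(pos))] + [
            neg[i] for i in rng.integers(0, len(neg), len(neg))
        ]
        values[b] = conditional_auc(conditional_roc(sample, condition_criterion))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return CAUCEstimate(
        cauc=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        chance=chance_level(condition_criterion),
    )


def chance_level(condition_criterion: float) -> float:
    """Chance cAUC in percent: 50 without screening (CC = 0), else 25."""
    if condition_criterion < 0:
        raise ValidationError("condition criterion must be nonnegative")
    return 50.0 if condition_criterion == 0.0 else 25.0
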