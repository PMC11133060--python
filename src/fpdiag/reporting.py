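"""Serialisation of bootstrap outcomes and ROC/cAUC tables, plus run summaries.

Outcomes are exchanged as CSV with log Bayes factors (log values survive the
astronomical BFs that well-separated conditions produce) so that scenario
execution and ROC analysis are fully decoupled.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .conditional_roc import CAUCEstimate, ConditionalROC, cauc_ci, chance_level, conditional_auc, conditional_roc
from .errors import SchemaError
from .scenario_resampler import ClassificationOutcome

__all__ = [
    "outcomes_to_frame",
    "frame_to_outcomes",
    "write_outcomes",
    "read_outcomes",
    "roc_to_frame",
    "summarize_outcomes",
]

_OUTCOME_COLUMNS = [
    "replicate",
    "polarity",
    "log_bf10_AB",
    "log_bf10_BC",
    "log_bf10_AC",
    "log_fixed_point_bf",
    "error",
]


def outcomes_to_frame(outcomes: Sequence[ClassificationOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        lb = o.pairwise_log_bf10 or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "replicate": o.replicate,
                "polarity": o.polarity,
                "log_bf10_AB": lb[0],
                "log_bf10_BC": lb[1],
                "log_bf10_AC": lb[2],
                "log_fixed_point_bf": np.nan if o.fixed_point_log_bf is None else o.fixed_point_log_bf,
                "error": o.error or "",
            }
        )
    return pd.DataFrame(rows, columns=_OUTCOME_COLUMNS)


def frame_to_outcomes(df: pd.DataFrame) -> list[ClassificationOutcome]:
    for col in _OUTCOME_COLUMNS[:-1]:
        if col not in df.columns:
            raise SchemaError(f"outcomes table missing column {col!r}")
    out: list[ClassificationOutcome] = []
    for rec in df.to_dict("records"):
        err_raw = rec.get("error", "")
        if err_raw is None or (isinstance(err_raw, float) and np.isnan(err_raw)):
            err_raw = ""
        err = str(err_raw)
        failed = err != "" or not np.isfinite(rec["log_bf10_AB"])
        out.append(
            ClassificationOutcome(
                replicate=int(rec["replicate"]),
                polarity=str(rec["polarity"]),  # type: ignore[arg-type]
                pairwise_log_bf10=None
                if failed
                else (float(rec["log_bf10_AB"]), float(rec["log_bf10_BC"]), float(rec["log_bf10_AC"])),
                fixed_point_log_bf=None
                if failed or not np.isfinite(rec["log_fixed_point_bf"])
                else float(rec["log_fixed_point_bf"]),
                error=err or None,
            )
        )
    return out


def write_outcomes(outcomes: Sequence[ClassificationOutcome], path) -> None:
    outcomes_to_frame(outcomes).to_csv(path, index=False)


def read_outcomes(path) -> list[ClassificationOutcome]:
    return frame_to_outcomes(pd.read_csv(path, keep_default_na=True))


def roc_to_frame(roc: ConditionalROC) -> pd.DataFrame:
    """One row per threshold of the FPC sweep."""
    return pd.DataFrame(
        {
            "condition_criterion": roc.condition_criterion,
            "fixed_point_criterion": roc.thresholds,
            "tpr": roc.tpr,
            "fpr": roc.fpr,
        }
    )


def summarize_outcomes(
    outcomes: Sequence[ClassificationOutcome],
    condition_criteria: Sequence[float],
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Machine-readable summary: per criterion, screen pass-rates and cAUC ± CI."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_pos = sum(1 for o in outcomes if o.polarity == "positive")
    n_neg = len(outcomes) - n_pos
    n_failed = sum(1 for o in outcomes if o.error is not None)
    cells = []
    for cc in condition_criteria:
        pass_pos = sum(1 for o in outcomes if o.polarity == "positive" and o.screen_passes(cc))
        pass_neg = sum(1 for o in outcomes if o.polarity == "negative" and o.screen_passes(cc))
        est: CAUCEstimate = cauc_ci(outcomes, cc, n_resamples=n_resamples, rng=rng)
        point = conditional_auc(conditional_roc(outcomes, cc))
        cells.append(
            {
                "condition_criterion": cc,
                "n_replicates": {"positive": n_pos, "negative": n_neg},
                "screen_pass_rate": {
                    "positive": pass_pos / n_pos if n_pos else float("nan"),
                    "negative": pass_neg / n_neg if n_neg else float("nan"),
                },
                "cauc_percent": 100.0 * point,
                "cauc_mean_percent": 100.0 * est.cauc,
                "cauc_ci_percent": [100.0 * est.ci_low, 100.0 * est.ci_high],
                "chance_percent": est.chance,
            }
        )
    return {"n_outcomes": len(outcomes), "n_failed": n_failed, "cells": cells}


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
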