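"""Positive/negative control resampling and the scenario bootstrap.

Every scenario starts from a two-condition base experiment (conditions CA
and PR) and resamples each participant's trials into three synthetic
conditions A, B, C:

* **positive control** — the mixture proportion changes across conditions:
  A holds ``P%`` CA trials (the rest PR), B a 50/50 split, and C the
  reciprocal of A.  A fixed point must be present by construction.
* **negative control** — all three conditions hold 50/50 CA/PR splits, but
  each condition draws from a different temporal third of the session
  (A from the beginning, B from the middle, C from the end), so the
  conditions still differ through the time-on-task drift while no mixture
  change occurs.

Three scenarios vary what else changes: ``reference`` draws positives from
the full session; ``time_on_task`` additionally confines each positive
condition to one temporal third under one of the six possible
condition-to-third assignments; ``sample_size`` subsamples participants
and/or trials.  The bootstrap runs the full test pipeline on one positive
and one negative dataset per replicate and records all Bayes factors, with
the decision criteria applied later by the ROC module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ResamplingError, ValidationError
from .fixed_point_test import run_fixed_point_test
from .rt_data import TemporalPart, Trial, TrialTable, split_into_parts

__all__ = [
    "ScenarioSpec",
    "ResampledDataset",
    "ClassificationOutcome",
    "build_positive",
    "build_negative",
    "enumerate_permutations",
    "subsample",
    "bootstrap_polarity",
    "run_bootstrap",
]

_CONDS = ("A", "B", "C")

#: identity assignment of synthetic conditions to temporal thirds, used by
#: every negative control and by Scenario-1 bookkeeping
IDENTITY_PERMUTATION: dict[str, TemporalPart] = {
    "A": TemporalPart.BEGINNING,
    "B": TemporalPart.MIDDLE,
    "C": TemporalPart.END,
}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one scenario run.

    ``mixture_proportion`` is the percentage P of CA trials in positive
    condition A (50–100); ``permutation`` assigns conditions to temporal
    thirds for time-on-task positives (identity when omitted); ``n_boot``
    defaults to 1000 (10,000 for the sample-size scenario, which probes
    unstable small-sample cells).
    """

    scenario: Literal["reference", "time_on_task", "sample_size"] = "reference"
    mixture_proportion: float = 100.0
    n_trials: int = 40
    n_participants: int | None = None
    permutation: Mapping[str, TemporalPart] | None = None
    n_boot: int | None = None
    condition_criteria: tuple[float, ...] = (0.0, 1.0, 64.0)
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in ("reference", "time_on_task", "sample_size"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if not 50.0 <= self.mixture_proportion <= 100.0:
            raise ValidationError("mixture_proportion must be in [50, 100] percent")
        if self.n_trials < 2:
            raise ValidationError("n_trials must be >= 2")
        if self.n_participants is not None and self.n_participants < 3:
            raise ValidationError("n_participants must be >= 3")
        if self.n_boot is not None and self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.permutation is not None:
            if set(self.permutation.keys()) != set(_CONDS) or set(self.permutation.values()) != set(TemporalPart):
                raise ValidationError("permutation must be a bijection {A,B,C} -> thirds")
        if any(c < 0 for c in self.condition_criteria):
            raise ValidationError("condition criteria must be nonnegative")

    @property
    def effective_n_boot(self) -> int:
        if self.n_boot is not None:
            return self.n_boot
        return 10_000 if self.scenario == "sample_size" else 1000

    @property
    def effective_permutation(self) -> dict[str, TemporalPart]:
        return dict(self.permutation) if self.permutation is not None else dict(IDENTITY_PERMUTATION)


@dataclass
class ResampledDataset:
    """Per-participant RT sets for the three synthetic conditions.

    ``data[pid][cond]`` is the RT array; ``sources[pid][cond]`` the parallel
    array of base-condition labels ("CA"/"PR") for the composition audit.
    """

    polarity: Literal["positive", "negative"]
    data: dict[str, dict[str, np.ndarray]]
    sources: dict[str, dict[str, np.ndarray]]
    spec: ScenarioSpec
    replicate: int = 0

    @property
    def participants(self) -> list[str]:
        return list(self.data.keys())

    def rts(self, participant: str, condition: str) -> np.ndarray:
        return self.data[participant][condition]

    def composition(self, participant: str, condition: str) -> dict[str, int]:
        """Counts of CA/PR source trials in one resampled condition."""
        src = self.sources[participant][condition]
        return {"CA": int(np.sum(src == "CA")), "PR": int(np.sum(src == "PR"))}


@dataclass(frozen=True)
class ClassificationOutcome:
    """All Bayes factors of one bootstrap replicate — the atom of ROC analysis.

    Decision criteria are deliberately not applied here; the ROC module
    sweeps them afterwards.  ``error`` is set (and the BFs are None) when the
    replicate failed, e.g. because a resampling pool was empty.
    """

    replicate: int
    polarity: Literal["positive", "negative"]
    pairwise_log_bf10: tuple[float, float, float] | None
    fixed_point_log_bf: float | None
    error: str | None = None

    @property
    def pairwise_bf10(self) -> tuple[float, float, float] | None:
        if self.pairwise_log_bf10 is None:
            return None
        return tuple(float(np.exp(v)) for v in self.pairwise_log_bf10)

    @property
    def fixed_point_bf(self) -> float | None:
        return None if self.fixed_point_log_bf is None else float(np.exp(self.fixed_point_log_bf))

    def screen_passes(self, condition_criterion: float) -> bool:
        """All three pairwise BFs strictly exceed the condition criterion."""
        if self.pairwise_log_bf10 is None:
            return False
        if condition_criterion == 0.0:
            return True
        thr = math.log(condition_criterion)
        return all(lb > thr for lb in self.pairwise_log_bf10)


def enumerate_permutations() -> list[dict[str, TemporalPart]]:
    """All six bijections of conditions {A,B,C} onto the temporal thirds.

    Order is fixed: thirds permuted lexicographically in (beginning, middle,
    end) order, so the identity assignment comes first.
    """
    parts = (TemporalPart.BEGINNING, TemporalPart.MIDDLE, TemporalPart.END)
    return [dict(zip(_CONDS, perm)) for perm in itertools.permutations(parts)]


def subsample(base: TrialTable, n_participants: int, rng: np.random.Generator) -> TrialTable:
    """Uniform draw of participants without replacement, keeping all their trials."""
    pids = base.participants
    if n_participants > len(pids):
        raise ValidationError(f"requested {n_participants} participants but only {len(pids)} available")
    chosen = set(rng.choice(len(pids), size=n_participants, replace=False))
    keep = {pids[i] for i in chosen}
    return TrialTable(
        trials=[t for t in base.trials if t.participant_id in keep],
        deadline_ms=base.deadline_ms,
    )


def _pool(trials: Sequence[Trial], cond: str) -> np.ndarray:
    return np.array([t.rt_ms for t in trials if t.condition == cond], dtype=float)


def _draw(pool: np.ndarray, k: int, rng: np.random.Generator, replace: bool, what: str) -> np.ndarray:
    if k == 0:
        return np.empty(0, dtype=float)
    if pool.size == 0 or (not replace and pool.size < k):
        raise ResamplingError(f"cannot draw {k} trials from a pool of {pool.size} ({what})")
    return rng.choice(pool, size=k, replace=replace)


def _positive_counts(p_percent: float, n_trials: int) -> dict[str, tuple[int, int]]:
    """(CA, PR) counts per condition; C is forced to the exact reciprocal of A."""
    n_a_ca = _round_half_away(p_percent / 100.0 * n_trials)
    n_b_ca = _round_half_away(0.5 * n_trials)
    return {
        "A": (n_a_ca, n_trials - n_a_ca),
        "B": (n_b_ca, n_trials - n_b_ca),
        "C": (n_trials - n_a_ca, n_a_ca),
    }


def build_positive(base: TrialTable, spec: ScenarioSpec, rng: np.random.Generator, replicate: int = 0) -> ResampledDataset:
    """Positive control: mixture proportions P / 50 / (100−P) across A, B, C.

    Reference and sample-size scenarios draw from each participant's full
    CA/PR pools; the time-on-task scenario restricts condition X to the
    temporal third assigned by ``spec.permutation``.
    """
    counts = _positive_counts(spec.mixture_proportion, spec.n_trials)
    by_part = spec.scenario == "time_on_task"
    perm = spec.effective_permutation
    data: dict[str, dict[str, np.ndarray]] = {}
    sources: dict[str, dict[str, np.ndarray]] = {}
    for pid in base.participants:
        if by_part:
            parts = split_into_parts(base, pid)
        conds: dict[str, np.ndarray] = {}
        srcs: dict[str, np.ndarray] = {}
        for cond in _CONDS:
            trials = parts[perm[cond]] if by_part else base.responded_trials(pid)
            n_ca, n_pr = counts[cond]
            where = f"participant {pid}, condition {cond}" + (f", part {perm[cond].value}" if by_part else "")
            ca = _draw(_pool(trials, "CA"), n_ca, rng, spec.with_replacement, where + ", CA")
            pr = _draw(_pool(trials, "PR"), n_pr, rng, spec.with_replacement, where + ", PR")
            conds[cond] = np.concatenate([ca, pr])
            srcs[cond] = np.array(["CA"] * n_ca + ["PR"] * n_pr)
        data[pid] = conds
        sources[pid] = srcs
    return ResampledDataset(polarity="positive", data=data, sources=sources, spec=spec, replicate=replicate)


def build_negative(base: TrialTable, spec: ScenarioSpec, rng: np.random.Generator, replicate: int = 0) -> ResampledDataset:
    """Negative control: 50/50 CA/PR splits drawn from the temporal thirds.

    Condition A draws from the beginning of the session, B from the middle,
    C from the end (identity assignment in every scenario), so the conditions
    differ through time-on-task drift but the mixture proportion is constant.
    """
    n_ca = _round_half_away(0.5 * spec.n_trials)
    n_pr = spec.n_trials - n_ca
    data: dict[str, dict[str, np.ndarray]] = {}
    sources: dict[str, dict[str, np.ndarray]] = {}
    for pid in base.participants:
        parts = split_into_parts(base, pid)
        conds: dict[str, np.ndarray] = {}
        srcs: dict[str, np.ndarray] = {}
        for cond in _CONDS:
            part = IDENTITY_PERMUTATION[cond]
            trials = parts[part]
            where = f"participant {pid}, condition {cond}, part {part.value}"
            ca = _draw(_pool(trials, "CA"), n_ca, rng, spec.with_replacement, where + ", CA")
            pr = _draw(_pool(trials, "PR"), n_pr, rng, spec.with_replacement, where + ", PR")
            conds[cond] = np.concatenate([ca, pr])
            srcs[cond] = np.array(["CA"] * n_ca + ["PR"] * n_pr)
        data[pid] = conds
        sources[pid] = srcs
    return ResampledDataset(polarity="negative", data=data, sources=sources, spec=spec, replicate=replicate)


def _one_outcome(base: TrialTable, spec: ScenarioSpec, polarity: str, replicate: int, seed: np.random.SeedSequence) -> ClassificationOutcome:
    rng = np.random.default_rng(seed)
    try:
        table = base
        if spec.n_participants is not None and spec.n_participants < len(base.participants):
            table = subsample(base, spec.n_participants, rng)
        build = build_positive if polarity == "positive" else build_negative
        ds = build(table, spec, rng, replicate=replicate)
        res = run_fixed_point_test(ds, force_steps=True)
        return ClassificationOutcome(
            replicate=replicate,
            polarity=polarity,  # type: ignore[arg-type]
            pairwise_log_bf10=tuple(b.log_bf10 for b in res.pairwise),
            fixed_point_log_bf=res.fixed_point_bf.log_bf_present,
        )
    except Exception as exc:  # record, never silently drop
        return ClassificationOutcome(
            replicate=replicate,
            polarity=polarity,  # type: ignore[arg-type]
            pairwise_log_bf10=None,
            fixed_point_log_bf=None,
            error=f"{type(exc).__name__}: {exc}",
        )


def bootstrap_polarity(
    base: TrialTable,
    spec: ScenarioSpec,
    polarity: Literal["positive", "negative"],
    n_boot: int | None = None,
) -> list[ClassificationOutcome]:
    """Bootstrap one polarity only.

    Uses the same per-(replicate, polarity) seed derivation as
    :func:`run_bootstrap`, so positives and negatives computed separately are
    identical to a paired run — useful when one negative set is shared across
    a sweep of mixture proportions or permutations, which touch only the
    positive controls.
    """
    n = n_boot if n_boot is not None else spec.effective_n_boot
    children = np.random.SeedSequence(spec.seed).spawn(2 * n)
    offset = 0 if polarity == "positive" else 1
    return [_one_outcome(base, spec, polarity, i + 1, children[2 * i + offset]) for i in range(n)]


def run_bootstrap(base: TrialTable, spec: ScenarioSpec, n_boot: int | None = None) -> list[ClassificationOutcome]:
    """Run the bootstrap: one positive and one negative replicate per draw.

    Child seeds are spawned deterministically from ``spec.seed``, one per
    (replicate, polarity), so results are independent of execution order and
    identical across reruns.  Failed replicates are recorded with their
    error, never dropped.  Returns ``2·n_boot`` outcomes, interleaved.
    """
    n = n_boot if n_boot is not None else spec.effective_n_boot
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * n)
    outcomes: list[ClassificationOutcome] = []
    for i in range(n):
        outcomes.append(_one_outcome(base, spec, "positive", i + 1, children[2 * i]))
        outcomes.append(_one_outcome(base, spec, "negative", i + 1, children[2 * i + 1]))
    return outcomes
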