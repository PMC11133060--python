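"""The four-step fixed-point test with its sequential decision rule.

Step 1 screens for a behavioural effect of the manipulation: all three
pairwise condition differences (paired JZS t-tests on per-participant mean
RTs) must exceed the *condition criterion*; without distributional
differences the fixed-point property cannot be meaningfully tested, and the
fixed point is considered absent.  Steps 2–3 estimate each participant's
three condition densities on a shared grid and locate the crossing point of
each condition pair.  Step 4 computes the repeated-measures ANOVA Bayes
factor asking whether the three crossing points per participant share one
distribution; the fixed point is detected when that Bayes factor exceeds the
*fixed-point criterion*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable

import numpy as np

from .bayes_factors import (
    DEFAULT_FIXED_SCALE,
    DEFAULT_RANDOM_SCALE,
    DEFAULT_T_SCALE,
    FixedPointBF,
    PairwiseBF,
    jzs_paired_bf,
    rm_anova_fixed_point_bf,
)
from .density_crossing import (
    DEFAULT_GRID_POINTS,
    CrossingPoint,
    estimate_density,
    find_crossings,
    select_crossing,
    shared_grid,
)
from .errors import NoCrossingError, ValidationError

if TYPE_CHECKING:
    from .scenario_resampler import ResampledDataset

__all__ = ["FixedPointResult", "condition_screen", "compute_crossings", "run_fixed_point_test"]

_PAIRS: tuple[tuple[str, str], ...] = (("A", "B"), ("B", "C"), ("A", "C"))


@dataclass(frozen=True)
class FixedPointResult:
    """Outcome of the four-step test on one three-condition dataset.

    ``crossings`` maps participant id → (A–B, B–C, A–C) crossing points and
    is present only when the condition screen passed; ``excluded`` lists
    participants dropped because some pair of their densities never crossed
    within the grid.
    """

    pairwise: tuple[PairwiseBF, PairwiseBF, PairwiseBF]
    passed_condition_screen: bool
    condition_criterion: float
    fixed_point_criterion: float
    crossings: dict[str, tuple[CrossingPoint, CrossingPoint, CrossingPoint]] | None = None
    excluded: tuple[str, ...] = ()
    fixed_point_bf: FixedPointBF | None = None
    detected: bool = False

    def to_dict(self) -> dict:
        """JSON-serialisable report of all BFs, crossings, and the decision."""
        out = {
            "condition_criterion": self.condition_criterion,
            "fixed_point_criterion": self.fixed_point_criterion,
            "pairwise_bf10": {f"{b.pair[0]}-{b.pair[1]}": b.bf10 for b in self.pairwise},
            "passed_condition_screen": self.passed_condition_screen,
            "fixed_point_bf": None if self.fixed_point_bf is None else self.fixed_point_bf.bf_present,
            "excluded_participants": list(self.excluded),
            "detected": self.detected,
        }
        if self.crossings is not None:
            out["crossings"] = {
                pid: {f"{c.pair[0]}-{c.pair[1]}": c.rt_ms for c in triple}
                for pid, triple in self.crossings.items()
            }
        return out


def condition_screen(
    dataset: "ResampledDataset",
    condition_criterion: float,
    cauchy_scale: float = DEFAULT_T_SCALE,
    summary: Callable[[np.ndarray], float] = np.mean,
) -> tuple[tuple[PairwiseBF, PairwiseBF, PairwiseBF], bool]:
    """Step 1: pairwise JZS t-test BFs on per-participant summary RTs.

    For each condition pair, each participant contributes one summary RT per
    condition (the mean by default; pass ``np.median`` for medians) and the
    paired differences across participants feed the JZS test.  The screen
    passes iff all three BF10 values strictly exceed the condition criterion.
    """
    if condition_criterion < 0:
        raise ValidationError("condition_criterion must be nonnegative")
    summaries = {
        cond: np.array([summary(dataset.rts(pid, cond)) for pid in dataset.participants])
        for cond in ("A", "B", "C")
    }
    bfs = tuple(
        jzs_paired_bf(summaries[p1] - summaries[p2], cauchy_scale=cauchy_scale, pair=(p1, p2))
        for p1, p2 in _PAIRS
    )
    passed = all(bf.exceeds(condition_criterion) for bf in bfs)
    return bfs, passed


def compute_crossings(
    dataset: "ResampledDataset",
    n_grid: int = DEFAULT_GRID_POINTS,
) -> tuple[dict[str, tuple[CrossingPoint, CrossingPoint, CrossingPoint]], tuple[str, ...]]:
    """Steps 2–3: per-participant KDEs on one shared grid and pair crossings.

    Returns the crossing table and the ids of participants excluded because
    at least one of their density pairs never crossed within the grid.
    """
    table: dict[str, tuple[CrossingPoint, CrossingPoint, CrossingPoint]] = {}
    excluded: list[str] = []
    from .density_crossing import silverman_bandwidth

    for pid in dataset.participants:
        samples = {c: dataset.rts(pid, c) for c in ("A", "B", "C")}
        hs = {c: silverman_bandwidth(x) for c, x in samples.items()}
        grid = shared_grid(list(samples.values()), n_points=n_grid, bandwidths=list(hs.values()))
        dens = {c: estimate_density(x, grid, bandwidth=hs[c]) for c, x in samples.items()}
        triple: list[CrossingPoint] = []
        try:
            for p1, p2 in _PAIRS:
                triple.append(select_crossing(find_crossings(dens[p1], dens[p2], pair=(p1, p2))))
        except NoCrossingError:
            excluded.append(pid)
            continue
        table[pid] = tuple(triple)
    return table, tuple(excluded)


def run_fixed_point_test(
    dataset: "ResampledDataset",
    condition_criterion: float = 1.0,
    fixed_point_criterion: float = 3.0,
    cauchy_scale: float = DEFAULT_T_SCALE,
    fixed_scale: float = DEFAULT_FIXED_SCALE,
    random_scale: float = DEFAULT_RANDOM_SCALE,
    n_grid: int = DEFAULT_GRID_POINTS,
    force_steps: bool = False,
) -> FixedPointResult:
    """Run the full four-step test with the sequential decision rule.

    If the condition screen fails the fixed point is considered absent and
    steps 2–4 are skipped (``force_steps=True`` computes them anyway, which
    the scenario bootstrap uses so that decision criteria can be varied after
    the fact).  Detection requires both criteria to be strictly exceeded.
    """
    pairwise, passed = condition_screen(dataset, condition_criterion, cauchy_scale=cauchy_scale)
    if not passed and not force_steps:
        return FixedPointResult(
            pairwise=pairwise,
            passed_condition_screen=False,
            condition_criterion=condition_criterion,
            fixed_point_criterion=fixed_point_criterion,
        )
    table, excluded = compute_crossings(dataset, n_grid=n_grid)
    if len(table) < 3:
        raise ValidationError(
            f"only {len(table)} participants have complete crossing triples; need >= 3"
        )
    matrix = np.array([[c.rt_ms for c in table[pid]] for pid in table])
    fp_bf = rm_anova_fixed_point_bf(matrix, fixed_scale=fixed_scale, random_scale=random_scale)
    detected = passed and fp_bf.exceeds(fixed_point_criterion)
    return FixedPointResult(
        pairwise=pairwise,
        passed_condition_screen=passed,
        condition_criterion=condition_criterion,
        fixed_point_criterion=fixed_point_criterion,
        crossings=table,
        excluded=excluded,
        fixed_point_bf=fp_bf,
        detected=detected,
    )
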