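"""Synthetic two-condition RT experiments and analytic mixture samples.

The generator emulates a blocked lottery-choice experiment with two
instructed strategies: a "calculate" condition (CA, slow — participants
compute expected values) and a "preference" condition (PR, fast) alternating
over 30 blocks of 8 trials under a 6.5 s response deadline.  The statistical
structure matches what the scenario analysis assumes about such data:

* a between-condition offset (PR faster than CA by 730 ms on average),
* a time-on-task speed-up entering as a step function over session thirds
  (−217 ms per third),
* a condition × time-on-task interaction (PR speeds up by a further
  −153 ms per third),
* a Gaussian participant random intercept, and
* right-skewed trial noise (shifted lognormal by default).

The module also provides pure analytic mixtures of two closed-form base
densities, which is what the fixed-point property is a statement about:
every mixture ``p·f_A + (1−p)·f_B`` passes through the point(s) where the
two base densities intersect, for every ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ValidationError
from .rt_data import Trial, TrialTable

__all__ = [
    "TrialNoiseSpec",
    "GeneratorParams",
    "BaseDistributionSpec",
    "generate_experiment",
    "sample_mixture",
    "analytic_mixture_density",
]


@dataclass(frozen=True)
class TrialNoiseSpec:
    """Right-skewed trial-level noise around a cell mean.

    A trial's RT is ``shift + X`` where ``shift = shift_frac * cell_mean`` and
    ``X ~ LogNormal(mu, sigma)`` with ``mu`` chosen so the RT mean equals the
    cell mean.  ``sigma`` controls the skew; ``shift_frac`` the irreducible
    non-decision floor as a fraction of the cell mean.
    """

    family: str = "shifted_lognormal"
    sigma: float = 0.5
    shift_frac: float = 0.35

    def __post_init__(self) -> None:
        if self.family != "shifted_lognormal":
            raise ValidationError(f"unknown trial-noise family {self.family!r}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0 <= self.shift_frac < 1:
            raise ValidationError("shift_frac must be in [0, 1)")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic RT experiment.

    The per-trial expected RT is::

        base_mean_ms + condition_effect_ms * 1[PR]
                     + tot_slope_ms * (part - 1)
                     + interaction_ms * (part - 1) * 1[PR]
                     + participant offset

    with ``part`` in {1, 2, 3} the session third of the trial's block.  The
    default slopes are the fixed-effect estimates a linear mixed model
    recovers from data of the emulated task (condition −730 ms, time-on-task
    −217 ms per third, interaction −153 ms per third).
    """

    n_participants: int = 44
    n_blocks: int = 30
    trials_per_block: int = 8
    base_mean_ms: float = 3200.0
    condition_effect_ms: float = -730.0
    tot_slope_ms: float = -217.0
    interaction_ms: float = -153.0
    participant_sd_ms: float = 500.0
    trial_noise: TrialNoiseSpec = field(default_factory=TrialNoiseSpec)
    deadline_ms: float = 6500.0
    omission_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_blocks, self.trials_per_block) < 1:
            raise ValidationError("all counts must be >= 1")
        if not 0 <= self.omission_rate <= 1:
            raise ValidationError("omission_rate must be in [0, 1]")
        if self.participant_sd_ms < 0 or self.deadline_ms <= 0 or self.base_mean_ms <= 0:
            raise ValidationError("scales must be positive")
        for cond in (0.0, 1.0):
            for part in (1, 2, 3):
                if self._cell_mean(cond, part) <= 0:
                    raise ValidationError(
                        f"cell mean non-positive for condition={'PR' if cond else 'CA'}, part={part}"
                    )

    def _cell_mean(self, is_pr: float, part: int) -> float:
        return (
            self.base_mean_ms
            + self.condition_effect_ms * is_pr
            + self.tot_slope_ms * (part - 1)
            + self.interaction_ms * (part - 1) * is_pr
        )


def _draw_rts(cell_means: np.ndarray, noise: TrialNoiseSpec, deadline: float, rng: np.random.Generator) -> np.ndarray:
    """Shifted-lognormal draws with the given means, truncated to (0, deadline] by rejection."""
    shift = noise.shift_frac * cell_means
    mean_x = cell_means - shift
    mu = np.log(mean_x) - noise.sigma**2 / 2.0
    out = shift + rng.lognormal(mean=mu, sigma=noise.sigma)
    # redraw deadline violations so the retained distribution keeps its shape below the cut
    for _ in range(1000):
        bad = out > deadline
        if not bad.any():
            break
        out[bad] = shift[bad] + rng.lognormal(mean=mu[bad], sigma=noise.sigma)
    else:
        raise ValidationError("cell means too close to the deadline: truncation does not converge")
    return out


def generate_experiment(params: GeneratorParams) -> TrialTable:
    """Generate a full synthetic experiment as a :class:`TrialTable`.

    Conditions alternate block-wise; the starting condition alternates across
    participants (counterbalancing).  Omissions are drawn independently at
    ``params.omission_rate`` and carry no RT.  Same seed, same table.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    base, rem = divmod(p.n_blocks, 3)
    part_sizes = [base + (1 if k < rem else 0) for k in range(3)] if p.n_blocks >= 3 else None
    trials: list[Trial] = []
    offsets = rng.normal(0.0, p.participant_sd_ms, size=p.n_participants)
    for i in range(p.n_participants):
        pid = f"p{i + 1:03d}"
        start_pr = i % 2  # counterbalance CA-first / PR-first
        blocks = np.arange(1, p.n_blocks + 1)
        is_pr = ((blocks - 1 + start_pr) % 2).astype(float)
        # session third of each block; a non-divisible block count puts the
        # remainder in the earliest part(s), mirroring the thirds rule
        if part_sizes is not None:
            part = np.repeat([1, 2, 3], part_sizes)
        else:
            part = np.ones(p.n_blocks, dtype=int)
        cell = np.array([p._cell_mean(c, pt) for c, pt in zip(is_pr, part)])
        cell_means = np.repeat(cell + offsets[i], p.trials_per_block)
        cell_means = np.clip(cell_means, 50.0, None)  # random intercept must not push a cell negative
        rts = _draw_rts(cell_means, p.trial_noise, p.deadline_ms, rng)
        omitted = rng.random(rts.size) < p.omission_rate
        conds = np.repeat(np.where(is_pr > 0, "PR", "CA"), p.trials_per_block)
        blks = np.repeat(blocks, p.trials_per_block)
        for j in range(rts.size):
            trials.append(
                Trial(
                    participant_id=pid,
                    condition=str(conds[j]),
                    block_index=int(blks[j]),
                    trial_index=j + 1,
                    rt_ms=np.nan if omitted[j] else float(rts[j]),
                    responded=not bool(omitted[j]),
                )
            )
    return TrialTable(trials=trials, deadline_ms=p.deadline_ms)


# ---------------------------------------------------------------------------
# analytic base distributions and mixtures

_FAMILIES = {"normal", "lognormal", "shifted_lognormal", "gamma"}


@dataclass(frozen=True)
class BaseDistributionSpec:
    """A closed-form base RT distribution.

    Families
    --------
    normal
        ``params = (loc, scale)``
    lognormal / shifted_lognormal
        ``params = (mu, sigma[, shift])`` — log-scale mean and sd, optional
        location shift in ms
    gamma
        ``params = (shape, scale[, shift])``
    """

    family: str = "shifted_lognormal"
    params: tuple[float, ...] = (np.log(1500.0), 0.4, 300.0)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}")
        self.frozen()  # validates parameter count/values

    def frozen(self) -> stats.rv_continuous:
        """The corresponding frozen scipy distribution."""
        p = self.params
        if self.family == "normal":
            loc, scale = p
            if scale <= 0:
                raise ValidationError("normal scale must be positive")
            return stats.norm(loc=loc, scale=scale)
        if self.family in ("lognormal", "shifted_lognormal"):
            mu, sigma = p[0], p[1]
            shift = p[2] if len(p) > 2 else 0.0
            if sigma <= 0:
                raise ValidationError("lognormal sigma must be positive")
            return stats.lognorm(s=sigma, loc=shift, scale=np.exp(mu))
        shape, scale = p[0], p[1]
        shift = p[2] if len(p) > 2 else 0.0
        if shape <= 0 or scale <= 0:
            raise ValidationError("gamma shape and scale must be positive")
        return stats.gamma(a=shape, loc=shift, scale=scale)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self.frozen().pdf(np.asarray(x, dtype=float))

    def mean(self) -> float:
        return float(self.frozen().mean())


def sample_mixture(
    a: BaseDistributionSpec,
    b: BaseDistributionSpec,
    p: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` values, each from ``a`` with probability ``p`` else from ``b``."""
    if not 0 <= p <= 1:
        raise ValidationError(f"mixture proportion p={p} outside [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from_a = rng.random(n) < p
    out = np.empty(n, dtype=float)
    n_a = int(from_a.sum())
    if n_a:
        out[from_a] = a.frozen().rvs(size=n_a, random_state=rng)
    if n - n_a:
        out[~from_a] = b.frozen().rvs(size=n - n_a, random_state=rng)
    return out


def analytic_mixture_density(
    a: BaseDistributionSpec,
    b: BaseDistributionSpec,
    p: float,
    x: np.ndarray,
) -> np.ndarray:
    """Exact mixture density ``p·f_a(x) + (1−p)·f_b(x)`` on the grid ``x``."""
    if not 0 <= p <= 1:
        raise ValidationError(f"mixture proportion p={p} outside [0, 1]")
    x = np.asarray(x, dtype=float)
    return p * a.pdf(x) + (1.0 - p) * b.pdf(x)
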