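"""Bayes factors for the two inferential steps of the fixed-point test.

Two quantities are needed:

* a JZS paired-samples t-test Bayes factor (condition screening, step 1):
  evidence for a difference in paired RT means under a Cauchy prior on the
  standardised effect size, against the point null;
* a repeated-measures one-way ANOVA Bayes factor (step 4): evidence that the
  per-participant crossing points of the three condition-pair density
  estimates share one distribution (null: participant random effect only)
  against a model adding a condition-pair fixed effect.  It is reported
  null-over-alternative, so values above 1 favour a common crossing point —
  i.e. a fixed point being *present*.

Both use the standard g-prior construction: effects are normal with variance
``g·σ²`` and ``g`` carries an inverse-gamma(1/2, r²/2) mixing prior, which is
equivalent to a Cauchy(0, r) prior on the standardised effect.  All
integrals over ``g`` are evaluated deterministically — adaptive quadrature
for the one-dimensional t-test integral, a Gauss–Hermite product rule for
the two g parameters of the ANOVA — so results are exactly reproducible
without MCMC.

The t-test integral substitutes ``g = r²/z²`` (``z`` standard normal, since
``g ~ InvGamma(1/2, r²/2)``) and integrates adaptively over ``z``; the ANOVA
integrals run a composite Gauss–Legendre product rule on ``log g``, where
both the inverse-gamma weight and the marginal-likelihood kernel are smooth
and the tails decay exponentially.

Default prior scales follow the conventions of the Rouder-style BF tests:
Cauchy scale √2/2 for the t-test effect, 1/2 for ANOVA fixed effects and 1
for the participant random effect; all are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PairwiseBF",
    "FixedPointBF",
    "jzs_paired_bf",
    "rm_anova_fixed_point_bf",
    "DEFAULT_T_SCALE",
    "DEFAULT_FIXED_SCALE",
    "DEFAULT_RANDOM_SCALE",
]

DEFAULT_T_SCALE = math.sqrt(2.0) / 2.0
DEFAULT_FIXED_SCALE = 0.5
DEFAULT_RANDOM_SCALE = 1.0

def _log_grid_rule(lo: float = -10.0, hi: float = 45.0, panels: int = 55, degree: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss–Legendre nodes/weights on ``u = log(g/r²)`` over [lo, hi].

    If ``g ~ InvGamma(1/2, r²/2)`` then ``g/r² ~ InvGamma(1/2, 1/2)``, whose
    log transform has the scale-free weight ``exp(−u/2 − e^(−u)/2)/√(2π)`` —
    a doubly-exponential left tail and an ``e^(−u/2)`` right tail — so one
    fixed window serves every prior scale.
    """
    x, w = np.polynomial.legendre.leggauss(degree)
    edges = np.linspace(lo, hi, panels + 1)
    mid = (edges[:-1] + edges[1:]) / 2.0
    half = (edges[1:] - edges[:-1]) / 2.0
    return (mid[:, None] + half[:, None] * x[None, :]).ravel(), (half[:, None] * w[None, :]).ravel()


_LOG_G_NODES, _LOG_G_WEIGHTS = _log_grid_rule()
# log of the InvGamma(1/2, 1/2) weight in u = log(g/r²), Jacobian included
_LOG_G_WEIGHT_DENSITY = -0.5 * math.log(2.0 * math.pi) - _LOG_G_NODES / 2.0 - np.exp(-_LOG_G_NODES) / 2.0


@dataclass(frozen=True)
class PairwiseBF:
    """JZS t-test Bayes factor for one ordered condition pair.

    ``bf10`` is evidence for a difference over no difference.  ``log_bf10``
    is always finite and should be preferred for thresholding when the
    evidence is overwhelming.
    """

    pair: tuple[str, str]
    bf10: float
    log_bf10: float

    def exceeds(self, criterion: float) -> bool:
        """Strictly exceeds a Bayes-factor criterion (computed in log space)."""
        if criterion < 0:
            raise ValidationError("criterion must be nonnegative")
        if criterion == 0.0:
            return True  # BFs are strictly positive
        return self.log_bf10 > math.log(criterion)


@dataclass(frozen=True)
class FixedPointBF:
    """ANOVA Bayes factor for the presence of a fixed point.

    ``bf_present`` is null-over-alternative: > 1 means the crossing points
    are more likely draws from a single distribution (fixed point present).
    """

    bf_present: float
    log_bf_present: float

    def exceeds(self, criterion: float) -> bool:
        if criterion < 0:
            raise ValidationError("criterion must be nonnegative")
        if criterion == 0.0:
            return True
        return self.log_bf_present > math.log(criterion)


def _log_jzs_numerator(t: float, n: int, r: float) -> float:
    """log ∫ (1+ng)^(−1/2) (1 + t²/((1+ng)ν))^(−(ν+1)/2) dInvGamma(g; 1/2, r²/2).

    Evaluated as a half-line integral over the normal mixing variable z with
    g = r²/z², using adaptive quadrature on a stabilised integrand.
    """
    nu = n - 1

    def log_f(z: float) -> float:
        g = (r * r) / (z * z)
        one_ng = 1.0 + n * g
        return -0.5 * math.log(one_ng) - 0.5 * (nu + 1) * math.log1p(t * t / (one_ng * nu))

    # stabilise: factor out the maximum of the log-integrand on a coarse grid
    zs = np.geomspace(1e-4, 40.0, 50)
    one_ng = 1.0 + n * (r * r) / (zs * zs)
    m = float(np.max(-0.5 * np.log(one_ng) - 0.5 * (nu + 1) * np.log1p(t * t / (one_ng * nu))))
    log_norm = -0.5 * math.log(2.0 * math.pi)

    def integrand(z: float) -> float:
        return 2.0 * math.exp(log_f(z) - m + log_norm - 0.5 * z * z)

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-12, epsrel=1e-11, limit=200)
    return m + math.log(val)


def jzs_paired_bf(
    differences: np.ndarray,
    cauchy_scale: float = DEFAULT_T_SCALE,
    pair: tuple[str, str] = ("A", "B"),
) -> PairwiseBF:
    """JZS Bayes factor for a paired-samples t-test on per-participant differences.

    Parameters
    ----------
    differences
        Vector of paired differences, one per participant.
    cauchy_scale
        Scale ``r`` of the Cauchy prior on the standardised effect size.
    pair
        Condition labels, carried through for reporting.

    Returns
    -------
    PairwiseBF with ``bf10`` = marginal likelihood under the Cauchy-effect
    alternative over that under the point null.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValidationError("need a 1-D vector of at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValidationError("differences contain non-finite values")
    if cauchy_scale <= 0:
        raise ValidationError("cauchy_scale must be positive")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("paired differences have zero variance")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    nu = n - 1
    log_null = -0.5 * (nu + 1) * math.log1p(t * t / nu)
    log_bf = _log_jzs_numerator(t, n, cauchy_scale) - log_null
    return PairwiseBF(pair=tuple(pair), bf10=float(np.exp(log_bf)), log_bf10=log_bf)


def _anova_sufficient_stats(y: np.ndarray) -> tuple[float, float, float, float, int, int]:
    """Sufficient statistics for the balanced one-way RM design.

    Returns (total SS, SS of the participant-mean projection, SS of the
    centred condition-mean projection, grand sum, n participants, a levels).
    """
    n, a = y.shape
    tot = float(np.sum(y * y))
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    grand = float(y.mean())
    pv1 = a * float(np.sum(row_means**2))
    pv2 = n * float(np.sum((col_means - grand) ** 2))
    s = float(y.sum())
    return tot, pv1, pv2, s, n, a


def _log_score_grid(
    g_a: np.ndarray,
    g_b: np.ndarray,
    stats_: tuple[float, float, float, float, int, int],
) -> np.ndarray:
    """log of the conditional marginal-likelihood kernel S(g_a, g_b).

    For the balanced design the covariance Σ = I + g_a·(participant blocks)
    + g_b·(centred condition blocks) has three eigenspaces — participant
    means (eigenvalue 1 + a·g_a, multiplicity n), centred condition means
    (1 + n·g_b, multiplicity a−1), and the residual space (1) — so the
    determinant and quadratic forms reduce to scalars.  The intercept and σ²
    are integrated analytically under the Jeffreys prior; constants common
    to both models are dropped.
    """
    tot, pv1, pv2, s, n, a = stats_
    N = n * a
    lam1 = 1.0 + a * g_a
    lam2 = 1.0 + n * g_b
    log_det = n * np.log(lam1) + (a - 1) * np.log(lam2)
    n_eff = N / lam1
    y_sy = pv1 / lam1 + pv2 / lam2 + (tot - pv1 - pv2)
    r2 = y_sy - (s * s) / (N * lam1)
    r2 = np.maximum(r2, 1e-300)
    return -0.5 * np.log(n_eff) - 0.5 * log_det - 0.5 * (N - 1) * np.log(r2)


def _log_expect_1d(logf, scale: float) -> float:
    """log ∫ f(g) dInvGamma(g; 1/2, scale²/2), composite GL rule on log(g/scale²)."""
    u, w = _LOG_G_NODES, _LOG_G_WEIGHTS
    logs = logf(scale * scale * np.exp(u)) + _LOG_G_WEIGHT_DENSITY
    m = float(logs.max())
    return m + math.log(float(np.sum(w * np.exp(logs - m))))


def _log_expect_2d(logf, scale_a: float, scale_b: float) -> float:
    """log of the double integral over both inverse-gamma priors (product rule)."""
    u, w = _LOG_G_NODES, _LOG_G_WEIGHTS
    g_a = scale_a * scale_a * np.exp(u)
    g_b = scale_b * scale_b * np.exp(u)
    logs = (
        logf(g_a[:, None], g_b[None, :])
        + _LOG_G_WEIGHT_DENSITY[:, None]
        + _LOG_G_WEIGHT_DENSITY[None, :]
    )
    m = float(logs.max())
    return m + math.log(float(np.sum(np.outer(w, w) * np.exp(logs - m))))


def rm_anova_fixed_point_bf(
    crossings: np.ndarray,
    fixed_scale: float = DEFAULT_FIXED_SCALE,
    random_scale: float = DEFAULT_RANDOM_SCALE,
) -> FixedPointBF:
    """Repeated-measures ANOVA Bayes factor for a common crossing point.

    Parameters
    ----------
    crossings
        Complete participant × condition-pair matrix of crossing RTs
        (ms); rows are participants (≥ 3), columns the three pairs.
    fixed_scale, random_scale
        g-prior scales for the condition-pair fixed effect and the
        participant random effect.

    Returns
    -------
    FixedPointBF with ``bf_present`` = marginal likelihood of the
    participant-only model over that of the model adding a condition-pair
    effect.  Values above 1 favour the fixed point being present.
    """
    y = np.asarray(crossings, dtype=float)
    if y.ndim != 2:
        raise ValidationError("crossings must be a 2-D participant × pair matrix")
    n, a = y.shape
    if n < 3:
        raise ValidationError(f"need at least 3 participants, got {n}")
    if a < 2:
        raise ValidationError("need at least 2 condition-pair columns")
    if not np.all(np.isfinite(y)):
        raise ValidationError("crossings matrix contains missing or non-finite entries")
    if fixed_scale <= 0 or random_scale <= 0:
        raise ValidationError("prior scales must be positive")
    if np.var(y) == 0.0:
        raise DegenerateInputError("crossings matrix is constant")

    st = _anova_sufficient_stats(y)
    log_null = _log_expect_1d(lambda g_a: _log_score_grid(g_a, np.zeros_like(g_a), st), random_scale)
    log_full = _log_expect_2d(lambda ga, gb: _log_score_grid(ga, gb, st), random_scale, fixed_scale)
    log_bf01 = log_null - log_full
    return FixedPointBF(bf_present=float(np.exp(log_bf01)), log_bf_present=log_bf01)
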