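"""Independent numerical oracles used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation:

* ``jzs_bf_delta_route`` — the JZS t-test BF as a one-dimensional integral
  over the *effect size* (noncentral-t likelihood × Cauchy prior), whereas
  the implementation integrates over the g mixing parameter.
* ``anova_log_score_matrix`` — the conditional marginal-likelihood kernel of
  the RM-ANOVA BF via explicit design matrices and dense linear algebra,
  whereas the implementation uses the balanced-design eigenvalue reduction.
* ``anova_bf_mc`` — the RM-ANOVA BF by direct Monte Carlo over the two
  inverse-gamma g priors (sampling g = r²/z², z standard normal), whereas
  the implementation uses a deterministic Gauss–Legendre product rule.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats

from fpdiag.bayes_factors import _anova_sufficient_stats, _log_score_grid


def jzs_bf_delta_route(differences: np.ndarray, scale: float = math.sqrt(2) / 2) -> float:
    """JZS paired BF10 by adaptive quadrature over the standardised effect size."""
    d = np.asarray(differences, dtype=float)
    n = d.size
    nu = n - 1
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * math.sqrt(n)) * stats.cauchy.pdf(delta, 0.0, scale)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, points=None, limit=400, epsabs=1e-14, epsrel=1e-12)
    den = stats.t.pdf(t, nu)
    return num / den


def anova_log_score_matrix(y: np.ndarray, g_a: float, g_b: float) -> float:
    """log marginal-likelihood kernel via dense N×N covariance algebra.

    Builds Σ = I + g_a·X_a X_aᵀ + g_b·X_b* X_b*ᵀ explicitly (participant
    indicators; sum-to-zero orthonormal condition contrasts) and evaluates
    −½·log(1ᵀΣ⁻¹1) − ½·log|Σ| − ((N−1)/2)·log R² directly.
    """
    y = np.asarray(y, dtype=float)
    n, a = y.shape
    N = n * a
    yv = y.reshape(-1)  # participant-major ordering
    x_a = np.kron(np.eye(n), np.ones((a, 1)))
    # orthonormal contrasts spanning the complement of the unit vector
    c = np.eye(a) - np.ones((a, a)) / a
    evals, evecs = np.linalg.eigh(c)
    q = evecs[:, evals > 0.5]
    x_b = np.kron(np.ones((n, 1)), q)
    sigma = np.eye(N) + g_a * (x_a @ x_a.T) + g_b * (x_b @ x_b.T)
    sign, logdet = np.linalg.slogdet(sigma)
    assert sign > 0
    sol_y = np.linalg.solve(sigma, yv)
    sol_1 = np.linalg.solve(sigma, np.ones(N))
    n_eff = float(np.ones(N) @ sol_1)
    r2 = float(yv @ sol_y) - float(np.ones(N) @ sol_y) ** 2 / n_eff
    return -0.5 * math.log(n_eff) - 0.5 * logdet - 0.5 * (N - 1) * math.log(r2)


def anova_bf_mc(
    y: np.ndarray,
    n_draws: int = 1_000_000,
    fixed_scale: float = 0.5,
    random_scale: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of log BF01 and the standard error of that log.

    Samples g from its prior via g = r²/z² (z standard normal) and averages
    the scalar marginal-likelihood kernel; numerator and denominator use
    independent draws, and the SE combines both by the delta method.
    """
    y = np.asarray(y, dtype=float)
    st = _anova_sufficient_stats(y)
    rng = np.random.default_rng(seed)
    g_a0 = random_scale**2 / rng.standard_normal(n_draws) ** 2
    l0 = _log_score_grid(g_a0, np.zeros(1), st)
    g_a1 = random_scale**2 / rng.standard_normal(n_draws) ** 2
    g_b1 = fixed_scale**2 / rng.standard_normal(n_draws) ** 2
    l1 = _log_score_grid(g_a1, g_b1, st)
    m = max(float(l0.max()), float(l1.max()))
    e0 = np.exp(l0 - m)
    e1 = np.exp(l1 - m)
    log_bf = math.log(e0.mean()) - math.log(e1.mean())
    se = math.sqrt(
        e0.var() / (n_draws * e0.mean() ** 2) + e1.var() / (n_draws * e1.mean() ** 2)
    )
    return log_bf, se


def normal_crossing_points(mu1: float, s1: float, mu2: float, s2: float) -> list[float]:
    """Exact crossing point(s) of two normal densities (log-density equality)."""
    if s1 == s2:
        return [(mu1 + mu2) / 2.0] if mu1 != mu2 else []
    # quadratic a·x² + b·x + c = 0 from equating log densities
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (mu1 / s1**2 - mu2 / s2**2)
    c = mu2**2 / s2**2 - mu1**2 / s1**2 + 2.0 * math.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    roots = sorted([(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)])
    return roots
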