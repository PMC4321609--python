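"""Statistical layer for SSA populations.

Three procedures cover the analysis of spindle-size-asymmetry data:

* **Folded-normal fitting.**  SSA magnitudes are absolute values of a
  signed latent difference, so their distribution on [0, inf) is the
  folded normal: pdf(x) = [phi((x-mu)/sigma) + phi((x+mu)/sigma)] / sigma.
  Parameters are estimated by constrained maximum likelihood (mu >= 0).

* **Permutation tests.**  Differences between developmental stages are
  assessed by randomly permuting group labels; the statistic is the
  absolute difference of group means, and the p-value uses the add-one
  estimator p = (1 + #{permuted >= observed}) / (n_perm + 1), which is
  valid (never zero) for any number of permutations.

* **Regression with confidence bands.**  The 3D-vs-2D comparison is an
  ordinary least-squares line with its 95% pointwise band
  (t-multiplier) and the 95% Working-Hotelling simultaneous band
  (sqrt(2 F) multiplier), which covers the entire true line jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "FoldedNormalParams",
    "PermutationResult",
    "RegressionBands",
    "StageComparison",
    "folded_normal_pdf",
    "fit_folded_normal",
    "permutation_test",
    "linear_regression_bands",
    "stage_comparison",
]


@dataclass(frozen=True)
class FoldedNormalParams:
    """Location mu >= 0 and scale sigma > 0 of a folded normal, in percent.

    The distribution of |X| for X ~ N(mu, sigma^2) is invariant under
    mu -> -mu, so mu is constrained non-negative for identifiability.
    """

    mu: float
    sigma: float
    converged: bool = True
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


def folded_normal_pdf(
    x, params: FoldedNormalParams, strict_domain: bool = False
) -> np.ndarray | float:
    """Density of the folded normal at ``x`` (zero for x < 0).

    With ``strict_domain`` a negative ``x`` raises instead of returning 0.
    At mu = 0 this is the half-normal 2 phi(x/sigma)/sigma.
    """
    arr = np.asarray(x, dtype=float)
    if strict_domain and np.any(arr < 0):
        raise ValueError("folded-normal support is [0, inf)")
    mu, sigma = params.mu, params.sigma
    dens = (stats.norm.pdf((arr - mu) / sigma) + stats.norm.pdf((arr + mu) / sigma)) / sigma
    dens = np.where(arr < 0, 0.0, dens)
    return float(dens) if np.isscalar(x) else dens


def _folded_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma = theta
    sigma = np.exp(log_sigma)
    z1 = (x - mu) / sigma
    z2 = (x + mu) / sigma
    # log(phi(z1) + phi(z2)) with a stable log-sum-exp
    a = -0.5 * z1**2
    b = -0.5 * z2**2
    m = np.maximum(a, b)
    log_pdf = m + np.log(np.exp(a - m) + np.exp(b - m)) - 0.5 * np.log(2 * np.pi) - log_sigma
    return -float(np.sum(log_pdf))


def fit_folded_normal(samples: Sequence[float]) -> FoldedNormalParams:
    """Constrained MLE of the folded normal from non-negative magnitudes.

    Starts from the method-of-moments relation E[X^2] = mu^2 + sigma^2
    and refines by L-BFGS-B with a mu >= 0 box constraint.  Requires at
    least 10 samples; an all-equal sample has no scale and is rejected.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("folded-normal fitting needs at least 10 samples")
    if np.any(x < 0):
        raise ValueError("SSA magnitudes must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")

    m1, m2 = float(np.mean(x)), float(np.mean(x**2))
    sd = float(np.std(x, ddof=1))
    # moment start: split the second moment between mu^2 and sigma^2
    mu0 = float(np.sqrt(max(m2 - sd**2, 1e-8)))
    starts = [(mu0, sd), (0.0, np.sqrt(m2)), (m1, sd)]
    best = None
    for mu_s, sigma_s in starts:
        res = optimize.minimize(
            _folded_nll,
            x0=np.array([mu_s, np.log(max(sigma_s, 1e-6))]),
            args=(x,),
            method="L-BFGS-B",
            bounds=[(0.0, None), (None, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, log_sigma_hat = best.x
    return FoldedNormalParams(
        mu=float(mu_hat),
        sigma=float(np.exp(log_sigma_hat)),
        converged=bool(best.success),
        log_likelihood=-float(best.fun),
    )


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, p-value and reproducibility metadata."""

    observed_stat: float
    p_value: float
    n_perm: int
    seed: int


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    add_one: bool = True,
) -> PermutationResult:
    """Two-sided permutation test on |mean(a) - mean(b)|.

    Group labels are shuffled ``n_perm`` times; with ``add_one`` (the
    default) the p-value is (1 + #{>= observed}) / (n_perm + 1), which
    is never zero and exactly valid under exchangeability.  Setting
    ``add_one=False`` reports the raw proportion #{>= observed} / n_perm.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    count = 0
    # batched shuffles keep memory bounded for large n_perm
    batch = max(1, min(n_perm, 2_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        keys = rng.random((k, pooled.size))
        order = np.argsort(keys, axis=1)
        shuffled = pooled[order]
        stat = np.abs(shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1))
        count += int(np.count_nonzero(stat >= observed - 1e-12))
        done += k
    if add_one:
        p = (1 + count) / (n_perm + 1)
    else:
        p = count / n_perm
    return PermutationResult(
        observed_stat=float(observed), p_value=float(p), n_perm=n_perm, seed=seed
    )


@dataclass
class RegressionBands:
    """OLS line with pointwise and Working-Hotelling simultaneous 95% bands.

    ``pointwise_band(x)`` and ``simultaneous_band(x)`` evaluate the band
    limits at arbitrary abscissae.  The simultaneous band uses the
    sqrt(2 F_{level; 2, n-2}) multiplier appropriate for a two-parameter
    line, so it contains the pointwise band at every x.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci_95: tuple[float, float]
    n: int
    level: float
    residual_scale: float
    x_mean: float
    sxx: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def _se_mean(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.residual_scale * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)

    def pointwise_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        t_mult = stats.t.ppf(0.5 + self.level / 2, self.n - 2)
        fit = self.predict(x)
        half = t_mult * self._se_mean(x)
        return fit - half, fit + half

    def simultaneous_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        w_mult = np.sqrt(2.0 * stats.f.ppf(self.level, 2, self.n - 2))
        fit = self.predict(x)
        half = w_mult * self._se_mean(x)
        return fit - half, fit + half


def linear_regression_bands(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> RegressionBands:
    """OLS of y on x with slope CI and 95% pointwise / simultaneous bands."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    intercept_se, slope_se = model.bse
    ci = model.conf_int(alpha=1 - level)
    return RegressionBands(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        slope_ci_95=(float(ci[1][0]), float(ci[1][1])),
        n=int(x.size),
        level=level,
        residual_scale=float(np.sqrt(model.scale)),
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


@dataclass
class StageComparison:
    """Per-stage folded-normal fits plus permutation tests vs a reference stage."""

    fits: dict[str, FoldedNormalParams]
    tests: dict[str, PermutationResult]
    reference: str
    adjusted_p: dict[str, float] | None = None
    note: str = (
        "p-values are raw by default; Holm adjustment available via adjust='holm'"
    )


def stage_comparison(
    groups: Mapping[str, Sequence[float]],
    reference: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    adjust: str | None = None,
) -> StageComparison:
    """Fit each developmental stage and test each against the reference stage.

    ``reference`` defaults to the first stage in mapping order (the
    earliest stage when the mapping is built chronologically).  With a
    single stage only the fit is returned.  ``adjust='holm'`` attaches
    Holm-adjusted p-values alongside the raw ones.
    """
    names = list(groups)
    if not names:
        raise ValueError("no stages given")
    fits = {name: fit_folded_normal(groups[name]) for name in names}
    reference = reference or names[0]
    if reference not in groups:
        raise KeyError(f"reference stage {reference!r} not in groups")
    tests: dict[str, PermutationResult] = {}
    for i, name in enumerate(names):
        if name == reference:
            continue
        tests[name] = permutation_test(
            groups[reference], groups[name], n_perm=n_perm, seed=seed + i
        )
    adjusted = None
    if adjust == "holm" and tests:
        from statsmodels.stats.multitest import multipletests

        keys = list(tests)
        _, p_adj, _, _ = multipletests([tests[k].p_value for k in keys], method="holm")
        adjusted = dict(zip(keys, (float(p) for p in p_adj)))
    return StageComparison(fits=fits, tests=tests, reference=reference, adjusted_p=adjusted)
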