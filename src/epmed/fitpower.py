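"""SEM goodness-of-fit indices and post-hoc power computations.

Fit of the path model is judged by the maximum-likelihood discrepancy
between the sample covariance S and the model-implied covariance Sigma,

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^{-1}) - p,     chi2 = (n - 1) F_ML,

with the usual derived indices: RMSEA (with a 90% CI from noncentral
chi-square inversion), CFI against the independence baseline, and SRMR over
standardized residual covariances (diagonal included by default).

Two post-hoc power computations are provided: power of the RMSEA-based
exact-fit test via the noncentral chi-square with noncentrality
lambda = (n-1) * df * epsilon^2, and joint-significance power for a
specific indirect effect a*b with standardized-coefficient standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .pathmodel import ModelSpec, PathEstimates


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    r2_outcome: float | None
    n: int

    def __post_init__(self) -> None:
        assert self.chi2 >= 0 and self.rmsea >= 0 and self.srmr >= 0
        assert 0.0 <= self.cfi <= 1.0


@dataclass
class PowerResult:
    power: float
    alpha: float
    inputs: dict
    noncentrality: float | None = None


def model_degrees_of_freedom(spec: ModelSpec) -> int:
    """Degrees of freedom of the path model: moments minus free parameters.

    Free parameters: the saturated exogenous covariance block (markers +
    age), all declared regression paths, residual variances for mediators
    and outcome, and the declared mediator residual covariances.
    """
    p = len(spec.predictors)
    nm = len(spec.mediators)
    v = p + 1 + nm + 1
    moments = v * (v + 1) // 2
    exog = (p + 1) * (p + 2) // 2
    reg = (nm * p + len(spec.covariate_edges) + (p + nm)
           + int(spec.covariate_on_outcome))
    resid = (nm + 1) + len(spec.residual_corr_pairs)
    return moments - (exog + reg + resid)


def model_implied_covariance(est: PathEstimates, spec: ModelSpec | None = None
                             ) -> pd.DataFrame:
    """Model-implied covariance of all observed variables.

    Built from the structural coefficients via Sigma = (I-B)^{-1} Psi
    (I-B)^{-T}, with the exogenous (markers + age) covariance block free at
    its sample value, mediator residual covariances free only for the
    declared pairs, and all other residual covariances fixed at zero.
    """
    spec = spec or est.spec
    preds = list(spec.predictors)
    meds = list(spec.mediators)
    names = preds + [spec.covariate] + meds + [spec.outcome]
    p = len(preds)
    nm = len(meds)
    v = len(names)

    B = np.zeros((v, v))
    for j, m in enumerate(meds):
        row = p + 1 + j
        B[row, :p] = est.a.loc[m, preds].to_numpy()
        B[row, p] = est.age_coefs[m]
    yrow = p + 1 + nm
    B[yrow, :p] = est.c_prime[preds].to_numpy()
    B[yrow, p] = est.age_outcome
    B[yrow, p + 1:p + 1 + nm] = est.b[meds].to_numpy()

    Psi = np.zeros((v, v))
    Psi[: p + 1, : p + 1] = est.exog_cov.loc[preds + [spec.covariate],
                                             preds + [spec.covariate]].to_numpy()
    Psi[p + 1:p + 1 + nm, p + 1:p + 1 + nm] = est.resid_cov.loc[meds, meds].to_numpy()
    Psi[yrow, yrow] = est.resid_var[spec.outcome]

    inv = np.linalg.inv(np.eye(v) - B)
    sigma = inv @ Psi @ inv.T
    sigma = (sigma + sigma.T) / 2
    wmin = float(np.linalg.eigvalsh(sigma).min())
    if wmin < -1e-8:
        raise ValueError(f"implied covariance not PSD (smallest eigenvalue {wmin:.3e})")
    return pd.DataFrame(sigma, index=names, columns=names)


def _fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0:
        raise ValueError("sample covariance is not positive definite")
    if sign_m <= 0:
        raise ValueError("implied covariance is singular")
    f = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(Sigma))) - p
    return max(f, 0.0)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """Invert the noncentral chi-square for the RMSEA confidence limits."""
    lo_tail = (1 + level) / 2   # lambda with P(X <= chi2) = 0.95 -> lower limit
    hi_tail = (1 - level) / 2

    def bound(target):
        if stats.ncx2.cdf(chi2, df, 1e-10) < target:
            return 0.0
        hi = max(chi2 * 2, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2
            if hi > 1e7:
                break
        sol = optimize.brentq(lambda nc: stats.ncx2.cdf(chi2, df, nc) - target,
                              1e-12, hi)
        return sol

    lam_lo = bound(lo_tail)
    lam_hi = bound(hi_tail)
    denom = df * (n - 1)
    return (np.sqrt(lam_lo / denom), np.sqrt(lam_hi / denom))


def fit_indices(
    sample_cov,
    implied_cov,
    n: int,
    df_model: int,
    r2_outcome: float | None = None,
    srmr_diagonal: bool = True,
) -> FitIndices:
    """Chi-square, RMSEA (+90% CI), CFI and SRMR from S and Sigma.

    The CFI baseline is the independence model (free variances, all
    covariances zero).  SRMR averages squared standardized residual
    covariances over the lower triangle, including the diagonal unless
    ``srmr_diagonal`` is False.
    """
    S = np.asarray(sample_cov, dtype=float)
    Sigma = np.asarray(implied_cov, dtype=float)
    if S.shape != Sigma.shape:
        raise ValueError("sample and implied covariance dimensions differ")
    p = S.shape[0]

    chi2 = (n - 1) * _fml(S, Sigma)
    pval = float(stats.chi2.sf(chi2, df_model)) if df_model > 0 else float("nan")
    rmsea = float(np.sqrt(max(chi2 - df_model, 0.0) / (df_model * (n - 1)))) \
        if df_model > 0 else 0.0
    rmsea_ci = _rmsea_ci(chi2, df_model, n) if df_model > 0 else (0.0, 0.0)

    chi2_b = (n - 1) * _fml(S, np.diag(np.diag(S)))
    df_b = p * (p - 1) // 2
    num = max(chi2 - df_model, 0.0)
    den = max(chi2_b - df_b, chi2 - df_model, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)

    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    tril = np.tril_indices(p, 0 if srmr_diagonal else -1)
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))

    return FitIndices(float(chi2), int(df_model), pval, rmsea, rmsea_ci,
                      float(np.clip(cfi, 0.0, 1.0)), srmr, r2_outcome, n)


def rmsea_power(
    df: int, n: int, epsilon_a: float, epsilon_0: float = 0.0, alpha: float = 0.05
) -> PowerResult:
    """Power of the RMSEA-based likelihood-ratio test of model fit.

    Under a population RMSEA epsilon the test statistic is noncentral
    chi-square with noncentrality lambda = (n-1) * df * epsilon^2; the
    critical value comes from the null epsilon_0 (exact fit when 0) and
    power is the upper tail probability under epsilon_a.
    """
    if df < 1 or n <= 1:
        raise ValueError("need df >= 1 and n > 1")
    if not epsilon_a >= epsilon_0 >= 0:
        raise ValueError("need epsilon_a >= epsilon_0 >= 0")
    lam0 = (n - 1) * df * epsilon_0**2
    lama = (n - 1) * df * epsilon_a**2
    crit = stats.chi2.ppf(1 - alpha, df) if lam0 == 0 else stats.ncx2.ppf(1 - alpha, df, lam0)
    power = float(stats.ncx2.sf(crit, df, lama))
    return PowerResult(
        power, alpha,
        dict(df=df, n=n, epsilon_a=epsilon_a, epsilon_0=epsilon_0),
        noncentrality=float(lama),
    )


def mediation_power_joint(
    a: float, b: float, c_prime: float, n: int, alpha: float = 0.05
) -> PowerResult:
    """Joint-significance power for the indirect effect a*b.

    Standardized paths: a (gene -> endophenotype), b (endophenotype ->
    reading, adjusted for the gene) and c' (direct path).  Power is the
    product of the probabilities that the a-path and b-path z-tests both
    reject, using large-sample standard errors of standardized
    coefficients.
    """
    for name, val in (("a", a), ("b", b), ("c_prime", c_prime)):
        if abs(val) >= 1:
            raise ValueError(f"standardized path {name} must satisfy |{name}| < 1")
    r2_y = b**2 + c_prime**2 + 2 * a * b * c_prime
    corr = np.array([
        [1.0, a, c_prime + a * b],
        [a, 1.0, b + a * c_prime],
        [c_prime + a * b, b + a * c_prime, 1.0],
    ])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("paths imply a non-PSD correlation matrix")
    se_a = np.sqrt((1 - a**2) / (n - 2))
    se_b = np.sqrt((1 - r2_y) / ((n - 3) * (1 - a**2)))
    z_crit = ndtri(1 - alpha / 2)
    power_a = float(ndtr(abs(a) / se_a - z_crit))
    power_b = float(ndtr(abs(b) / se_b - z_crit))
    return PowerResult(
        power_a * power_b, alpha,
        dict(a=a, b=b, c_prime=c_prime, n=n, power_a=power_a, power_b=power_b),
    )


def mediation_power_montecarlo(
    a: float, b: float, c_prime: float, n: int, alpha: float = 0.05,
    n_sim: int = 10_000, seed: int = 0,
) -> PowerResult:
    """Monte-Carlo check of the joint-significance power.

    Simulates (X, M, Y) from the standardized single-mediator model and
    counts how often both OLS path t-tests reject at level alpha.
    """
    rng = np.random.default_rng(seed)
    var_m = 1 - a**2
    var_y = 1 - (b**2 + c_prime**2 + 2 * a * b * c_prime)
    if var_m <= 0 or var_y <= 0:
        raise ValueError("paths imply negative residual variance")
    hits = 0
    z_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    z_crit_b = stats.t.ppf(1 - alpha / 2, n - 3)
    for _ in range(n_sim):
        x = rng.standard_normal(n)
        m = a * x + np.sqrt(var_m) * rng.standard_normal(n)
        y = c_prime * x + b * m + np.sqrt(var_y) * rng.standard_normal(n)
        xz = (x - x.mean()) / x.std()
        mz = (m - m.mean()) / m.std()
        yz = (y - y.mean()) / y.std()
        a_hat = xz @ mz / n
        t_a = a_hat * np.sqrt((n - 2) / max(1e-12, 1 - a_hat**2))
        D = np.column_stack([xz, mz])
        coef, res, *_ = np.linalg.lstsq(D, yz, rcond=None)
        resid = yz - D @ coef
        s2 = resid @ resid / (n - 3)
        cov = s2 * np.linalg.inv(D.T @ D)
        t_b = coef[1] / np.sqrt(cov[1, 1])
        if abs(t_a) > z_crit and abs(t_b) > z_crit_b:
            hits += 1
    return PowerResult(hits / n_sim, alpha,
                       dict(a=a, b=b, c_prime=c_prime, n=n, n_sim=n_sim))
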