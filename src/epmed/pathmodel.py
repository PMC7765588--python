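"""Multiple-predictor / multiple-mediator path model with cluster bootstrap.

The model is a recursive observed-variable system: each of the five
mediators is regressed on all coded markers (plus age, where an age
covariate edge is declared), and the reading outcome is regressed on all
markers and all mediators.  Point estimates come from equation-wise least
squares on standardized data; for a recursive system with these residual
assumptions the equation-wise solution coincides with the maximum-
likelihood point estimates, which keeps each bootstrap replicate cheap.

Indirect effects use the product-of-coefficients decomposition: the
specific indirect effect of marker k through mediator j is a_jk * b_j, the
total indirect effect is the sum over mediators, and the total effect adds
the direct path c'_k.  Inference is by a family-clustered bias-corrected
(BC) percentile bootstrap: whole families (unrelated controls are singleton
clusters) are resampled with replacement to the original cluster count,
each replicate is re-standardized and refit, and the BC interval uses the
normal-quantile bias correction z0 with bounds at the
Phi(2 z0 +/- z_{alpha/2}) percentiles of the replicate distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import ndtr, ndtri

from .markers import MEDIATORS

log = logging.getLogger(__name__)

DEFAULT_RESIDUAL_PAIRS = (
    ("WE", "RTLI_b"), ("RAP", "RTLI_b"), ("RAP", "RTLI_t"),
    ("RAP", "RAN_rt"), ("RTLI_b", "RTLI_t"),
)
DEFAULT_AGE_EDGES = ("RTLI_b", "RAP", "RAN_rt")


@dataclass
class ModelSpec:
    """Declarative description of the path model and its inference settings."""

    predictors: list[str]
    mediators: tuple[str, ...] = MEDIATORS
    outcome: str = "reading"
    covariate: str = "age"
    covariate_edges: tuple[str, ...] = DEFAULT_AGE_EDGES
    covariate_on_outcome: bool = False
    residual_corr_pairs: tuple[tuple[str, str], ...] = DEFAULT_RESIDUAL_PAIRS
    cluster: str = "family_id"
    n_boot: int = 5000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.mediators) & set(self.predictors):
            raise ValueError("mediators and predictors must be disjoint")
        for edge in self.covariate_edges:
            if edge not in self.mediators:
                raise ValueError(f"covariate edge target {edge!r} is not a mediator")
        for a, b in self.residual_corr_pairs:
            if a not in self.mediators or b not in self.mediators:
                raise ValueError(f"residual pair ({a}, {b}) references unknown mediator")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PathEstimates:
    """Standardized path coefficients and residual structure."""

    spec: ModelSpec
    a: pd.DataFrame          # mediators x predictors
    age_coefs: pd.Series     # age -> mediator (0 where no edge declared)
    age_outcome: float       # age -> outcome (0 unless declared)
    b: pd.Series             # mediator -> outcome
    c_prime: pd.Series       # direct marker -> outcome
    intercepts: pd.Series    # zero in the standardized metric, kept for record
    resid_var: pd.Series     # per mediator and outcome
    resid_cov: pd.DataFrame  # mediator residual covariances (declared pairs only)
    exog_cov: pd.DataFrame   # predictors + covariate sample covariance
    sample_cov: pd.DataFrame  # all model variables, standardized scale
    r2_outcome: float
    n: int
    scales: pd.DataFrame     # per-column mean/sd for back-transformation


@dataclass
class IndirectEffects:
    """Product-of-coefficients effect decomposition."""

    specific: pd.DataFrame    # predictors x mediators, a_jk * b_j
    total: pd.Series          # per predictor, sum over mediators
    total_effect: pd.Series   # c'_k + total_k


@dataclass
class BootstrapResult:
    """Point estimates with bias-corrected percentile intervals."""

    table: pd.DataFrame  # effect, predictor, mediator, estimate, se, lower, upper, significant
    n_boot: int
    n_failed: int
    seed: int
    replicates: np.ndarray | None = None
    effect_index: pd.DataFrame | None = None


def standardize(data: pd.DataFrame, columns=None):
    """Center and scale columns to unit SD; returns (standardized, scales).

    ``scales`` records mean and sd per column so the transformation can be
    inverted exactly.  A zero-variance column is an error naming it.
    """
    columns = list(columns) if columns is not None else list(data.columns)
    out = data.copy()
    rec = {}
    for c in columns:
        x = data[c].to_numpy(dtype=float)
        mu = np.nanmean(x)
        sd = np.nanstd(x)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"zero-variance column {c!r} cannot be standardized")
        out[c] = (x - mu) / sd
        rec[c] = (mu, sd)
    scales = pd.DataFrame(rec, index=["mean", "sd"]).T
    return out, scales


def unstandardize(data: pd.DataFrame, scales: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    for c in scales.index:
        if c in out:
            out[c] = out[c] * scales.loc[c, "sd"] + scales.loc[c, "mean"]
    return out


# ---------------------------------------------------------------------------
# numeric core
# ---------------------------------------------------------------------------


class _Arrays:
    """Column-packed numeric view of the model frame: [preds | age | M | y]."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        cols = (list(spec.predictors) + [spec.covariate] + list(spec.mediators)
                + [spec.outcome])
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"model frame lacks columns {missing}")
        sub = data[cols + [spec.cluster]].copy()
        n0 = len(sub)
        sub = sub.dropna()
        if len(sub) < n0:
            log.warning("listwise deletion dropped %d of %d subjects",
                        n0 - len(sub), n0)
        self.frame = sub
        self.X = sub[cols].to_numpy(dtype=float)
        self.cols = cols
        self.p = len(spec.predictors)
        self.nm = len(spec.mediators)
        self.age_col = self.p
        self.med_sl = slice(self.p + 1, self.p + 1 + self.nm)
        self.y_col = self.p + 1 + self.nm
        self.med_has_age = np.array(
            [m in spec.covariate_edges for m in spec.mediators]
        )
        self.outcome_has_age = bool(spec.covariate_on_outcome)
        clusters, inv = np.unique(sub[spec.cluster].to_numpy(), return_inverse=True)
        self.cluster_members = [np.flatnonzero(inv == i) for i in range(len(clusters))]
        self.n_clusters = len(clusters)


def _zscore_or_none(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        return None
    return (X - mu) / sd


def _solve_system(Z: np.ndarray, arr: _Arrays, want_resid: bool = False):
    """Equation-wise least squares on a standardized column-packed array.

    Returns (a, age_coefs, b, cp, extras) or None when any design is
    numerically rank-deficient.
    """
    p, nm = arr.p, arr.nm
    P = Z[:, :p]
    age = Z[:, arr.age_col:arr.age_col + 1]
    Med = Z[:, arr.med_sl]
    y = Z[:, arr.y_col]

    a = np.empty((nm, p))
    age_coefs = np.zeros(nm)
    resid_m = np.empty_like(Med) if want_resid else None
    try:
        for with_age in (False, True):
            sel = np.flatnonzero(arr.med_has_age == with_age)
            if sel.size == 0:
                continue
            D = np.hstack([P, age]) if with_age else P
            G = cho_factor(D.T @ D)
            coef = cho_solve(G, D.T @ Med[:, sel])
            a[sel] = coef[:p].T
            if with_age:
                age_coefs[sel] = coef[p]
            if want_resid:
                resid_m[:, sel] = Med[:, sel] - D @ coef
        Dy = np.hstack([P, Med, age]) if arr.outcome_has_age else np.hstack([P, Med])
        Gy = cho_factor(Dy.T @ Dy)
        coef_y = cho_solve(Gy, Dy.T @ y)
    except LinAlgError:
        return None
    cp = coef_y[:p]
    b = coef_y[p:p + nm]
    age_y = float(coef_y[p + nm]) if arr.outcome_has_age else 0.0
    extras = None
    if want_resid:
        resid_y = y - Dy @ coef_y
        extras = dict(resid_m=resid_m, resid_y=resid_y)
    return a, age_coefs, b, cp, age_y, extras


def _effects_vector(a, b, cp):
    specific = a * b[:, None]          # (nm, p)
    total = specific.sum(axis=0)       # (p,)
    return np.concatenate([specific.ravel(), total, cp + total])


def fit_path_model(data: pd.DataFrame, spec: ModelSpec) -> PathEstimates:
    """Fit the path model by equation-wise least squares on standardized data.

    ``data`` is the model frame (one row per subject) holding the coded
    marker predictors, the age covariate, the five mediators, the outcome
    and the family cluster column.  Rows with any missing value are dropped
    (logged).  Collinear predictors raise an error listing the offending
    columns.
    """
    arr = _Arrays(data, spec)
    n = arr.X.shape[0]
    n_coef = arr.p + 1 + arr.nm
    if n <= n_coef:
        raise ValueError(f"n = {n} too small for {n_coef} coefficients per equation")
    sds = arr.X.std(axis=0)
    zero = [c for c, s in zip(arr.cols, sds) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s) {zero} cannot be standardized")
    Z = _zscore_or_none(arr.X)

    design = np.hstack([Z[:, :arr.p], Z[:, arr.age_col:arr.age_col + 1]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, s, vt = np.linalg.svd(design, full_matrices=False)
        null = vt[s < s.max() * 1e-10]
        names = list(spec.predictors) + [spec.covariate]
        involved = sorted({names[j] for v in null for j in np.flatnonzero(np.abs(v) > 0.1)})
        raise ValueError(f"rank-deficient design; collinear columns: {involved}")

    sol = _solve_system(Z, arr, want_resid=True)
    if sol is None:
        raise ValueError("normal equations are singular; check predictors for collinearity")
    a, age_coefs, b, cp, age_y, extras = sol

    meds = list(spec.mediators)
    resid_m = extras["resid_m"]
    resid_y = extras["resid_y"]
    resid_var = pd.Series(
        np.r_[resid_m.var(axis=0), resid_y.var()], index=meds + [spec.outcome]
    )
    rc = pd.DataFrame(0.0, index=meds, columns=meds)
    full_cov = np.cov(resid_m, rowvar=False, ddof=0)
    for mi, mj in spec.residual_corr_pairs:
        i, j = meds.index(mi), meds.index(mj)
        rc.iloc[i, j] = rc.iloc[j, i] = full_cov[i, j]
    np.fill_diagonal(rc.values, resid_m.var(axis=0))

    exog_names = list(spec.predictors) + [spec.covariate]
    exog_cov = pd.DataFrame(
        np.cov(Z[:, : arr.p + 1], rowvar=False, ddof=0),
        index=exog_names, columns=exog_names,
    )
    sample_cov = pd.DataFrame(np.cov(Z, rowvar=False, ddof=0),
                              index=arr.cols, columns=arr.cols)
    _, scales = standardize(arr.frame[arr.cols])

    return PathEstimates(
        spec=spec,
        a=pd.DataFrame(a, index=meds, columns=spec.predictors),
        age_coefs=pd.Series(age_coefs, index=meds),
        age_outcome=age_y,
        b=pd.Series(b, index=meds),
        c_prime=pd.Series(cp, index=spec.predictors),
        intercepts=pd.Series(0.0, index=meds + [spec.outcome]),
        resid_var=resid_var,
        resid_cov=rc,
        exog_cov=exog_cov,
        sample_cov=sample_cov,
        r2_outcome=float(1.0 - resid_y.var()),
        n=n,
        scales=scales,
    )


def indirect_effects(est: PathEstimates) -> IndirectEffects:
    """Product-of-coefficients decomposition of the fitted model.

    specific[k, j] = a_jk * b_j; total_k = sum_j specific[k, j];
    total_effect_k = c'_k + total_k.  The additivity identity holds exactly
    by construction.
    """
    specific = (est.a * est.b.to_numpy()[:, None]).T  # predictors x mediators
    total = specific.sum(axis=1)
    return IndirectEffects(
        specific=specific,
        total=total.rename("total_indirect"),
        total_effect=(est.c_prime + total).rename("total_effect"),
    )


def _effect_index(spec: ModelSpec) -> pd.DataFrame:
    rows = [
        dict(effect="specific", predictor=k, mediator=j)
        for j in spec.mediators for k in spec.predictors
    ]
    rows += [dict(effect="total_indirect", predictor=k, mediator=None)
             for k in spec.predictors]
    rows += [dict(effect="total_effect", predictor=k, mediator=None)
             for k in spec.predictors]
    return pd.DataFrame(rows)


def bc_interval(replicates: np.ndarray, point: np.ndarray, ci_level: float):
    """Bias-corrected percentile interval, vectorized over effect columns.

    z0 is the normal quantile of the proportion of replicates below the
    point estimate (clipped away from 0/1); the interval takes the
    Phi(2 z0 -/+ z_{alpha/2}) percentiles of the replicate distribution.
    """
    B = replicates.shape[0]
    prop = (replicates < point).mean(axis=0)
    prop = np.clip(prop, 1.0 / (B + 1), B / (B + 1.0))
    z0 = ndtri(prop)
    za = ndtri(1 - (1 - ci_level) / 2)
    q_lo = ndtr(2 * z0 - za)
    q_hi = ndtr(2 * z0 + za)
    lower = np.empty_like(point)
    upper = np.empty_like(point)
    for j in range(point.size):
        lower[j], upper[j] = np.quantile(replicates[:, j], (q_lo[j], q_hi[j]))
    return lower, upper


def cluster_bootstrap(
    data: pd.DataFrame, spec: ModelSpec, keep_replicates: bool = False
) -> BootstrapResult:
    """Family-clustered BC percentile bootstrap of all indirect effects.

    Clusters (families; unrelated controls are singleton clusters) are
    resampled with replacement to the original cluster count.  Each
    replicate is re-standardized and refit; replicates with a constant
    column or singular normal equations are dropped and counted as failed
    (> 5% failures warns, > 25% is an error).
    """
    if spec.n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    arr = _Arrays(data, spec)
    Z = _zscore_or_none(arr.X)
    if Z is None:
        raise ValueError("zero-variance column in the model frame")
    sol = _solve_system(Z, arr)
    if sol is None:
        raise ValueError("full-sample fit failed; check design for collinearity")
    point = _effects_vector(sol[0], sol[2], sol[3])

    rng = np.random.default_rng(spec.seed)
    members = arr.cluster_members
    nc = arr.n_clusters
    reps = np.empty((spec.n_boot, point.size))
    n_ok = 0
    n_failed = 0
    for _ in range(spec.n_boot):
        pick = rng.integers(0, nc, size=nc)
        idx = np.concatenate([members[c] for c in pick])
        Zb = _zscore_or_none(arr.X[idx])
        solb = _solve_system(Zb, arr) if Zb is not None else None
        if solb is None:
            n_failed += 1
            continue
        reps[n_ok] = _effects_vector(solb[0], solb[2], solb[3])
        n_ok += 1
    reps = reps[:n_ok]

    frac = n_failed / spec.n_boot
    if frac > 0.25:
        raise RuntimeError(
            f"{n_failed}/{spec.n_boot} bootstrap replicates failed to fit"
        )
    if frac > 0.05:
        warnings.warn(f"{n_failed}/{spec.n_boot} bootstrap replicates failed",
                      stacklevel=2)

    lower, upper = bc_interval(reps, point, spec.ci_level)
    idx = _effect_index(spec)
    table = idx.assign(
        estimate=point,
        se=reps.std(axis=0, ddof=1),
        lower=lower,
        upper=upper,
    )
    table["significant"] = (table["lower"] > 0) | (table["upper"] < 0)
    return BootstrapResult(
        table=table,
        n_boot=spec.n_boot,
        n_failed=n_failed,
        seed=spec.seed,
        replicates=reps if keep_replicates else None,
        effect_index=idx if keep_replicates else None,
    )
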