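"""Trial-level scoring of the five endophenotypes and the reading composite.

Scoring rules, in brief:

* temporal order judgment (rapid auditory processing, RAP): per-ISI accuracy
  is coded 1/2/3 against the sample 25th/75th percentiles; the subject score
  is the mean of the five ISI codes.
* rapid naming (RAN): mean vocal RT over correct trials, RTs > 1000 ms
  excluded as outliers, then z-normalized within the sample.
* cued detection (warning effect, WE): RTs outside [150, 1500] ms excluded;
  per SOA a composite of the four modality x validity cell means; WE is the
  250 ms SOA composite minus the 100 ms SOA composite.
* motion illusion (RTLI): per-subject logistic psychometric fit
  y = 1 / (1 + exp(-b (x - t))) with bounds 0 and 1, returning the slope b
  and 50% threshold t; b is log-transformed and t square-root-transformed
  before modelling.
* reading: mean of the available z-scored reading measures (error counts
  sign-flipped so that higher always means better).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markers import MEDIATORS
from .synthetic import READING_MEASURES

log = logging.getLogger(__name__)

RAN_OUTLIER_MS = 1000.0
ATT_MIN_MS, ATT_MAX_MS = 150.0, 1500.0


def score_rap(trials: pd.DataFrame) -> pd.Series:
    """Percentile-coded temporal order judgment score (1..3 per ISI, averaged).

    ``trials`` columns: subject_id, isi_ms, correct.  Percentiles are
    computed per ISI over the whole sample (linear interpolation between
    order statistics).  Rule order: accuracy <= P25 codes 1, else >= P75
    codes 3, else 2 — so a degenerate distribution (P25 == P75) codes
    everyone 1, with a warning.
    """
    acc = (
        trials.groupby(["subject_id", "isi_ms"])["correct"].mean().mul(100.0)
        .unstack("isi_ms")
    )
    if acc.shape[0] < 4:
        raise ValueError("need at least 4 subjects to define sample percentiles")
    codes = pd.DataFrame(index=acc.index, columns=acc.columns, dtype=float)
    for isi in acc.columns:
        col = acc[isi].to_numpy(dtype=float)
        p25, p75 = np.percentile(col[~np.isnan(col)], [25, 75])
        if p25 == p75:
            warnings.warn(
                f"degenerate accuracy distribution at ISI {isi} ms (P25 == P75); "
                "all subjects coded 1 by rule order", stacklevel=2,
            )
        codes[isi] = np.select([col <= p25, col >= p75], [1.0, 3.0], 2.0)
        codes.loc[acc[isi].isna(), isi] = np.nan
    return codes.mean(axis=1).rename("RAP")


def score_ran(trials: pd.DataFrame, normalize: bool = True) -> pd.Series:
    """Mean correct-naming RT with the 1000 ms outlier rule, z-scored in-sample.

    ``trials`` columns: subject_id, rt_ms, correct.  Subjects with no usable
    trial get a missing score (logged).
    """
    usable = trials[(trials["correct"] == 1) & (trials["rt_ms"] <= RAN_OUTLIER_MS)]
    mean_rt = usable.groupby("subject_id")["rt_ms"].mean()
    all_subj = pd.Index(trials["subject_id"].unique(), name="subject_id")
    mean_rt = mean_rt.reindex(all_subj)
    n_missing = int(mean_rt.isna().sum())
    if n_missing:
        log.warning("RAN: %d subject(s) with no usable trials -> missing", n_missing)
    if not normalize:
        return mean_rt.rename("RAN_rt")
    return ((mean_rt - mean_rt.mean()) / mean_rt.std(ddof=1)).rename("RAN_rt")


def score_attention_we(trials: pd.DataFrame) -> pd.Series:
    """Multisensory warning effect: SOA-250 composite minus SOA-100 composite.

    ``trials`` columns: subject_id, modality, soa_ms, validity, rt_ms,
    responded.  Catch trials and RTs outside [150, 1500] ms are excluded;
    the per-SOA composite is the mean of the four modality x validity cell
    means.  Any empty cell yields a missing WE (logged).
    """
    resp = trials[
        (trials["validity"].isin(("valid", "invalid")))
        & (trials["responded"] == 1)
        & (trials["rt_ms"] >= ATT_MIN_MS)
        & (trials["rt_ms"] <= ATT_MAX_MS)
    ]
    cells = resp.groupby(["subject_id", "soa_ms", "modality", "validity"])["rt_ms"].mean()
    # per subject and SOA: require all 4 cells
    comp = cells.groupby(["subject_id", "soa_ms"]).agg(["mean", "size"])
    comp.loc[comp["size"] < 4, "mean"] = np.nan
    wide = comp["mean"].unstack("soa_ms")
    all_subj = pd.Index(trials["subject_id"].unique(), name="subject_id")
    wide = wide.reindex(all_subj)
    we = (wide.get(250) - wide.get(100)).rename("WE")
    n_missing = int(we.isna().sum())
    if n_missing:
        log.warning("WE: %d subject(s) with empty cells after filtering -> missing",
                    n_missing)
    return we


@dataclass
class PsychometricFit:
    """Logistic psychometric fit: slope ``b`` (> 0) and 50% threshold ``t``."""

    b: float
    t: float
    converged: bool
    rss: float

    def predict(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.b * (np.asarray(x, float) - self.t)))


_B_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
_T_GRID = tuple(np.arange(0.0, 10.5, 1.0))


def fit_rtli(contrast, proportion) -> PsychometricFit:
    """Least-squares logistic fit of perceived-rotation proportions.

    Minimizes the sum of squared deviations between observed proportions and
    1/(1+exp(-b(x-t))) over b > 0 and t, with multi-start over a coarse
    (b, t) grid.  All-zero or all-one (or otherwise flat) response curves
    are flagged as non-converged with missing parameters.
    """
    x = np.asarray(contrast, dtype=float)
    y = np.asarray(proportion, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if np.unique(x).size < 2 or np.ptp(y) < 1e-9:
        return PsychometricFit(np.nan, np.nan, False, np.nan)

    def resid(theta):
        b, t = theta
        return 1.0 / (1.0 + np.exp(-b * (x - t))) - y

    # grid pre-screen, then local refinement from the best few starts
    bb, tt = np.meshgrid(_B_GRID, _T_GRID, indexing="ij")
    pred = 1.0 / (1.0 + np.exp(-bb[..., None] * (x - tt[..., None])))
    grid_rss = ((pred - y) ** 2).sum(axis=-1)
    order = np.argsort(grid_rss, axis=None)[:3]
    best = None
    for flat in order:
        i, j = np.unravel_index(flat, grid_rss.shape)
        sol = optimize.least_squares(
            resid, x0=(bb[i, j], tt[i, j]), bounds=((1e-8, -20.0), (np.inf, 40.0)),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    rss, sol = best
    b, t = sol.x
    return PsychometricFit(float(b), float(t), bool(sol.success), rss)


def fit_rtli_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-subject psychometric fits from a tidy response table.

    ``responses`` columns: subject_id, contrast_pct, n_presentations,
    n_perceived.
    """
    out = []
    for subj, grp in responses.groupby("subject_id"):
        fit = fit_rtli(grp["contrast_pct"], grp["n_perceived"] / grp["n_presentations"])
        out.append(dict(subject_id=subj, RTLI_b=fit.b, RTLI_t=fit.t,
                        converged=fit.converged, rss=fit.rss))
    return pd.DataFrame(out).set_index("subject_id")


def transform_eps(table: pd.DataFrame) -> pd.DataFrame:
    """Normality transforms: RTLI_b -> ln(RTLI_b), RTLI_t -> sqrt(RTLI_t).

    Non-positive slopes and negative thresholds become missing (logged).
    Other columns pass through; the returned frame carries a
    ``transforms`` attribute recording what was applied.
    """
    out = table.copy()
    if "RTLI_b" in out:
        bad = out["RTLI_b"] <= 0
        if bad.any():
            log.warning("transform: %d non-positive RTLI_b value(s) -> missing",
                        int(bad.sum()))
        out["RTLI_b"] = np.log(out["RTLI_b"].where(~bad))
    if "RTLI_t" in out:
        bad = out["RTLI_t"] < 0
        if bad.any():
            log.warning("transform: %d negative RTLI_t value(s) -> missing",
                        int(bad.sum()))
        out["RTLI_t"] = np.sqrt(out["RTLI_t"].where(~bad))
    out.attrs["transforms"] = {"RTLI_b": "log", "RTLI_t": "sqrt"}
    return out


def reading_composite(measures: pd.DataFrame,
                      directions: dict[str, int] | None = None) -> pd.Series:
    """Mean of available z-scored reading measures (higher = better).

    ``directions`` maps measure column -> +1 (higher better) or -1 (error or
    time counts, sign-flipped before averaging); defaults to the standard
    speed/error panel.  Subjects with no measure at all get a missing
    composite.
    """
    if directions is None:
        directions = {name: d for name, d in READING_MEASURES if name in measures}
    if not directions:
        raise ValueError("no reading measure columns found")
    zcols = {}
    for name, d in directions.items():
        col = measures[name]
        zcols[name] = d * (col - col.mean()) / col.std(ddof=1)
    z = pd.DataFrame(zcols)
    comp = z.mean(axis=1).rename("reading")
    comp.attrs["n_measures"] = z.notna().sum(axis=1)
    return comp


def score_all(trials: dict[str, pd.DataFrame], ages: pd.Series | None = None
              ) -> pd.DataFrame:
    """Run the full scoring pipeline over a dict of raw task tables.

    Returns one row per subject with the transformed endophenotypes
    (WE, RTLI_b, RTLI_t, RAP, RAN_rt), the reading composite, and age if
    provided.
    """
    rtli = fit_rtli_table(trials["rtli"])
    table = pd.concat(
        [
            score_attention_we(trials["attention"]),
            rtli[["RTLI_b", "RTLI_t"]],
            score_rap(trials["rap"]),
            score_ran(trials["ran"]),
        ],
        axis=1,
    )
    table = transform_eps(table)[list(MEDIATORS)]
    reading = reading_composite(trials["reading"].set_index("subject_id"))
    table = table.join(reading)
    if ages is not None:
        table = table.join(ages.rename("age"))
    return table


def correlation_screen(
    predictors: pd.DataFrame,
    endophenotypes: pd.DataFrame,
    outcome: pd.Series,
) -> pd.DataFrame:
    """Two-tailed bivariate Pearson screen, pairwise-complete observations.

    Returns a tidy table with one row per (predictor or endophenotype,
    variable) pair: r, two-tailed p, and the pair count — mirroring the
    usual marker x trait correlation table layout.
    """
    eps = endophenotypes.copy()
    eps[outcome.name or "outcome"] = outcome
    rows = []
    for xname, xcol in predictors.items():
        for yname, ycol in eps.items():
            rows.append(_pearson_row("marker", xname, yname, xcol, ycol))
    for ep in endophenotypes.columns:
        rows.append(_pearson_row("endophenotype", ep, outcome.name or "outcome",
                                 endophenotypes[ep], outcome))
    return pd.DataFrame(rows)


def _pearson_row(kind, xname, yname, x, y):
    pair = pd.concat([x, y], axis=1).dropna()
    n = len(pair)
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs for ({xname}, {yname})")
    a, b = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(a, b)
    return dict(kind=kind, x=xname, y=yname, r=float(r), p=float(p), n=n)
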