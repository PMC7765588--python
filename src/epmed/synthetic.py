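"""Family-structured synthetic cohorts with known ground-truth parameters.

The generator emulates the statistical structure of a nuclear-family
candidate-gene study of reading ability: probands with 1-2 siblings plus
unrelated control readers, 20 biallelic markers drawn under Hardy-Weinberg
equilibrium with Mendelian transmission inside families, five correlated
endophenotype mediators with age effects, and a continuous reading outcome
driven by standardized direct (gene -> reading) and indirect
(gene -> mediator -> reading) paths.  All structural variables are generated
on the standardized (unit-variance) scale, so the configured path
coefficients are the true standardized effects that the path model should
recover.

Optionally, raw trial-level task tables (temporal-order judgment, rapid
naming, cued detection, motion-illusion psychometric responses, reading
measures) are emitted such that the scoring module recovers the latent
mediator values up to sampling noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import genetics
from .genetics import GenotypeMatrix
from .markers import DEFAULT_VARIANTS, MEDIATORS, VariantInfo

ISIS_MS = (20, 40, 80, 120, 280)
SOAS_MS = (100, 250)
CONTRASTS_PCT = tuple(range(11))  # 0..10% in 1% steps
READING_MEASURES = (
    ("text_speed", +1), ("text_errors", -1),
    ("word_speed", +1), ("word_errors", -1),
    ("pseudoword_speed", +1), ("pseudoword_errors", -1),
)


class ConfigError(ValueError):
    """Raised when a cohort configuration implies an infeasible model."""


def _default_A() -> np.ndarray:
    A = np.zeros((5, 20))
    k = list(v.marker for v in DEFAULT_VARIANTS).index("rs9853895")
    A[MEDIATORS.index("RAP"), k] = -0.188
    A[MEDIATORS.index("RTLI_b"), k] = -0.249
    return A


def _default_B() -> np.ndarray:
    B = np.zeros(5)
    B[MEDIATORS.index("RAP")] = 0.298
    B[MEDIATORS.index("RTLI_b")] = 0.249
    return B


def _default_Cp() -> np.ndarray:
    Cp = np.zeros(20)
    Cp[list(v.marker for v in DEFAULT_VARIANTS).index("rs9853895")] = -0.111
    return Cp


def _default_age_paths() -> np.ndarray:
    ap = np.zeros(5)
    ap[MEDIATORS.index("RTLI_b")] = 0.25
    ap[MEDIATORS.index("RAP")] = 0.25
    ap[MEDIATORS.index("RAN_rt")] = -0.25
    return ap


def _default_resid_corr() -> np.ndarray:
    # Residual correlations on the five pairs controlled in the path model,
    # signed by trait polarity (sign of each trait's association with reading).
    C = np.eye(5)
    sign = dict(WE=-1, RTLI_b=+1, RTLI_t=-1, RAP=+1, RAN_rt=-1)
    pairs = (("WE", "RTLI_b"), ("RAP", "RTLI_b"), ("RAP", "RTLI_t"),
             ("RAP", "RAN_rt"), ("RTLI_b", "RTLI_t"))
    for a, b in pairs:
        i, j = MEDIATORS.index(a), MEDIATORS.index(b)
        C[i, j] = C[j, i] = 0.2 * sign[a] * sign[b]
    return C


@dataclass
class CohortConfig:
    """Ground-truth generating model for a synthetic cohort.

    Path matrices are in standardized units: ``A`` (5 mediators x 20
    markers) holds gene->mediator paths, ``B`` mediator->reading paths,
    ``Cp`` direct gene->reading paths and ``age_paths`` age->mediator paths.
    ``family_icc`` is the proportion of mediator/outcome residual variance
    shared within a family.
    """

    n_families: int = 99
    sibs_per_family: int | tuple[int, int] = (1, 2)
    n_controls: int = 79
    variants: tuple[VariantInfo, ...] = DEFAULT_VARIANTS
    A: np.ndarray = field(default_factory=_default_A)
    B: np.ndarray = field(default_factory=_default_B)
    Cp: np.ndarray = field(default_factory=_default_Cp)
    age_paths: np.ndarray = field(default_factory=_default_age_paths)
    mediator_residual_corr: np.ndarray = field(default_factory=_default_resid_corr)
    family_icc: float = 0.2
    age_range: tuple[float, float] = (7.0, 14.0)
    maf_threshold: float = 0.35
    seed: int = 0
    emit_trials: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        self.age_paths = np.asarray(self.age_paths, dtype=float)
        self.mediator_residual_corr = np.asarray(self.mediator_residual_corr, float)
        m = len(self.variants)
        if self.A.shape != (5, m) or self.B.shape != (5,) or self.Cp.shape != (m,):
            raise ConfigError("path matrix shapes must be A: 5 x markers, B: 5, Cp: markers")
        for v in self.variants:
            if not 0.0 < v.maf <= 0.5:
                raise ConfigError(f"marker {v.marker}: MAF must be in (0, 0.5]")
        C = self.mediator_residual_corr
        if C.shape != (5, 5) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ConfigError("mediator_residual_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigError("mediator_residual_corr is not positive semi-definite")
        if not 0.0 <= self.family_icc < 1.0:
            raise ConfigError("family_icc must be in [0, 1)")
        # variance budgets (validated at construction)
        self.mediator_residual_var()
        self.outcome_residual_var()

    @property
    def markers(self) -> list[str]:
        return [v.marker for v in self.variants]

    def coding_model(self) -> dict[str, str]:
        return {
            v.marker: "additive3" if v.maf >= self.maf_threshold else "dominant2"
            for v in self.variants
        }

    def mediator_residual_var(self) -> np.ndarray:
        vr = 1.0 - (self.A**2).sum(axis=1) - self.age_paths**2
        for j, v in enumerate(vr):
            if v <= 0:
                raise ConfigError(
                    f"mediator equation {MEDIATORS[j]}: paths imply residual "
                    f"variance {v:.4f} <= 0"
                )
        return vr

    def mediator_corr(self) -> np.ndarray:
        """Implied correlation matrix of the (unit-variance) mediators."""
        vr = self.mediator_residual_var()
        D = np.sqrt(np.outer(vr, vr))
        R = (self.A @ self.A.T + np.outer(self.age_paths, self.age_paths)
             + D * self.mediator_residual_corr)
        return R

    def outcome_residual_var(self) -> float:
        R = self.mediator_corr()
        var_sys = (
            float(self.Cp @ self.Cp)
            + float(self.B @ R @ self.B)
            + 2.0 * float(self.B @ self.A @ self.Cp)
        )
        vy = 1.0 - var_sys
        if vy <= 0:
            raise ConfigError(
                f"outcome equation: paths imply residual variance {vy:.4f} <= 0"
            )
        return vy

    def to_json(self) -> str:
        d = dict(
            n_families=self.n_families,
            sibs_per_family=list(np.atleast_1d(self.sibs_per_family).tolist()),
            n_controls=self.n_controls,
            markers=self.markers,
            maf=[v.maf for v in self.variants],
            coding_model=self.coding_model(),
            A=self.A.tolist(), B=self.B.tolist(), Cp=self.Cp.tolist(),
            age_paths=self.age_paths.tolist(),
            mediator_residual_corr=self.mediator_residual_corr.tolist(),
            family_icc=self.family_icc, age_range=list(self.age_range),
            seed=self.seed, emit_trials=self.emit_trials,
        )
        return json.dumps(d, indent=2)


def default_config(**overrides) -> CohortConfig:
    """Study-scale configuration with the published headline path effects."""
    return CohortConfig(**overrides)


def null_config(**overrides) -> CohortConfig:
    """All structural paths zero (age and residual structure retained)."""
    base = dict(A=np.zeros((5, 20)), B=np.zeros(5), Cp=np.zeros(20))
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class Cohort:
    """A generated cohort: subjects, genotypes, latent mediators, outcome."""

    subjects: pd.DataFrame  # subject_id, family_id, role, age
    genotypes: GenotypeMatrix
    mediators: pd.DataFrame  # latent true values, unit variance scale
    reading: pd.Series
    config: CohortConfig
    trials: dict[str, pd.DataFrame] | None = None

    @property
    def n(self) -> int:
        return len(self.subjects)

    def unrelated_mask(self) -> pd.Series:
        """Probands + controls: the subset used for MAF/HWE computations."""
        return self.subjects["role"].isin(("proband", "control")).set_axis(
            self.subjects["subject_id"]
        )


def _coded_moments(v: VariantInfo, model: str) -> tuple[float, float]:
    q = v.maf
    if model == "additive3":
        return 2 * q, np.sqrt(2 * q * (1 - q))
    p1 = 1.0 - (1.0 - q) ** 2
    return p1, np.sqrt(p1 * (1 - p1))


def generate(config: CohortConfig) -> Cohort:
    """Generate a cohort from the configured ground-truth model.

    Sibling genotypes are produced by explicit parental simulation: two
    parental genotypes per family are drawn from HWE proportions and
    transmitted Mendelianly, so within-family genotype correlation is
    genetically real.  Controls are independent HWE draws in singleton
    families.
    """
    rng = np.random.default_rng(config.seed)
    F, nc = config.n_families, config.n_controls
    q = np.array([v.maf for v in config.variants])
    M = len(q)

    sibs = config.sibs_per_family
    if isinstance(sibs, tuple):
        extra = rng.integers(sibs[0], sibs[1] + 1, size=F)
    else:
        extra = np.full(F, int(sibs))
    fam_sizes = 1 + extra
    n_child = int(fam_sizes.sum())
    n = n_child + nc

    # --- subjects ---------------------------------------------------------
    child_fam = np.repeat(np.arange(F), fam_sizes)
    fam_ids = [f"F{i + 1:04d}" for i in range(F)]
    ctl_fam_ids = [f"C{i + 1:04d}" for i in range(nc)]
    first_child = np.r_[0, np.cumsum(fam_sizes)[:-1]]
    roles = np.array(["sibling"] * n_child, dtype=object)
    roles[first_child] = "proband"
    subjects = pd.DataFrame(
        dict(
            subject_id=[f"S{i + 1:05d}" for i in range(n)],
            family_id=[fam_ids[f] for f in child_fam] + ctl_fam_ids,
            role=list(roles) + ["control"] * nc,
        )
    )
    lo, hi = config.age_range
    subjects["age"] = rng.uniform(lo, hi, size=n)

    # --- genotypes --------------------------------------------------------
    parental = (rng.random((F, 2, 2, M)) < q).astype(np.int8)  # fam, parent, allele
    pick = rng.integers(0, 2, size=(2, n_child, M))
    pat = np.take_along_axis(parental[child_fam, 0], pick[0][:, None, :], axis=1)[:, 0, :]
    mat = np.take_along_axis(parental[child_fam, 1], pick[1][:, None, :], axis=1)[:, 0, :]
    child_dos = (pat + mat).astype(float)
    ctl_dos = rng.binomial(2, q, size=(nc, M)).astype(float)
    dosage = pd.DataFrame(
        np.vstack([child_dos, ctl_dos]),
        index=pd.Index(subjects["subject_id"], name="subject_id"),
        columns=config.markers,
    )
    genotypes = GenotypeMatrix(dosage, list(config.variants))

    # --- structural equations --------------------------------------------
    coding = config.coding_model()
    Gz = np.empty((n, M))
    for k, v in enumerate(config.variants):
        model = coding[v.marker]
        x = dosage[v.marker].to_numpy()
        if model == "dominant2":
            x = (x > 0).astype(float)
        mu, sd = _coded_moments(v, model)
        Gz[:, k] = (x - mu) / sd

    age_z = (subjects["age"].to_numpy() - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))

    vr = config.mediator_residual_var()
    vy = config.outcome_residual_var()
    icc = config.family_icc
    C = config.mediator_residual_corr
    L = np.linalg.cholesky(C + 1e-12 * np.eye(5))
    n_clusters = F + nc
    u_fam = rng.standard_normal((n_clusters, 5)) @ L.T
    u_fam_y = rng.standard_normal(n_clusters)
    eps = rng.standard_normal((n, 5)) @ L.T
    eps_y = rng.standard_normal(n)
    cluster_of = np.r_[child_fam, F + np.arange(nc)]

    resid = np.sqrt(icc) * u_fam[cluster_of] + np.sqrt(1 - icc) * eps
    med = Gz @ config.A.T + np.outer(age_z, config.age_paths) + np.sqrt(vr) * resid
    mediators = pd.DataFrame(med, index=dosage.index, columns=list(MEDIATORS))

    resid_y = np.sqrt(icc) * u_fam_y[cluster_of] + np.sqrt(1 - icc) * eps_y
    reading = pd.Series(
        Gz @ config.Cp + med @ config.B + np.sqrt(vy) * resid_y,
        index=dosage.index, name="reading",
    )

    cohort = Cohort(subjects, genotypes, mediators, reading, config)
    if config.emit_trials:
        cohort.trials = emit_trial_data(cohort, config)
    return cohort


def cohort_frame(cohort: Cohort, coded: genetics.CodedGenotypes | None = None) -> pd.DataFrame:
    """Assemble the analysis table: family, age, coded markers, mediators, reading.

    Marker coding runs through the genetics pipeline (MAF on the unrelated
    subset, 35% rule), exactly as it would for real data.
    """
    if coded is None:
        unrel = cohort.subjects.set_index("subject_id")["role"].isin(
            ("proband", "control")
        )
        coded = genetics.code_genotypes(cohort.genotypes, unrelated=unrel)
    df = cohort.subjects.set_index("subject_id")[["family_id", "age"]].copy()
    df = df.join(coded.values).join(cohort.mediators).join(cohort.reading)
    return df


# ---------------------------------------------------------------------------
# trial-level emission
# ---------------------------------------------------------------------------

RAP_ISI_DIFFICULTY = (-1.2, -0.6, 0.0, 0.6, 1.4)  # probit scale, easier at long ISI
RAP_SKILL_SLOPE = 0.8
RAN_MEAN_MS, RAN_SUBJECT_SD_MS, RAN_TRIAL_SD_MS = 450.0, 60.0, 80.0
ATT_BASE_MS, ATT_VALIDITY_MS, ATT_TRIAL_SD_MS = 420.0, 10.0, 60.0
WE_MEAN_MS, WE_SD_MS = -20.0, 15.0
RTLI_LOGB_MEAN, RTLI_LOGB_SD = 0.45, 0.35
RTLI_SQRT_T_MEAN, RTLI_SQRT_T_SD = 2.0, 0.35
READING_LOADING = np.sqrt(0.548)  # pairwise r between measures = loading^2


def emit_trial_data(
    cohort: Cohort,
    config: CohortConfig | None = None,
    trial_multiplier: int = 1,
    noiseless_rtli: bool = False,
) -> dict[str, pd.DataFrame] | None:
    """Emit raw task tables consistent with the cohort's latent mediators.

    Applying the scoring module to these tables recovers the latent
    mediator values up to sampling noise.  ``trial_multiplier`` scales all
    per-condition trial counts (for round-trip precision studies);
    ``noiseless_rtli`` replaces binomial illusion responses with expected
    per-level counts so the psychometric fit inverts the logistic exactly.
    """
    config = config or cohort.config
    if not config.emit_trials:
        warnings.warn("emit_trials is disabled in the configuration; no tables emitted",
                      stacklevel=2)
        return None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    sid = cohort.subjects["subject_id"].to_numpy()
    n = len(sid)
    z = {m: cohort.mediators[m].to_numpy() for m in MEDIATORS}
    mult = int(trial_multiplier)

    # temporal order judgment: 8 trials x 5 ISIs, two-alternative (chance 50%)
    rows = []
    n_trials = 8 * mult
    for isi, diff in zip(ISIS_MS, RAP_ISI_DIFFICULTY):
        p = 0.5 + 0.5 * ndtr(diff + RAP_SKILL_SLOPE * z["RAP"])
        correct = rng.random((n, n_trials)) < p[:, None]
        rows.append(
            pd.DataFrame(
                dict(
                    subject_id=np.repeat(sid, n_trials),
                    isi_ms=isi,
                    trial=np.tile(np.arange(1, n_trials + 1), n),
                    correct=correct.ravel().astype(int),
                )
            )
        )
    rap = pd.concat(rows, ignore_index=True)

    # rapid naming: 32 vocal RTs, ~3% naming errors
    n_trials = 32 * mult
    rt_mean = RAN_MEAN_MS + RAN_SUBJECT_SD_MS * z["RAN_rt"]
    rts = rng.normal(rt_mean[:, None], RAN_TRIAL_SD_MS, size=(n, n_trials))
    ran = pd.DataFrame(
        dict(
            subject_id=np.repeat(sid, n_trials),
            trial=np.tile(np.arange(1, n_trials + 1), n),
            rt_ms=np.clip(rts, 1.0, None).ravel(),
            correct=(rng.random((n, n_trials)) < 0.97).ravel().astype(int),
        )
    )

    # cued detection: per modality 32 valid + 32 invalid (16 per SOA) + 16 catch
    we_ms = WE_MEAN_MS + WE_SD_MS * z["WE"]
    base = ATT_BASE_MS + rng.normal(0.0, 25.0, size=n)
    att_rows = []
    for modality in ("visual", "auditory"):
        for soa in SOAS_MS:
            for validity, vadj in (("valid", -ATT_VALIDITY_MS), ("invalid", ATT_VALIDITY_MS)):
                k = 16 * mult
                mean_rt = base + vadj + (we_ms if soa == 250 else 0.0)
                rts = rng.normal(mean_rt[:, None], ATT_TRIAL_SD_MS, size=(n, k))
                att_rows.append(
                    pd.DataFrame(
                        dict(
                            subject_id=np.repeat(sid, k),
                            modality=modality,
                            block=np.tile(np.r_[np.ones(k // 2, int), np.full(k - k // 2, 2)], n),
                            soa_ms=soa,
                            validity=validity,
                            rt_ms=np.clip(rts, 1.0, None).ravel(),
                            responded=1,
                        )
                    )
                )
        k = 16 * mult  # catch trials: no target, no RT
        att_rows.append(
            pd.DataFrame(
                dict(
                    subject_id=np.repeat(sid, k),
                    modality=modality,
                    block=np.tile(np.r_[np.ones(k // 2, int), np.full(k - k // 2, 2)], n),
                    soa_ms=np.tile(np.repeat(SOAS_MS, k // 2), n),
                    validity="catch",
                    rt_ms=np.nan,
                    responded=0,
                )
            )
        )
    attention = pd.concat(att_rows, ignore_index=True)

    # motion illusion: 5 presentations per contrast level, logistic in contrast
    b = np.exp(RTLI_LOGB_MEAN + RTLI_LOGB_SD * z["RTLI_b"])
    t = (RTLI_SQRT_T_MEAN + RTLI_SQRT_T_SD * z["RTLI_t"]) ** 2
    n_pres = 5 * mult
    rtli_rows = []
    for x in CONTRASTS_PCT:
        y = 1.0 / (1.0 + np.exp(-b * (x - t)))
        perceived = (n_pres * y) if noiseless_rtli else rng.binomial(n_pres, y)
        rtli_rows.append(
            pd.DataFrame(
                dict(subject_id=sid, contrast_pct=float(x),
                     n_presentations=n_pres, n_perceived=perceived)
            )
        )
    rtli = pd.concat(rtli_rows, ignore_index=True)

    # reading measures: six indicators of the latent composite, r = loading^2
    lam = READING_LOADING
    zread = cohort.reading.to_numpy()
    read_cols = {"subject_id": sid}
    for name, direction in READING_MEASURES:
        noise = rng.standard_normal(n)
        read_cols[name] = direction * lam * zread + np.sqrt(1 - lam**2) * noise
    reading_measures = pd.DataFrame(read_cols)

    return dict(rap=rap, ran=ran, attention=attention, rtli=rtli,
                reading=reading_measures)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort to disk: CSV tables, minimal VCF, ground-truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    genetics.write_genotypes_csv(cohort.genotypes, out / "genotypes.csv")
    genetics.write_variants_csv(cohort.genotypes.variants, out / "variants.csv")
    genetics.write_genotypes_vcf(cohort.genotypes, out / "genotypes.vcf")
    cohort.mediators.to_csv(out / "mediators.csv", index_label="subject_id")
    cohort.reading.to_frame().to_csv(out / "reading.csv", index_label="subject_id")
    (out / "truth.json").write_text(cohort.config.to_json())
    if cohort.trials is not None:
        for name, df in cohort.trials.items():
            df.to_csv(out / f"trials_{name}.csv", index=False)
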