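"""Path model estimation, effect decomposition and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest

import epmed
from epmed.pathmodel import ModelSpec, bc_interval, standardize, unstandardize


def _chain_frame(n=200, seed=0, noise=0.0):
    """Single predictor -> single mediator -> outcome frame."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = x + noise * rng.standard_normal(n)
    y = m.copy()
    return pd.DataFrame(dict(
        x=x, M=m, reading=y, age=rng.uniform(7, 14, n),
        family_id=[f"f{i}" for i in range(n)],
    ))


CHAIN_SPEC = dict(predictors=["x"], mediators=("M",), covariate_edges=(),
                  residual_corr_pairs=())


class TestStandardize:
    def test_unit_moments_and_inverse(self):
        df = pd.DataFrame(dict(a=[1.0, 2.0, 3.0], b=[5.0, 5.5, 9.0]))
        z, scales = standardize(df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)
        z2, _ = standardize(z)
        pd.testing.assert_frame_equal(z, z2)  # idempotent
        back = unstandardize(z, scales)
        assert np.allclose(back, df, atol=1e-12)

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame(dict(flat=[1.0, 1.0, 1.0])))


class TestFit:
    def test_deterministic_chain(self):
        # exact chain is collinear (M == x); an infinitesimal perturbation
        # makes the decomposition identifiable: a = 1, b = 1, c' = 0
        frame = _chain_frame(noise=1e-4)
        est = epmed.fit_path_model(frame, ModelSpec(**CHAIN_SPEC))
        assert est.a.loc["M", "x"] == pytest.approx(1.0, abs=1e-3)
        assert est.b["M"] == pytest.approx(1.0, abs=1e-3)
        assert est.c_prime["x"] == pytest.approx(0.0, abs=1e-3)
        assert est.r2_outcome == pytest.approx(1.0, abs=1e-6)

    def test_subject_order_invariance(self, frame, spec, estimates):
        shuffled = frame.sample(frac=1.0, random_state=1)
        est2 = epmed.fit_path_model(shuffled, spec)
        assert np.allclose(estimates.a, est2.a, atol=1e-10)
        assert np.allclose(estimates.b, est2.b, atol=1e-10)
        assert np.allclose(estimates.c_prime, est2.c_prime, atol=1e-10)

    def test_parameter_recovery_at_large_n(self):
        cfg = epmed.default_config(n_families=1500, n_controls=1200, seed=7)
        coh = epmed.generate(cfg)
        est = epmed.fit_path_model(
            epmed.cohort_frame(coh),
            ModelSpec(predictors=list(coh.genotypes.markers)),
        )
        assert est.a.loc["RAP", "rs9853895"] == pytest.approx(-0.188, abs=0.03)
        assert est.a.loc["RTLI_b", "rs9853895"] == pytest.approx(-0.249, abs=0.03)
        assert est.b["RAP"] == pytest.approx(0.298, abs=0.03)
        assert est.c_prime["rs9853895"] == pytest.approx(-0.111, abs=0.03)

    def test_collinear_predictors_reported(self):
        frame = _chain_frame(noise=0.5)
        frame["x2"] = frame["x"]
        spec = ModelSpec(predictors=["x", "x2"], mediators=("M",),
                         covariate_edges=(), residual_corr_pairs=())
        with pytest.raises(ValueError, match="x"):
            epmed.fit_path_model(frame, spec)

    def test_matches_generic_least_squares(self, frame, spec, estimates):
        import statsmodels.api as sm

        cols = spec.predictors + [spec.covariate] + list(spec.mediators) \
            + [spec.outcome]
        z, _ = standardize(frame[cols])
        # mediator equation with an age edge
        fit = sm.OLS(z["RAP"], z[spec.predictors + ["age"]]).fit()
        assert np.allclose(estimates.a.loc["RAP"],
                           fit.params[spec.predictors], atol=1e-10)
        assert estimates.age_coefs["RAP"] == pytest.approx(fit.params["age"],
                                                           abs=1e-10)
        # outcome equation
        fity = sm.OLS(z["reading"], z[spec.predictors + list(spec.mediators)]).fit()
        assert np.allclose(estimates.c_prime, fity.params[spec.predictors],
                           atol=1e-10)
        assert np.allclose(estimates.b, fity.params[list(spec.mediators)],
                           atol=1e-10)


class TestIndirectEffects:
    def test_zero_b_gives_zero_indirect(self, estimates):
        est = estimates
        import copy

        est2 = copy.deepcopy(est)
        est2.b[:] = 0.0
        eff = epmed.indirect_effects(est2)
        assert np.allclose(eff.specific, 0.0)
        assert np.allclose(eff.total, 0.0)
        assert np.allclose(eff.total_effect, est.c_prime)

    def test_additivity_exact(self, estimates):
        eff = epmed.indirect_effects(estimates)
        assert np.allclose(eff.specific.sum(axis=1), eff.total, atol=1e-12)
        assert np.allclose(eff.total_effect, estimates.c_prime + eff.total,
                           atol=1e-12)


class TestClusterBootstrap:
    def test_symmetric_replicates_reduce_to_percentile(self):
        # point estimate at the replicate median -> z0 = 0 -> plain percentile
        reps = np.linspace(-1, 1, 1000)[:, None]  # no replicate equals 0 exactly
        point = np.array([0.0])
        lo, hi = bc_interval(reps, point, 0.95)
        assert lo[0] == pytest.approx(np.quantile(reps[:, 0], 0.025), abs=1e-9)
        assert hi[0] == pytest.approx(np.quantile(reps[:, 0], 0.975), abs=1e-9)

    def test_same_seed_identical_different_seed_close(self, frame):
        preds = [c for c in frame.columns if c.startswith("rs") or c == "READ1"]
        spec1 = ModelSpec(predictors=preds, n_boot=5000, seed=1)
        r1 = epmed.cluster_bootstrap(frame, spec1)
        r1b = epmed.cluster_bootstrap(frame, spec1)
        pd.testing.assert_frame_equal(r1.table, r1b.table)
        spec2 = ModelSpec(predictors=preds, n_boot=5000, seed=2)
        r2 = epmed.cluster_bootstrap(frame, spec2)
        sel = (r1.table.effect == "specific") & (r1.table.predictor == "rs9853895")
        for col in ("lower", "upper"):
            diff = (r1.table[sel][col].to_numpy() - r2.table[sel][col].to_numpy())
            assert np.abs(diff).max() < 0.005

    def test_significance_flag_matches_interval(self, frame, spec):
        res = epmed.cluster_bootstrap(frame, spec)
        t = res.table
        assert ((t.lower <= t.upper) | t.lower.isna()).all()
        assert (t.significant == ((t.lower > 0) | (t.upper < 0))).all()
        # the designed-in pathway should be detected at study scale
        assert res.n_failed == 0

    def test_bootstrap_se_shrinks_with_cluster_count(self):
        ses = []
        for fams, ctls, seed in ((40, 30, 5), (400, 300, 6)):
            coh = epmed.generate(epmed.default_config(
                n_families=fams, n_controls=ctls, seed=seed))
            res = epmed.cluster_bootstrap(
                epmed.cohort_frame(coh),
                ModelSpec(predictors=list(coh.genotypes.markers),
                          n_boot=400, seed=seed),
            )
            sel = ((res.table.effect == "specific")
                   & (res.table.predictor == "rs9853895")
                   & (res.table.mediator == "RAP"))
            ses.append(float(res.table[sel]["se"].iloc[0]))
        assert ses[1] < ses[0]

    def test_unresampleable_marker_fails_loudly(self):
        # marker present in a single cluster: most replicates lose it entirely
        rng = np.random.default_rng(0)
        n = 60
        frame = pd.DataFrame(dict(
            x=np.r_[1.0, np.zeros(n - 1)],
            M=rng.standard_normal(n),
            reading=rng.standard_normal(n),
            age=rng.uniform(7, 14, n),
            family_id=[f"f{i}" for i in range(n)],
        ))
        spec = ModelSpec(predictors=["x"], mediators=("M",), covariate_edges=(),
                         residual_corr_pairs=(), n_boot=200, seed=0)
        with pytest.raises(RuntimeError, match="failed"):
            epmed.cluster_bootstrap(frame, spec)

    def test_minimum_replicates_enforced(self, frame, spec):
        import dataclasses

        bad = dataclasses.replace(spec, n_boot=50)
        with pytest.raises(ValueError, match="n_boot"):
            epmed.cluster_bootstrap(frame, bad)
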