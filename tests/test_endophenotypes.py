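"""Scoring rules: percentile coding, outlier filters, psychometric fits."""

import numpy as np
import pandas as pd
import pytest

from epmed.endophenotypes import (
    correlation_screen,
    fit_rtli,
    reading_composite,
    score_attention_we,
    score_ran,
    score_rap,
    transform_eps,
)


def _rap_trials(acc_by_subject: dict[str, float], isis=(20, 40, 80, 120, 280),
                n_trials=8):
    """Accuracy identical across ISIs: fraction of correct trials per subject."""
    rows = []
    for subj, acc in acc_by_subject.items():
        k = int(round(acc * n_trials))
        for isi in isis:
            for t in range(n_trials):
                rows.append(dict(subject_id=subj, isi_ms=isi, correct=int(t < k)))
    return pd.DataFrame(rows)


class TestRap:
    def test_chance_subject_among_perfect_scores_one(self):
        trials = _rap_trials({"lo": 0.5, "a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        rap = score_rap(trials)
        assert rap["lo"] == 1.0

    def test_codes_match_declared_percentile_rule(self):
        accs = {f"s{i}": a / 100 for i, a in enumerate(range(10, 101, 10))}
        trials = _rap_trials(accs, n_trials=10)
        rap = score_rap(trials)
        # independent brute force with the same (linear interpolation) estimator
        vals = np.array(sorted(100 * a for a in accs.values()), dtype=float)
        p25, p75 = np.percentile(vals, [25, 75])
        expect = {s: (1.0 if 100 * a <= p25 else 3.0 if 100 * a >= p75 else 2.0)
                  for s, a in accs.items()}
        for s, e in expect.items():
            assert rap[s] == e
        assert rap["s0"] == 1.0 and rap["s9"] == 3.0

    def test_degenerate_distribution_codes_one_with_warning(self):
        trials = _rap_trials({s: 0.75 for s in "abcd"})
        with pytest.warns(UserWarning, match="degenerate"):
            rap = score_rap(trials)
        assert (rap == 1.0).all()

    def test_requires_four_subjects(self):
        with pytest.raises(ValueError):
            score_rap(_rap_trials({"a": 0.5, "b": 1.0}))


class TestRan:
    def test_mean_and_outlier_cutoff(self):
        trials = pd.DataFrame(
            dict(subject_id=["s"] * 3 + ["t"] * 2,
                 rt_ms=[400.0, 600.0, 1200.0, 500.0, 500.0],
                 correct=[1, 1, 1, 1, 1])
        )
        raw = score_ran(trials, normalize=False)
        assert raw["s"] == pytest.approx(500.0)  # 1200 ms excluded as outlier
        assert raw["t"] == pytest.approx(500.0)

    def test_boundary_rt_exactly_1000_is_kept(self):
        trials = pd.DataFrame(dict(subject_id=["s", "s"], rt_ms=[1000.0, 1000.0001],
                                   correct=[1, 1]))
        assert score_ran(trials, normalize=False)["s"] == pytest.approx(1000.0)

    def test_incorrect_trials_excluded_and_normalization(self):
        rng = np.random.default_rng(0)
        trials = pd.DataFrame(
            dict(subject_id=np.repeat([f"s{i}" for i in range(20)], 10),
                 rt_ms=rng.uniform(300, 700, 200),
                 correct=rng.integers(0, 2, 200))
        )
        z = score_ran(trials)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_subject_with_no_usable_trials_is_missing(self):
        trials = pd.DataFrame(dict(subject_id=["a", "a", "b", "b", "c"],
                                   rt_ms=[400, 500, 450, 550, 1500.0],
                                   correct=[1, 1, 1, 1, 1]))
        raw = score_ran(trials, normalize=False)
        assert np.isnan(raw["c"])


def _att_trials(cell_rts: dict, subject="s"):
    rows = []
    for (modality, soa, validity), rts in cell_rts.items():
        for rt in rts:
            rows.append(dict(subject_id=subject, modality=modality, soa_ms=soa,
                             validity=validity, rt_ms=rt, responded=1))
    rows.append(dict(subject_id=subject, modality="visual", soa_ms=100,
                     validity="catch", rt_ms=np.nan, responded=0))
    return pd.DataFrame(rows)


class TestWarningEffect:
    CELLS = [(m, s, v) for m in ("visual", "auditory") for s in (100, 250)
             for v in ("valid", "invalid")]

    def test_identical_rts_give_zero(self):
        trials = _att_trials({c: [400.0, 400.0] for c in self.CELLS})
        assert score_attention_we(trials)["s"] == pytest.approx(0.0)

    def test_composite_difference(self):
        cells = {c: ([400.0] if c[1] == 100 else [380.0]) for c in self.CELLS}
        assert score_attention_we(_att_trials(cells))["s"] == pytest.approx(-20.0)

    def test_rt_outlier_filters(self):
        # 100 ms (< 150 floor) and 1600 ms (> 1500 ceiling) are excluded;
        # boundary values 150 and 1500 are kept
        cells = {c: [400.0] for c in self.CELLS}
        cells[("visual", 100, "valid")] = [100.0, 400.0, 1600.0]
        trials = _att_trials(cells)
        assert score_attention_we(trials)["s"] == pytest.approx(0.0)
        cells[("visual", 100, "valid")] = [150.0, 1500.0]
        we = score_attention_we(_att_trials(cells))["s"]
        assert we == pytest.approx(400.0 - (825.0 + 3 * 400.0) / 4)

    def test_empty_cell_gives_missing(self):
        cells = {c: [400.0] for c in self.CELLS}
        cells[("auditory", 250, "invalid")] = [100.0]  # filtered away entirely
        assert np.isnan(score_attention_we(_att_trials(cells))["s"])


class TestRtliFit:
    def test_noiseless_inversion(self):
        x = np.arange(11.0)
        y = 1 / (1 + np.exp(-2.0 * (x - 5.0)))
        fit = fit_rtli(x, y)
        assert fit.converged
        assert fit.b == pytest.approx(2.0, abs=1e-6)
        assert fit.t == pytest.approx(5.0, abs=1e-6)
        assert fit.predict(fit.t) == pytest.approx(0.5, abs=1e-12)

    def test_flat_curve_flagged_nonconverged(self):
        fit = fit_rtli(np.arange(11.0), np.zeros(11))
        assert not fit.converged and np.isnan(fit.b) and np.isnan(fit.t)

    def test_binomial_recovery_monte_carlo(self):
        # 5 Bernoulli draws per level from (b=1.5, t=4): median fit near truth
        rng = np.random.default_rng(12)
        x = np.arange(11.0)
        y_true = 1 / (1 + np.exp(-1.5 * (x - 4.0)))
        bs, ts = [], []
        for _ in range(500):
            y_obs = rng.binomial(5, y_true) / 5
            fit = fit_rtli(x, y_obs)
            if fit.converged:
                bs.append(fit.b)
                ts.append(fit.t)
        assert abs(np.median(bs) - 1.5) < 0.15
        assert abs(np.median(ts) - 4.0) < 0.4


def test_transforms():
    tab = pd.DataFrame(dict(RTLI_b=[1.0, np.e, -0.5], RTLI_t=[4.0, 9.0, 1.0],
                            RAP=[1.0, 2.0, 3.0]))
    out = transform_eps(tab)
    assert out["RTLI_b"][0] == pytest.approx(0.0)
    assert out["RTLI_b"][1] == pytest.approx(1.0)
    assert np.isnan(out["RTLI_b"][2])  # non-positive slope -> missing
    assert out["RTLI_t"][0] == pytest.approx(2.0)
    assert list(out["RAP"]) == [1.0, 2.0, 3.0]  # pass-through
    # monotone: subject ordering preserved
    b = pd.Series([0.5, 1.0, 2.0, 4.0])
    tr = transform_eps(pd.DataFrame(dict(RTLI_b=b)))["RTLI_b"]
    assert (tr.diff().dropna() > 0).all()


class TestReadingComposite:
    def test_identical_measures_return_their_zscore(self):
        col = pd.Series([1.0, 2.0, 5.0, 8.0])
        measures = pd.DataFrame({m: col for m, _ in
                                 zip(("a", "b", "c"), [1, 1, 1])})
        comp = reading_composite(measures, directions=dict(a=1, b=1, c=1))
        z = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(comp, z)

    def test_opposed_measures_cancel(self):
        col = pd.Series([1.0, 2.0, 5.0, 8.0])
        measures = pd.DataFrame(dict(a=col, b=-col))
        comp = reading_composite(measures, directions=dict(a=1, b=1))
        assert np.allclose(comp, 0.0)

    def test_error_counts_sign_flip(self):
        col = pd.Series([1.0, 2.0, 5.0, 8.0])
        measures = pd.DataFrame(dict(speed=col, errors=col))
        comp = reading_composite(measures, directions=dict(speed=1, errors=-1))
        assert np.allclose(comp, 0.0)

    def test_emitted_measures_intercorrelation_matches_target(self):
        import epmed

        cfg = epmed.default_config(seed=17, emit_trials=True,
                                   n_families=600, n_controls=500)
        coh = epmed.generate(cfg)
        trials = epmed.emit_trial_data(coh, cfg)
        meas = trials["reading"].set_index("subject_id")
        aligned = meas * np.array([d for _, d in
                                   zip(meas.columns, [1, -1, 1, -1, 1, -1])])
        corr = aligned.corr().to_numpy()
        mean_r = corr[np.triu_indices_from(corr, 1)].mean()
        assert abs(mean_r - 0.548) < 0.05


class TestCorrelationScreen:
    def test_exact_cases(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], name="x")
        preds = pd.DataFrame(dict(g=x))
        eps = pd.DataFrame(dict(up=2 * x, down=-2 * x))
        out = correlation_screen(preds, eps, x.rename("reading"))
        tab = out.set_index(["x", "y"])["r"]
        assert tab[("g", "up")] == pytest.approx(1.0)
        assert tab[("g", "down")] == pytest.approx(-1.0)
        assert tab[("g", "reading")] == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.normal(size=5), name="a")
        b = pd.Series(rng.normal(size=5), name="b")
        out = correlation_screen(pd.DataFrame(dict(a=a)), pd.DataFrame(dict(b=b)),
                                 pd.Series(rng.normal(size=5), name="reading"))
        r = out.set_index(["x", "y"])["r"][("a", "b")]
        am, bm = a - a.mean(), b - b.mean()
        brute = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert r == pytest.approx(brute, abs=1e-12)
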