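import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecospace.class_ecology_coupling import (
    _gls_profile,
    cross_time_class_regression,
    fit_gls_era_model,
    stage_class_correlation_series,
)
from ecospace.data_model import EcospaceError, range_through
from ecospace.synthetic_data import simulate_correlation_series

from conftest import make_record


def proportional_stage_records(ts, stage="C"):
    """Three classes whose mode counts are exactly proportional to their
    genus counts (10 genera/2 modes, 20/4, 40/8) -> log-log r = 1."""
    records = []
    uid = 0
    for cls, (n_gen, n_modes) in {
        "Cl1": (10, 2), "Cl2": (20, 4), "Cl3": (40, 8)
    }.items():
        for i in range(n_gen):
            mode = (1 + (i % n_modes) // 6, 1 + (i % n_modes) % 6, 1)
            records.append(
                make_record(f"G{uid}", stage, stage, mode, ts, class_=cls)
            )
            uid += 1
    return records


class TestCorrelationSeries:
    def test_proportional_counts_give_perfect_correlation(self, five_stage_timescale):
        ts = five_stage_timescale
        occ = range_through(proportional_stage_records(ts), ts)
        with pytest.warns(UserWarning):  # other stages dropped
            series = stage_class_correlation_series(occ, ts)
        assert list(series["stage"]) == ["C"]
        assert series["r"].iloc[0] == pytest.approx(1.0)
        assert series["n_classes"].iloc[0] == 3

    def test_small_classes_and_sparse_stages_filtered(self, five_stage_timescale):
        ts = five_stage_timescale
        records = proportional_stage_records(ts)
        # a 9-genus class must not count towards the 3-class minimum
        records += [
            make_record(f"X{i}", "C", "C", (6, 6, 6), ts, class_="Tiny") for i in range(9)
        ]
        occ = range_through(records, ts)
        with pytest.warns(UserWarning):
            series = stage_class_correlation_series(occ, ts)
        assert series["n_classes"].iloc[0] == 3

        # dropping one qualifying class leaves 2 < min_classes -> stage excluded
        two_cls = [r for r in records if r.class_ != "Cl3"]
        occ = range_through(two_cls, ts)
        with pytest.warns(UserWarning):
            series = stage_class_correlation_series(occ, ts)
        assert series.empty

    def test_correlation_invariant_to_log_base(self, five_stage_timescale):
        ts = five_stage_timescale
        occ = range_through(proportional_stage_records(ts), ts)
        from ecospace.class_ecology_coupling import class_summary

        sub = class_summary(occ)
        sub = sub[(sub["stage"] == "C") & (sub["n_genera"] >= 10)]
        r_nat = np.corrcoef(np.log(sub["n_genera"]), np.log(sub["n_modes"]))[0, 1]
        r_10 = np.corrcoef(np.log10(sub["n_genera"]), np.log10(sub["n_modes"]))[0, 1]
        assert r_nat == pytest.approx(r_10)


class TestGLSCore:
    def test_independence_limit_recovers_group_means(self):
        t = np.array([500.0, 400.0, 300.0, 200.0, 100.0, 50.0])
        y = np.array([0.2, 0.3, 0.1, 0.8, 0.7, 0.9])
        X = np.column_stack([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]]).astype(float)
        _, beta, _, _ = _gls_profile(1e-3, t, X, y)
        assert beta == pytest.approx([0.2, 0.8])

    def test_loglik_matches_multivariate_normal_density(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 100, 12))[::-1].copy()
        y = rng.normal(0.5, 0.2, 12)
        X = np.ones((12, 1))
        rho = 17.0
        ll, beta, sigma2, _ = _gls_profile(rho, t, X, y)
        cov = sigma2 * np.exp(-np.abs(t[:, None] - t[None, :]) / rho)
        expected = stats.multivariate_normal.logpdf(y, mean=(X @ beta), cov=cov)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_full_model_likelihood_dominates_reduced(self):
        series = simulate_correlation_series(
            {"Palaeozoic_postCambrian": 0.25, "Mesozoic": 0.5, "Cenozoic": 0.75},
            n_stages=45, sigma2=0.02, rho=15.0, seed=5,
        )
        full, lrt, reduced = fit_gls_era_model(series)
        assert full.loglik >= reduced.loglik - 1e-8
        assert lrt.statistic >= 0.0 and lrt.df == 2
        assert full.rho > 0 and full.sigma2 > 0

    def test_era_means_recovered_on_one_series(self):
        # moderate autocorrelation (rho = 2 stage spacings), where the ML
        # standard errors are well calibrated
        truth = {"Palaeozoic_postCambrian": 0.2, "Mesozoic": 0.5, "Cenozoic": 0.8}
        series = simulate_correlation_series(truth, n_stages=90, rho=10.0, seed=17)
        full, lrt, _ = fit_gls_era_model(series)
        for era, mu in truth.items():
            assert abs(full.coefficients[era] - mu) <= 3 * full.se[era]
        assert lrt.p < 0.01  # a strong true era effect is detected

    def test_permuted_era_labels_yield_calibrated_pvalues(self):
        # with no true era effect and non-contiguous (shuffled) labels the
        # LRT p-value should be roughly uniform
        rng = np.random.default_rng(99)
        rejections_10 = 0
        n_sims = 30
        for k in range(n_sims):
            series = simulate_correlation_series(
                {"A": 0.5, "B": 0.5, "C": 0.5}, n_stages=60, rho=10.0,
                seed=int(rng.integers(2**31)),
            )
            series["era"] = rng.permutation(series["era"].to_numpy())
            _, lrt, _ = fit_gls_era_model(series)
            rejections_10 += lrt.p < 0.10
        # binomial(30, 0.1): P(>8) < 0.3%
        assert rejections_10 <= 8

    def test_insufficient_eras_rejected(self):
        series = simulate_correlation_series({"OnlyEra": 0.5}, n_stages=10, seed=1)
        with pytest.raises(EcospaceError):
            fit_gls_era_model(series)

    def test_agrees_with_nlme_gls_oracle(self, tmp_path):
        """Independent cross-check of likelihood, coefficients and LRT
        against R's nlme::gls with an exponential spatial correlation."""
        series = simulate_correlation_series(
            {"Palaeozoic_postCambrian": 0.3, "Mesozoic": 0.55, "Cenozoic": 0.7},
            n_stages=24, sigma2=0.03, rho=12.0, seed=21,
        )
        csv = tmp_path / "series.csv"
        series.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""\
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            d$era <- factor(d$era)
            full <- gls(r ~ 0 + era, data = d,
                        correlation = corExp(form = ~midpoint), method = "ML")
            red <- gls(r ~ 1, data = d,
                       correlation = corExp(form = ~midpoint), method = "ML")
            out <- list(
              loglik_full = as.numeric(logLik(full)),
              loglik_reduced = as.numeric(logLik(red)),
              coef = as.list(coef(full)),
              range = coef(full$modelStruct$corStruct, unconstrained = FALSE)
            )
            cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 10))
        """))
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        oracle = json.loads(res.stdout)

        full, lrt, reduced = fit_gls_era_model(series)
        assert full.loglik == pytest.approx(oracle["loglik_full"], abs=1e-3)
        assert reduced.loglik == pytest.approx(oracle["loglik_reduced"], abs=1e-3)
        for era in full.coefficients:
            assert full.coefficients[era] == pytest.approx(
                oracle["coef"][f"era{era}"], abs=1e-4
            )
        assert full.rho == pytest.approx(float(oracle["range"]), rel=0.01)


class TestCrossTimeRegression:
    def test_self_prediction_is_perfect(self, five_stage_timescale):
        # each genus in its own mode -> predictor (modes) == response (genera)
        ts = five_stage_timescale
        records = []
        uid = 0
        for cls, n in {"Cl1": 3, "Cl2": 5, "Cl3": 8}.items():
            for i in range(n):
                mode = (1 + uid // 36, 1 + (uid // 6) % 6, 1 + uid % 6)
                records.append(make_record(f"G{uid}", "B", "B", mode, ts, class_=cls))
                uid += 1
        occ = range_through(records, ts)
        res = cross_time_class_regression(occ, "B", "B")
        assert res.r2 == pytest.approx(1.0) and res.n == 3

    def test_constant_response_explains_nothing(self, five_stage_timescale):
        ts = five_stage_timescale
        records = []
        uid = 0
        for cls, n_modes in {"Cl1": 1, "Cl2": 2, "Cl3": 3}.items():
            for i in range(4):  # same genus count everywhere
                mode = (1, 1, 1 + i % n_modes)
                records.append(make_record(f"G{uid}", "B", "D", mode, ts, class_=cls))
                uid += 1
        occ = range_through(records, ts)
        res = cross_time_class_regression(occ, "B", "D")
        assert res.r2 == 0.0 and res.slope == 0.0

    def test_insufficient_overlap_errors(self, five_stage_timescale):
        ts = five_stage_timescale
        records = [make_record("G0", "B", "B", (1, 1, 1), ts, class_="OnlyOne")]
        occ = range_through(records, ts)
        with pytest.raises(EcospaceError):
            cross_time_class_regression(occ, "B", "B")

    def test_phanerozoic_total_counts_distinct_genera(self, small_occurrences):
        records, occ = small_occurrences
        res = cross_time_class_regression(occ, "B", "phanerozoic_total", min_overlap=1)
        assert res.n == 1  # all fixture genera share one class
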