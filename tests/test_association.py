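import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctnetwb.association import (
    WellbeingTopologyModel,
    fdr_bh,
    fit_glm,
    run_association,
)

from .oracles import bh_stepup


def make_covariates(n, rng):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(20, 60, n),
            "sex": rng.choice(["M", "F"], n),
            "education_years": rng.uniform(8, 22, n),
            "icv_mm3": rng.uniform(1.2e6, 1.7e6, n),
            "mean_ct_mm": rng.uniform(2.3, 2.7, n),
        }
    )


class TestFitGlm:
    def test_noiseless_recovery(self, rng):
        cov = make_covariates(40, rng)
        metric = rng.normal(size=40)
        sex = (cov["sex"] == "M").astype(float)
        y = (
            0.1 * cov["age"] + 0.5 * sex - 0.2 * cov["education_years"]
            + 1e-6 * cov["icv_mm3"] + 2.0 * cov["mean_ct_mm"] + 3.0 * metric + 7.0
        )
        fit = fit_glm(y, metric, cov)
        assert fit.beta == pytest.approx(3.0, abs=1e-8)
        assert abs(fit.partial_r) == pytest.approx(1.0, abs=1e-6)
        assert fit.p_value < 1e-12

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        cov = make_covariates(30, rng)
        metric = rng.normal(size=30)
        y = rng.normal(size=30) + 0.4 * metric
        X = np.column_stack(
            [
                cov["age"], (cov["sex"] == "M").astype(float),
                cov["education_years"], cov["icv_mm3"], cov["mean_ct_mm"], metric,
            ]
        )
        sm_fit = sm.OLS(y, sm.add_constant(X, prepend=False)).fit()
        fit = fit_glm(y, metric, cov)
        assert fit.beta == pytest.approx(sm_fit.params[5])
        assert fit.beta_se == pytest.approx(sm_fit.bse[5])
        assert fit.p_value == pytest.approx(sm_fit.pvalues[5])
        assert fit.df_resid == sm_fit.df_resid

    def test_partial_r_identity(self, rng):
        cov = make_covariates(25, rng)
        metric = rng.normal(size=25)
        y = rng.normal(size=25)
        fit = fit_glm(y, metric, cov)
        t, df = fit.t_stat, fit.df_resid
        assert fit.partial_r**2 * (t**2 + df) == pytest.approx(t**2)
        assert np.sign(fit.partial_r) == np.sign(fit.beta)

    def test_null_p_values_uniform(self, rng):
        # metric independent of outcome: two-sided p approximately U(0,1)
        from scipy import stats

        cov = make_covariates(65, rng)
        ps = []
        for _ in range(400):
            metric = rng.normal(size=65)
            y = rng.normal(size=65)
            ps.append(fit_glm(y, metric, cov).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_constant_outcome_rejected(self, rng):
        cov = make_covariates(20, rng)
        with pytest.raises(ValueError, match="constant"):
            fit_glm(np.ones(20), rng.normal(size=20), cov)

    def test_rank_deficiency_names_column(self, rng):
        cov = make_covariates(20, rng)
        cov["education_years"] = 12.0
        with pytest.raises(ValueError, match="education_years"):
            fit_glm(rng.normal(size=20), rng.normal(size=20), cov)

    def test_orthogonal_covariates_reduce_to_simple_correlation(self, rng):
        n = 4000
        cov = make_covariates(n, rng)
        metric = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * metric
        fit = fit_glm(y, metric, cov)
        simple = np.corrcoef(y, metric)[0, 1]
        assert fit.partial_r == pytest.approx(simple, abs=0.02)


class TestFdrBh:
    def test_all_zero_p_all_significant(self):
        q, flags = fdr_bh(np.zeros(10))
        assert flags.all() and (q == 0).all()

    def test_arithmetic_sequence_matches_stepup(self):
        p = np.arange(1, 33) / 100.0
        qvals, flags = fdr_bh(p)
        oq, oflags = bh_stepup(p)
        np.testing.assert_array_equal(flags, oflags)
        np.testing.assert_allclose(qvals, oq)

    def test_single_p_is_identity(self):
        q, flags = fdr_bh([0.03])
        assert q[0] == pytest.approx(0.03)
        assert flags[0]

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=64)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_stepup(self, p):
        qvals, flags = fdr_bh(np.array(p))
        oq, oflags = bh_stepup(np.array(p))
        np.testing.assert_array_equal(flags, oflags)
        np.testing.assert_allclose(qvals, oq, atol=1e-12)
        assert (qvals >= np.array(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def synthetic_metrics(rng, ids, parcels, metrics=("Elocal", "BC")):
    rows = []
    for metric in metrics:
        for sid in ids:
            for parcel in parcels:
                rows.append(
                    {"subject_id": sid, "parcel": parcel, "metric": metric,
                     "value": rng.normal()}
                )
    return pd.DataFrame(rows)


class TestModel:
    def test_family_loop_matches_single_fits(self, rng):
        ids = [f"s{i}" for i in range(30)]
        parcels = [f"p{k}" for k in range(5)]
        metrics = synthetic_metrics(rng, ids, parcels)
        cov = make_covariates(30, rng)
        scores = pd.DataFrame(
            {
                "subject_id": ids,
                "emotional": rng.integers(0, 16, 30),
                "psychological": rng.integers(0, 31, 30),
                "social": rng.integers(0, 26, 30),
            }
        )
        scores["total"] = scores[["emotional", "psychological", "social"]].sum(axis=1)
        res = run_association(metrics, scores, cov)
        wide = metrics[metrics["metric"] == "Elocal"].pivot(
            index="subject_id", columns="parcel", values="value"
        ).loc[ids]
        for parcel in parcels:
            fit = fit_glm(scores["total"].to_numpy(float), wide[parcel].to_numpy(), cov)
            row = res.table[
                (res.table["metric"] == "Elocal")
                & (res.table["dimension"] == "total")
                & (res.table["parcel"] == parcel)
            ].iloc[0]
            assert row["beta"] == pytest.approx(fit.beta, rel=1e-9)
            assert row["p"] == pytest.approx(fit.p_value, rel=1e-9)
            assert row["partial_r"] == pytest.approx(fit.partial_r, rel=1e-9)
            assert row["df_resid"] == fit.df_resid

    def test_fdr_family_is_metric_by_dimension(self, rng):
        ids = [f"s{i}" for i in range(30)]
        parcels = [f"p{k}" for k in range(6)]
        metrics = synthetic_metrics(rng, ids, parcels)
        cov = make_covariates(30, rng)
        scores = pd.DataFrame(
            {"subject_id": ids, "emotional": rng.integers(0, 16, 30),
             "psychological": rng.integers(0, 31, 30),
             "social": rng.integers(0, 26, 30)}
        )
        scores["total"] = scores[["emotional", "psychological", "social"]].sum(axis=1)
        res = run_association(metrics, scores, cov)
        fam = res.family("BC", "social")
        oq, _ = bh_stepup(fam["p"].to_numpy())
        np.testing.assert_allclose(fam["q"].to_numpy(), oq, atol=1e-12)
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()

    def test_permuting_outcome_destroys_planted_significance(self, rng):
        # plant a strong direct metric-outcome link, then permute the outcome
        ids = [f"s{i}" for i in range(65)]
        parcels = [f"p{k}" for k in range(8)]
        metrics = synthetic_metrics(rng, ids, parcels, metrics=("Elocal",))
        cov = make_covariates(65, rng)
        planted = metrics[
            (metrics["metric"] == "Elocal") & (metrics["parcel"] == "p3")
        ]["value"].to_numpy()
        total = 35 + 10 * planted + rng.normal(scale=4, size=65)
        scores = pd.DataFrame(
            {"subject_id": ids, "emotional": rng.integers(0, 16, 65),
             "psychological": rng.integers(0, 31, 65),
             "social": rng.integers(0, 26, 65), "total": total}
        )
        res = run_association(metrics, scores, cov)
        hit = res.table[
            (res.table["dimension"] == "total") & (res.table["parcel"] == "p3")
        ].iloc[0]
        assert hit["significant"]

        perm = rng.permutation(65)
        scores_perm = scores.copy()
        scores_perm["total"] = total[perm]
        res_perm = run_association(metrics, scores_perm, cov)
        fam = res_perm.table[res_perm.table["dimension"] == "total"]
        assert not fam["significant"].any()

    def test_summary_and_effect_sizes_run(self, rng):
        ids = [f"s{i}" for i in range(30)]
        metrics = synthetic_metrics(rng, ids, ["p0", "p1"], metrics=("EC",))
        cov = make_covariates(30, rng)
        scores = pd.DataFrame(
            {"subject_id": ids, "emotional": rng.integers(0, 16, 30),
             "psychological": rng.integers(0, 31, 30),
             "social": rng.integers(0, 26, 30)}
        )
        scores["total"] = scores[["emotional", "psychological", "social"]].sum(axis=1)
        eglob = pd.DataFrame({"subject_id": ids, "value": rng.uniform(0.4, 0.8, 30)})
        res = WellbeingTopologyModel(metrics, scores, cov, eglob=eglob).fit()
        text = res.summary()
        assert "Eglob" in text and "FDR q" in text
        assert set(res.dimension_effect_sizes().columns) >= {
            "parcel", "metric", "total_partial_r",
        } or res.dimension_effect_sizes().empty

    def test_misaligned_subjects_rejected(self, rng):
        ids = [f"s{i}" for i in range(10)]
        metrics = synthetic_metrics(rng, ids, ["p0"], metrics=("DC",))
        cov = make_covariates(10, rng)
        scores = pd.DataFrame(
            {"subject_id": [f"x{i}" for i in range(10)],
             "emotional": 1, "psychological": 1, "social": 1, "total": 3}
        )
        with pytest.raises(ValueError, match="different subjects"):
            WellbeingTopologyModel(metrics, scores, cov)
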