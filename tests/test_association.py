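"""Cox presence survival, rank correlations, hypoxia score, BH, concordance."""

import numpy as np
import pandas as pd
import pytest

from tumbiome.association import (
    bh_adjust,
    concordance_intersect,
    cox_presence,
    covariate_associations,
    hypoxia_score,
    multi_threshold_survival,
    spearman_assoc,
    survival_associations,
)


def efron_loglik_reference(beta, z, time, event):
    """Plain-loop Efron partial log-likelihood for a binary covariate."""
    r = np.exp(beta * z)
    ll = 0.0
    for t in np.unique(time[event]):
        d_idx = np.flatnonzero((time == t) & event)
        risk = np.flatnonzero(time >= t)
        d = len(d_idx)
        d_sum = r[d_idx].sum()
        r_sum = r[risk].sum()
        ll += beta * z[d_idx].sum()
        for l in range(d):
            ll -= np.log(r_sum - (l / d) * d_sum)
    return ll


def grid_mle(z, time, event, lo=-5, hi=5):
    """Brute-force two-stage grid maximization of the partial likelihood."""
    grid = np.linspace(lo, hi, 4001)
    lls = np.array([efron_loglik_reference(b, z, time, event) for b in grid])
    i = int(np.argmax(lls))
    step = grid[1] - grid[0]
    fine = np.linspace(grid[i] - step, grid[i] + step, 2001)
    fls = np.array([efron_loglik_reference(b, z, time, event) for b in fine])
    j = int(np.argmax(fls))
    return fine[j], fls[j], efron_loglik_reference(0.0, z, time, event)


class TestCoxPresence:
    def toy(self):
        # presence group tends to die earlier but the groups interleave,
        # so the partial likelihood has an interior maximum; distinct times, n=12
        time = np.array([50, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600], float)
        event = np.array([1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0], bool)
        z = np.array([1, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0], float)
        return z, time, event

    def test_matches_brute_force_grid_oracle(self):
        from scipy.stats import chi2

        z, time, event = self.toy()
        res = cox_presence(z, time, event)
        bhat, llmax, ll0 = grid_mle(z, time, event)
        assert res.log_hr == pytest.approx(bhat, abs=1e-4)
        p_oracle = chi2.sf(2 * (llmax - ll0), 1)
        assert res.p == pytest.approx(p_oracle, abs=1e-4)

    def test_matches_grid_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        z = rng.integers(0, 2, 40).astype(float)
        time = np.ceil(rng.exponential(50 * np.exp(-0.6 * z))).astype(float)  # heavy ties
        event = time < 60
        time = np.minimum(time, 60)
        res = cox_presence(z, time, event)
        bhat, *_ = grid_mle(z, time, event)
        assert res.log_hr == pytest.approx(bhat, abs=1e-4)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        z, time, event = self.toy()
        res = cox_presence(z, time, event)
        df = pd.DataFrame({"t": time, "e": event.astype(int), "z": z})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert res.log_hr == pytest.approx(cph.params_["z"], abs=1e-5)
        assert res.p == pytest.approx(cph.log_likelihood_ratio_test().p_value, abs=1e-8)

    def test_degenerate_groups_return_flagged_null(self):
        time = np.arange(1.0, 11.0)
        event = np.ones(10, bool)
        assert cox_presence(np.ones(10), time, event).is_null
        assert cox_presence(np.zeros(10), time, event).is_null
        assert cox_presence(np.arange(10) % 2, time, np.zeros(10, bool)).is_null

    def test_complete_separation_flagged_not_raised(self):
        # all presence deaths precede every absence death: monotone likelihood
        time = np.array([1, 2, 3, 4, 100, 200, 300, 400], float)
        event = np.ones(8, bool)
        z = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        res = cox_presence(z, time, event)
        assert res.is_null and not res.converged

    def test_type_one_error_calibrated(self):
        """Presence independent of survival: p<0.05 rate stays in the binomial band."""
        rng = np.random.default_rng(11)
        n = 150
        hits = 0
        for _ in range(200):
            z = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1000, n)
            e = t < 800
            t = np.minimum(t, 800)
            res = cox_presence(z, t, e)
            hits += res.p is not None and res.p < 0.05
        assert abs(hits / 200 - 0.05) <= 0.03


class TestMultiThreshold:
    def test_constant_abundance_all_null(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, 50)
        out = multi_threshold_survival(np.ones(50), t, t < 90)
        assert len(out) == 9 and out["log_hr"].isna().all()

    def test_grid_of_nine_quantiles_gives_nine_rows(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=80)
        t = rng.exponential(100, 80)
        out = multi_threshold_survival(a, t, t < 90)
        assert len(out) == 9

    def test_p_minimized_near_planted_changepoint(self):
        rng = np.random.default_rng(2)
        n = 400
        a = rng.uniform(0, 1, n)
        hr = np.where(a > 0.7, 3.0, 1.0)  # hazard jumps above the 0.7 quantile
        t = rng.exponential(1000 / hr)
        e = t < 800
        t = np.minimum(t, 800)
        out = multi_threshold_survival(a, t, e)
        best_q = out.loc[out["p"].idxmin(), "quantile"]
        assert 0.5 <= best_q <= 0.9


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_assoc([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        a = np.array([1, 2, 2, 3, 5, 5, 5, 8], float)
        b = np.array([3, 1, 4, 5, 2, 2, 9, 7], float)
        rho, _ = spearman_assoc(a, b)

        def midranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            xs = x[order]
            while i < len(x):
                j = i
                while j < len(x) and xs[j] == xs[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        ra, rb = midranks(a), midranks(b)
        pearson = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)

    def test_missing_values_pairwise_deleted(self):
        a = [1, 2, 3, 4, np.nan, 6]
        b = [1, 2, 3, 4, 5, np.nan]
        rho, p = spearman_assoc(a, b)
        assert rho == pytest.approx(1.0)

    def test_constant_or_short_input_null(self):
        assert spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4]) == (None, None)
        assert spearman_assoc([1, 2, 3], [1, 2, 3]) == (None, None)


class TestHypoxiaScore:
    def expr(self):
        return pd.DataFrame(
            {
                "s1": [10.0, 10.0, 10.0],
                "s2": [1.0, 1.0, 1.0],
                "s3": [5.0, 5.0, 5.0],
            },
            index=["g1", "g2", "g3"],
        )

    def test_above_all_medians_scores_plus_k(self):
        score = hypoxia_score(self.expr(), ["g1", "g2", "g3"])
        assert score["s1"] == 3 and score["s2"] == -3

    def test_exactly_at_median_scores_minus_one(self):
        # s3 sits exactly on every gene median; strict ">" sends it to -1
        score = hypoxia_score(self.expr(), ["g1", "g2", "g3"])
        assert score["s3"] == -3

    def test_missing_genes_warn_absent_all_error(self):
        with pytest.warns(UserWarning, match="absent"):
            score = hypoxia_score(self.expr(), ["g1", "nope"])
        assert score.abs().max() <= 1
        with pytest.raises(ValueError, match="no signature genes"):
            hypoxia_score(self.expr(), ["nope"])

    def test_random_expression_mean_score_near_zero(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.standard_normal((21, 500)),
            index=[f"g{i}" for i in range(21)],
            columns=[f"s{i}" for i in range(500)],
        )
        score = hypoxia_score(expr, list(expr.index))
        se = np.sqrt(21) / np.sqrt(500)  # per-gene ±1 variance ~1, odd k avoids ties
        assert abs(score.mean()) <= 3 * se


class TestBH:
    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_passthrough_and_order_restored(self):
        q = bh_adjust([0.04, np.nan, 0.01])
        assert np.isnan(q[1])
        assert q[2] <= q[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_oracle(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 37)
        q = bh_adjust(p)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)


def assoc_frame(rows):
    df = pd.DataFrame(
        rows, columns=["taxon", "rank_level", "stratum", "covariate", "estimate", "p", "q"]
    )
    df["direction"] = np.sign(df["estimate"])
    df["cohort"] = "c"
    return df


class TestConcordance:
    def test_significant_same_direction_kept(self):
        a = assoc_frame([("t", "species", "all", "survival", 0.9, 0.001, 0.01)])
        b = assoc_frame([("t", "species", "all", "survival", 0.7, 0.004, 0.04)])
        out = concordance_intersect(a, b, alpha=0.05)
        assert len(out) == 1 and out.loc[0, "direction"] == 1

    def test_direction_disagreement_excluded(self):
        a = assoc_frame([("t", "species", "all", "survival", 0.9, 0.001, 0.01)])
        b = assoc_frame([("t", "species", "all", "survival", -0.7, 0.004, 0.04)])
        assert concordance_intersect(a, b).empty

    def test_one_cohort_nonsignificant_excluded(self):
        a = assoc_frame([("t", "species", "all", "survival", 0.9, 0.001, 0.01)])
        b = assoc_frame([("t", "species", "all", "survival", 0.7, 0.100, 0.20)])
        assert concordance_intersect(a, b).empty

    def test_unmatched_keys_ignored(self):
        a = assoc_frame([("t1", "species", "all", "survival", 0.9, 0.001, 0.01)])
        b = assoc_frame([("t2", "species", "all", "survival", 0.9, 0.001, 0.01)])
        assert concordance_intersect(a, b).empty


class TestDrivers:
    def test_survival_driver_strata_and_bh_families(self):
        rng = np.random.default_rng(8)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        md = pd.DataFrame(
            {
                "cancer_type": ["lung"] * 30 + ["colon"] * 30,
                "os_days": rng.exponential(500, n),
                "os_event": rng.integers(0, 2, n),
            },
            index=samples,
        )
        presence = pd.DataFrame(
            rng.random((5, n)) < 0.5, index=[f"t{i}" for i in range(5)], columns=samples
        )
        res = survival_associations(presence, md, cohort="demo")
        assert set(res["stratum"]) == {"all", "lung", "colon"}
        assert (res["q"].dropna() >= res["p"].dropna().min()).all()
        # q >= p within every family
        ok = res.dropna(subset=["p"])
        assert (ok["q"] >= ok["p"] - 1e-12).all()

    def test_covariate_driver_recovers_planted_correlation(self):
        rng = np.random.default_rng(9)
        n = 80
        samples = [f"s{i}" for i in range(n)]
        age = rng.uniform(40, 80, n)
        ab = pd.DataFrame(
            {s: [a / 10 + rng.normal(0, 0.3), rng.normal()] for s, a in zip(samples, age)},
            index=["t_age", "t_null"],
        )
        cov = pd.DataFrame({"age": age}, index=samples)
        res = covariate_associations(ab, cov, cohort="demo")
        row = res.set_index("taxon").loc["t_age"]
        assert row["estimate"] > 0.7 and row["q"] < 0.01
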