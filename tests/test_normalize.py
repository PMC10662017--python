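"""log-CPM precision weights, supervised normalization, rarefaction, prevalence."""

import numpy as np
import pandas as pd
import pytest

from tumbiome.normalize import (
    NormalizedAbundance,
    prevalence,
    rarefy,
    relative_abundance,
    snm_normalize,
    voom_transform,
)
from conftest import make_table


def poisson_table(seed=0, n_taxa=50, n_samples=40):
    rng = np.random.default_rng(seed)
    means = np.logspace(0.5, 3, n_taxa)
    counts = rng.poisson(means[:, None], size=(n_taxa, n_samples))
    cols = {f"s{j}": pd.Series(counts[:, j], index=range(n_taxa)) for j in range(n_samples)}
    return make_table(cols, {f"s{j}": 10_000 for j in range(n_samples)})


class TestVoom:
    def test_zero_count_closed_form(self):
        # library size 999,999 makes the log-cpm of a zero count exactly -1
        counts = {"a": pd.Series({1: 0, 2: 999_999}), "b": pd.Series({1: 50, 2: 1000})}
        table = make_table(counts, {"a": 1, "b": 1})
        na = voom_transform(table)
        assert na.values.loc[1, "a"] == pytest.approx(-1.0, abs=1e-12)

    def test_scale_invariance_up_to_offsets(self):
        table = poisson_table(seed=1)
        doubled = make_table(
            {s: table.counts[s] * 2 for s in table.samples},
            {s: 1 for s in table.samples},
        )
        va = voom_transform(table).values.to_numpy()
        vb = voom_transform(doubled).values.to_numpy()
        # +0.5/+1 offsets break exact invariance only at low counts
        big = table.counts.to_numpy() > 100
        assert np.max(np.abs(va[big] - vb[big])) < 0.02

    def test_weights_finite_positive_and_monotone_in_mean(self):
        table = poisson_table(seed=2)
        na = voom_transform(table)
        w = na.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()
        from scipy.stats import spearmanr

        rho, _ = spearmanr(table.counts.mean(axis=1), na.weights.mean(axis=1))
        assert rho > 0.9  # Poisson: log-scale variance falls as the mean grows

    def test_trend_matches_brute_force_tricube_regression(self):
        """Oracle: local linear fit with tricube weights recomputed by hand."""
        from tumbiome.normalize import _fit_trend

        rng = np.random.default_rng(3)
        n = 60
        sx = np.sort(rng.uniform(0, 10, n))
        sy = 2.0 + np.sin(sx / 3) + rng.normal(0, 0.05, n)
        values = np.tile(sx[:, None], (1, 4))  # row means equal sx
        predict = _fit_trend(values, values, sy**2, span=0.5)
        got = predict(sx)
        k = int(np.ceil(0.5 * n))
        expected = []
        for x0 in sx:
            d = np.abs(sx - x0)
            h = np.sort(d)[k - 1]
            w = np.clip(1 - (d / h) ** 3, 0, 1) ** 3
            X = np.column_stack([np.ones(n), sx - x0])
            beta = np.linalg.lstsq(X * w[:, None], sy * w, rcond=None)[0]
            expected.append(beta[0])
        # smoother implementations differ slightly in bandwidth bookkeeping;
        # agreement to a few percent of the signal range confirms the trend
        assert np.max(np.abs(got - np.asarray(expected))) < 0.05

    def test_zero_library_size_names_sample(self):
        counts = {"ok": pd.Series({1: 5, 2: 5}), "empty": pd.Series({1: 0, 2: 0})}
        table = make_table(counts, {"ok": 1, "empty": 1})
        with pytest.raises(ValueError, match="empty"):
            voom_transform(table)


def flat_norm(values: np.ndarray, samples) -> NormalizedAbundance:
    df = pd.DataFrame(values, columns=samples)
    return NormalizedAbundance(values=df, weights=pd.DataFrame(np.ones_like(values), columns=samples))


class TestSnm:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.n, self.t = 60, 40
        self.samples = [f"s{i}" for i in range(self.n)]
        self.batch = np.array(["A"] * 30 + ["B"] * 30)
        # cancer type balanced within batch: orthogonal bio/technical design
        self.ct = np.array(["x", "y"] * 30)
        self.md = pd.DataFrame(
            {"batch": self.batch, "cancer_type": self.ct}, index=self.samples
        )
        self.base = rng.normal(5, 1, (self.t, self.n))

    def test_planted_batch_shift_removed(self):
        vals = self.base + 2.0 * (self.batch == "B")
        out = snm_normalize(flat_norm(vals, self.samples), self.md, ["cancer_type"], ["batch"])
        diff = (
            out.values.loc[:, self.batch == "B"].mean(axis=1)
            - out.values.loc[:, self.batch == "A"].mean(axis=1)
        )
        assert np.abs(diff).max() < 0.05

    def test_planted_bio_effect_preserved(self):
        vals = self.base + 2.0 * (self.batch == "B")
        bio_rows = np.arange(20)
        vals[np.ix_(bio_rows, np.flatnonzero(self.ct == "y"))] += 1.0
        out = snm_normalize(flat_norm(vals, self.samples), self.md, ["cancer_type"], ["batch"])
        v = out.values.to_numpy()
        eff = (
            v[np.ix_(bio_rows, self.ct == "y")].mean(axis=1)
            - v[np.ix_(bio_rows, self.ct == "x")].mean(axis=1)
        )
        pre = (
            vals[np.ix_(bio_rows, self.ct == "y")].mean(axis=1)
            - vals[np.ix_(bio_rows, self.ct == "x")].mean(axis=1)
        )
        assert np.abs(eff.mean() / pre.mean() - 1) < 0.05

    def test_empty_adjustment_is_identity(self):
        na = flat_norm(self.base, self.samples)
        out = snm_normalize(na, self.md, ["cancer_type"], [])
        pd.testing.assert_frame_equal(out.values, na.values)

    def test_confounded_design_rejected_with_aliased_columns(self):
        md = self.md.copy()
        md["batch"] = np.where(md["cancer_type"] == "x", "A", "B")  # 1:1 confound
        with pytest.raises(ValueError, match="aliased"):
            snm_normalize(flat_norm(self.base, self.samples), md, ["cancer_type"], ["batch"])

    def test_adjustment_variance_suppressed_bio_retained(self):
        """Variance explained by the technical variable collapses; biology survives."""
        vals = self.base + 2.0 * (self.batch == "B")
        bio_rows = np.arange(20)
        vals[np.ix_(bio_rows, np.flatnonzero(self.ct == "y"))] += 1.5
        out = snm_normalize(flat_norm(vals, self.samples), self.md, ["cancer_type"], ["batch"])

        def r2(values, groups):
            r2s = []
            for row in values:
                grand = row.mean()
                ss_tot = ((row - grand) ** 2).sum()
                ss_b = sum(
                    (row[groups == g].mean() - grand) ** 2 * (groups == g).sum()
                    for g in np.unique(groups)
                )
                r2s.append(ss_b / ss_tot)
            return float(np.mean(r2s))

        assert r2(out.values.to_numpy(), self.batch) < 0.01
        bio_pre = r2(vals[bio_rows], self.ct)
        bio_post = r2(out.values.to_numpy()[bio_rows], self.ct)
        assert bio_post >= 0.8 * bio_pre


class TestRelativeAbundance:
    def test_microbial_fractions(self):
        table = make_table({"s": pd.Series({1: 2, 2: 3})}, {"s": 100})
        rel = relative_abundance(table)
        assert rel["s"].tolist() == [0.4, 0.6]

    def test_including_human_portion(self):
        table = make_table({"s": pd.Series({1: 3, 2: 2})}, {"s": 95})
        rel = relative_abundance(table, include_human=True)
        assert rel.loc[1, "s"] == pytest.approx(0.03)
        assert rel.loc["human", "s"] == pytest.approx(0.95)

    def test_columns_sum_to_one(self, toy_table):
        rel = relative_abundance(toy_table)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        table = make_table(
            {"a": pd.Series({1: 5, 2: 5}), "b": pd.Series({1: 30, 2: 20})}, {"a": 1, "b": 1}
        )
        out = rarefy(table, depth="min", seed=0)
        assert out.counts["a"].tolist() == [5, 5]  # a is the minimum-depth sample

    def test_column_sums_equal_depth(self, toy_table):
        out = rarefy(toy_table, depth="min", seed=1)
        depth = toy_table.library_sizes().min()
        assert (out.counts.sum(axis=0) == depth).all()

    def test_deterministic_for_fixed_seed(self, toy_table):
        a = rarefy(toy_table, seed=42).counts
        b = rarefy(toy_table, seed=42).counts
        pd.testing.assert_frame_equal(a, b)

    def test_mean_matches_hypergeometric_expectation(self):
        """Oracle: E[rarefied count] = depth * count / total, across 500 seeds."""
        col = pd.Series({1: 40, 2: 10, 3: 50})
        table = make_table({"s": col}, {"s": 1})
        depth = 20
        draws = np.array(
            [rarefy(table, depth=depth, seed=s).counts["s"].to_numpy() for s in range(500)]
        )
        total = col.sum()
        expected = depth * col.to_numpy() / total
        # hypergeometric variance for each taxon
        var = (
            depth
            * (col.to_numpy() / total)
            * (1 - col.to_numpy() / total)
            * (total - depth)
            / (total - 1)
        )
        se = np.sqrt(var / 500)
        assert (np.abs(draws.mean(axis=0) - expected) <= 3 * se).all()

    def test_nonpositive_depth_rejected(self, toy_table):
        with pytest.raises(ValueError, match="depth"):
            rarefy(toy_table, depth=0)

    def test_explicit_depth_drops_shallow_samples_with_warning(self, toy_table):
        with pytest.warns(UserWarning, match="dropping"):
            out = rarefy(toy_table, depth=20, seed=0)
        assert "s2" not in out.samples  # s2 has 17 reads total


class TestPrevalence:
    def test_any_read_is_present(self):
        table = make_table({"s": pd.Series({1: 1, 2: 0})}, {"s": 1})
        prev = prevalence(table)
        assert bool(prev.presence.loc[1, "s"]) is True
        assert bool(prev.presence.loc[2, "s"]) is False

    def test_idempotent_and_commutes_with_reordering(self, toy_table):
        rare = rarefy(toy_table, seed=3)
        p1 = prevalence(rare).presence
        shuffled = toy_table.subset_taxa(list(reversed(toy_table.taxa)))
        p2 = prevalence(rarefy(shuffled, seed=3)).presence
        pd.testing.assert_frame_equal(p1.sort_index(), p2.sort_index())
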