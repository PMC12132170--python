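import numpy as np
import pandas as pd
import pytest

from agechrom.da import (
    LN2,
    AccessibilityAgingModel,
    cross_sex,
    fit_da,
    summarize_across_celltypes,
)
from agechrom.simulate import generate_pseudobulk_da


def hand_poisson_irls(y, age, offset, max_iter=100):
    """Standalone IRLS for log-linear Poisson regression (test oracle)."""
    X = np.column_stack([np.ones_like(age), age])
    beta = np.array([np.log(max(y.mean(), 1e-8)) - np.mean(offset), 0.0])
    for _ in range(max_iter):
        mu = np.exp(offset + X @ beta)
        W = np.diag(mu)
        z = X @ beta + (y - mu) / mu
        beta_new = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
        if np.abs(beta_new - beta).max() < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestModelFit:
    def test_equal_counts_equal_libraries_null(self):
        counts = pd.DataFrame(
            np.full((6, 10), 20), index=[f"s{i}" for i in range(6)],
            columns=[f"p{i}" for i in range(10)],
        )
        meta = pd.DataFrame({"sample": counts.index, "age_months": [1, 1, 5, 5, 21, 21],
                             "sex": "F"})
        res = AccessibilityAgingModel(counts=counts, sample_meta=meta).fit()
        assert np.allclose(res.table["logfc_per_month"], 0.0, atol=1e-8)
        assert (res.table["p"] > 0.9).all()

    def test_poisson_limit_matches_irls_oracle(self, rng):
        n, P = 12, 30
        ages = np.tile([1.0, 5.0, 21.0], 4)
        base = rng.uniform(5, 50, P)
        lfc = rng.normal(0, 0.03, P)
        depth = rng.uniform(0.5, 2.0, n)
        mu = depth[:, None] * base[None, :] * np.exp(ages[:, None] * lfc[None, :])
        counts = pd.DataFrame(rng.poisson(mu), index=[f"s{i}" for i in range(n)],
                              columns=[f"p{j}" for j in range(P)])
        meta = pd.DataFrame({"sample": counts.index, "age_months": ages, "sex": "F"})
        libsize = counts.sum(axis=1).to_numpy()
        model = AccessibilityAgingModel(counts=counts, sample_meta=meta,
                                        dispersion=0.0, min_total=0,
                                        normalization="libsize")
        res = model.fit()
        offset = np.log(libsize)
        for j, peak in enumerate(counts.columns):
            beta = hand_poisson_irls(counts[peak].to_numpy(float), ages, offset)
            assert res.table.set_index("peak").loc[peak, "logfc_per_month"] == pytest.approx(
                beta[1] / LN2, abs=1e-6
            )

    def test_poisson_limit_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        counts, meta = generate_pseudobulk_da(n_samples=12, n_peaks=20, dispersion=0.0,
                                              baseline_mean=30, seed=5)
        res = AccessibilityAgingModel(counts=counts, sample_meta=meta, dispersion=0.0,
                                      normalization="libsize").fit()
        offset = np.log(counts.sum(axis=1).to_numpy(float))
        ages = meta["age_months"].to_numpy()
        X = sm.add_constant(ages)
        for peak in res.table["peak"].head(10):
            fit = sm.GLM(counts[peak].to_numpy(float), X, family=sm.families.Poisson(),
                         offset=offset).fit()
            assert res.table.set_index("peak").loc[peak, "logfc_per_month"] == pytest.approx(
                fit.params[1] / LN2, abs=1e-6
            )

    def test_nb_matches_statsmodels_at_fixed_dispersion(self, rng):
        import statsmodels.api as sm

        counts, meta = generate_pseudobulk_da(n_samples=20, n_peaks=15, dispersion=0.1,
                                              baseline_mean=40, seed=6)
        alpha = 0.1
        res = AccessibilityAgingModel(counts=counts, sample_meta=meta, dispersion=alpha,
                                      normalization="libsize").fit()
        offset = np.log(counts.sum(axis=1).to_numpy(float))
        X = sm.add_constant(meta["age_months"].to_numpy())
        for peak in res.table["peak"].head(8):
            fit = sm.GLM(counts[peak].to_numpy(float), X,
                         family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=offset).fit()
            assert res.table.set_index("peak").loc[peak, "logfc_per_month"] == pytest.approx(
                fit.params[1] / LN2, abs=1e-5
            )

    def test_library_scale_invariance(self):
        counts, meta = generate_pseudobulk_da(n_samples=12, n_peaks=25, dispersion=0.05,
                                              seed=2)
        lib = counts.sum(axis=1).to_numpy(float)
        a = AccessibilityAgingModel(counts=counts, sample_meta=meta,
                                    library_sizes=lib).fit()
        b = AccessibilityAgingModel(counts=counts, sample_meta=meta,
                                    library_sizes=lib * 7.5).fit()
        assert np.allclose(a.table["logfc_per_month"], b.table["logfc_per_month"], atol=1e-9)
        assert np.allclose(a.table["p"], b.table["p"], atol=1e-9)

    def test_low_count_peaks_excluded_and_reported(self):
        counts, meta = generate_pseudobulk_da(n_samples=8, n_peaks=10, seed=0)
        counts.iloc[:, 0] = 0
        res = AccessibilityAgingModel(counts=counts, sample_meta=meta, min_total=5).fit()
        assert "peak00000" in res.excluded_peaks
        assert "peak00000" not in set(res.table["peak"])

    def test_single_age_rejected(self):
        counts = pd.DataFrame(np.ones((4, 3)), index=list("abcd"), columns=list("xyz"))
        meta = pd.DataFrame({"sample": list("abcd"), "age_months": 5.0, "sex": "F"})
        with pytest.raises(ValueError, match="single age"):
            AccessibilityAgingModel(counts=counts, sample_meta=meta)

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        meta = pd.DataFrame({"sample": list("abc"), "age_months": [1, 5, 21], "sex": "F"})
        with pytest.raises(ValueError, match=">= 4"):
            AccessibilityAgingModel(counts=counts, sample_meta=meta)

    def test_stratum_wrapper_selects_sex(self):
        counts, meta = generate_pseudobulk_da(n_samples=12, n_peaks=5, seed=1)
        meta["sex"] = ["F", "M"] * 6
        res = fit_da(counts, meta, sex_stratum="F")
        assert (res.table["sex_stratum"] == "F").all()


class TestCrossSex:
    def _table(self, peaks, q, lfc, sex):
        return pd.DataFrame(
            {"peak": peaks, "tissue": "t", "cell_type": "ct", "sex_stratum": sex,
             "logfc_per_month": lfc, "p": q, "q": q,
             "direction": np.where(np.asarray(lfc) > 0, "up", "down"), "mean_cpm": 10.0}
        )

    def test_identical_strata_all_shared(self):
        peaks = [f"p{i}" for i in range(6)]
        lfc = [0.1, 0.2, -0.1, 0.15, -0.2, 0.05]
        f = self._table(peaks, [0.01] * 6, lfc, "F")
        m = self._table(peaks, [0.01] * 6, lfc, "M")
        out = cross_sex(f, m)
        assert sorted(out["shared"]) == sorted(peaks)
        assert out["spearman_shared_logfc"] == pytest.approx(1.0)
        assert out["concordant_share"] == 1.0
        assert out["F_specific"] == [] and out["M_specific"] == []

    def test_sex_specific_requires_floor(self):
        f = self._table(["p1", "p2"], [0.01, 0.01], [0.1, 0.1], "F")
        # p1 null in males (tiny logFC) -> F-specific; p2 has a sub-threshold
        # but sizeable male logFC -> not called sex-specific
        m = self._table(["p1", "p2"], [0.9, 0.9], [0.001, 0.1], "M")
        out = cross_sex(f, m, logfc_floor=0.02)
        assert out["F_specific"] == ["p1"]
        assert out["M_specific"] == []

    def test_empty_significant_sets(self):
        f = self._table(["p1"], [0.9], [0.1], "F")
        m = self._table(["p1"], [0.9], [0.1], "M")
        out = cross_sex(f, m)
        assert out["shared"] == [] and np.isnan(out["spearman_shared_logfc"])


class TestSummarize:
    def _rows(self, peak, n_up, n_down, q=0.01):
        rows = []
        for i in range(n_up):
            rows.append({"peak": peak, "tissue": f"t{i%3}", "cell_type": f"up{i}",
                         "sex_stratum": "F", "logfc_per_month": 0.1, "p": q, "q": q,
                         "direction": "up", "mean_cpm": 5})
        for i in range(n_down):
            rows.append({"peak": peak, "tissue": f"t{i%3}", "cell_type": f"dn{i}",
                         "sex_stratum": "F", "logfc_per_month": -0.1, "p": q, "q": q,
                         "direction": "down", "mean_cpm": 5})
        return rows

    def test_class_rules(self):
        da = pd.DataFrame(
            self._rows("shared_up", 12, 0)
            + self._rows("opp", 6, 5)
            + self._rows("few", 3, 0)
            + self._rows("shared_dn", 0, 10)
        )
        out = summarize_across_celltypes(da).set_index("peak")
        assert out.loc["shared_up", "class"] == "shared-up"
        assert out.loc["opp", "class"] == "opposite"
        assert out.loc["few", "class"] == "other"
        assert out.loc["shared_dn", "class"] == "shared-down"
        assert out.loc["shared_up", "n_celltypes_up"] == 12

    def test_insignificant_rows_ignored(self):
        da = pd.DataFrame(self._rows("x", 12, 0, q=0.5) + self._rows("y", 1, 0))
        out = summarize_across_celltypes(da)
        assert "x" not in set(out["peak"])

    def test_single_celltype_rejected(self):
        da = pd.DataFrame(self._rows("x", 1, 0))
        with pytest.raises(ValueError, match=">= 2 cell types"):
            summarize_across_celltypes(da)


def test_planted_da_recovered_in_study_fixture(fixture_run):
    """Sex-shared planted peaks reach q < 0.05 in most strata of the study fixture."""
    import agechrom.io as ageio

    run_dir, truth = fixture_run
    da = ageio.read_tsv(run_dir / "outputs" / "da_results.tsv")
    planted = {
        p for p, e in truth["effects"]["da_effects"].items()
        if e["sex_scope"] == "shared" and e["cell_types"] is None
    }
    sig = da[da["q"] < 0.05]
    assert len(planted & set(sig["peak"])) / len(planted) >= 0.8
    # F-only planted peaks should be found in the female stratum
    f_only = {p for p, e in truth["effects"]["da_effects"].items() if e["sex_scope"] == "F-only"}
    sig_f = set(sig.loc[sig["sex_stratum"] == "F", "peak"])
    assert len(f_only & sig_f) / len(f_only) >= 0.8
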