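import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from memoscore.evaluate import (ModelSpec, bh_adjust, build_model_grid,
                                compare_nested, fdr_layers, fit_model,
                                run_grid, sensitivity_exclude)


def gaussian_ols_oracle(y, X_cols):
    """Closed-form OLS + full Gaussian log-likelihood for a small fixture."""
    n = len(y)
    X = np.column_stack([np.ones(n)] + X_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1 - rss / tss
    k = len(X_cols)
    q = k + 2
    ll = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
    return {"r2": r2, "aic": -2 * ll + 2 * q, "bic": -2 * ll + q * np.log(n),
            "adj_r2": 1 - (1 - r2) * (n - 1) / (n - k - 1)}


def spec(background=("x",), risk=()):
    return ModelSpec(label="m", background=tuple(background),
                     risk_terms=tuple(risk))


class TestFitModel:
    def test_four_point_fixture_matches_closed_form(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cohort = pd.DataFrame({"em_score": y, "x": x})
        fit = fit_model(spec(), cohort)
        oracle = gaussian_ols_oracle(y, [x])
        assert fit.r2 == pytest.approx(oracle["r2"], abs=1e-8)
        assert fit.adj_r2 == pytest.approx(oracle["adj_r2"], abs=1e-8)
        assert fit.aic == pytest.approx(oracle["aic"], abs=1e-8)
        assert fit.bic == pytest.approx(oracle["bic"], abs=1e-8)

    def test_outcome_equal_to_covariate_gives_r2_one(self):
        x = np.arange(8, dtype=float)
        cohort = pd.DataFrame({"em_score": x, "x": x})
        assert fit_model(spec(), cohort).r2 >= 1 - 1e-10

    def test_noise_term_raises_r2_but_lowers_adjusted_r2_on_average(self):
        rng = np.random.default_rng(0)
        d_r2, d_adj = [], []
        for _ in range(200):
            n = 30
            cohort = pd.DataFrame({
                "em_score": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "caide": rng.standard_normal(n),  # pure-noise extra term
            })
            base = fit_model(spec(), cohort)
            ext = fit_model(ModelSpec("m2", ("x",), ("caide",)), cohort)
            d_r2.append(ext.r2 - base.r2)
            d_adj.append(ext.adj_r2 - base.adj_r2)
        assert all(d >= 0 for d in d_r2)
        assert np.mean(d_adj) < 0

    def test_rank_deficiency_names_terms(self):
        x = np.arange(6, dtype=float)
        cohort = pd.DataFrame({"em_score": x + 1, "x": x, "z": 2 * x})
        with pytest.raises(ValueError, match="z"):
            fit_model(ModelSpec("m", ("x", "z"), ()), cohort)


class TestModelGrid:
    def test_twelve_specs_without_double_prs(self):
        specs = build_model_grid(["age_at_test", "draw_interval"])
        assert len(specs) == 12
        for s in specs:
            assert not {"lasso_prs", "gwama_prs"} <= set(s.risk_terms)
            assert "age_at_test" in s.background
        assert [s.label for s in specs] == sorted(s.label for s in specs)

    def test_spec_refuses_both_prss(self):
        with pytest.raises(ValueError, match="both PRSs"):
            ModelSpec("bad", ("age_at_test",), ("lasso_prs", "gwama_prs"))

    def test_grid_contains_expected_combinations(self):
        specs = build_model_grid(["age_at_test"])
        labels = {s.label for s in specs}
        assert "bg" in labels
        assert "bg+caide+lasso_prs+mrs" in labels
        assert "bg+mrs+gwama_prs" in labels


class TestCompareNested:
    def cohort(self, n=60, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "em_score": rng.standard_normal(n),
            "age_at_test": rng.uniform(60, 75, n),
            "caide": rng.integers(0, 12, n).astype(float),
            "score_mrs": rng.standard_normal(n),
        })
        df["em_score"] += 0.3 * df["score_mrs"]
        return df

    def test_identical_specs_give_zero_deltas(self):
        fit = fit_model(ModelSpec("a", ("age_at_test",), ("caide",)),
                        self.cohort())
        row = compare_nested(fit, fit)
        assert row.delta_r2_pp == 0 and row.delta_aic == 0 and row.delta_bic == 0

    def test_delta_r2_nonnegative_and_in_percentage_points(self):
        c = self.cohort()
        base = fit_model(ModelSpec("a", ("age_at_test",), ()), c)
        ext = fit_model(ModelSpec("b", ("age_at_test",), ("mrs",)), c)
        row = compare_nested(base, ext)
        assert row.delta_r2_pp >= 0
        assert row.delta_r2_pp == pytest.approx(100 * (ext.r2 - base.r2))
        assert "mrs" in row.added_terms

    def test_non_nested_pair_rejected(self):
        c = self.cohort()
        f1 = fit_model(ModelSpec("a", ("age_at_test",), ("caide",)), c)
        f2 = fit_model(ModelSpec("b", ("age_at_test",), ("mrs",)), c)
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(f1, f2)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.031]))[0] == pytest.approx(0.031)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_matches_independent_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.uniform(1e-12, 1, size=rng.integers(1, 40))
            mine = bh_adjust(p)
            _, oracle, *_ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, oracle, atol=1e-12)
            assert np.all(mine >= p - 1e-15)  # adjusted never below raw

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))


class TestFdrLayers:
    def records(self):
        return pd.DataFrame({
            "term": ["caide", "mrs", "lasso_prs", "gwama_prs", "lasso_prs"],
            "model": ["m1", "m1", "m1", "m2", "m2"],
            "dataset": ["test"] * 5,
            "p": [0.04, 0.01, 0.02, 0.03, 0.05],
        })

    def test_within_layer_pools_both_prss(self):
        out = fdr_layers(self.records(), "within_layer")
        assert set(out["family"]) == {"caide", "mrs", "prs"}
        prs = out[out["family"] == "prs"]
        np.testing.assert_allclose(sorted(prs["p_adj"]),
                                   bh_adjust(np.array([0.02, 0.03, 0.05])))

    def test_per_prs_keeps_families_separate(self):
        out = fdr_layers(self.records(), "per_prs")
        lasso = out[out["term"] == "lasso_prs"]
        np.testing.assert_allclose(sorted(lasso["p_adj"]),
                                   bh_adjust(np.array([0.02, 0.05])))

    def test_single_member_family_is_raw(self):
        out = fdr_layers(self.records(), "within_layer")
        assert out.loc[out["term"] == "caide", "p_adj"].iloc[0] == \
            pytest.approx(0.04)

    def test_global_null_family_false_positive_rate_controlled(self):
        rng = np.random.default_rng(3)
        false_hits = 0
        n_rep = 500
        for _ in range(n_rep):
            rec = pd.DataFrame({
                "term": ["caide"] * 4 + ["mrs"] * 4 + ["lasso_prs"] * 4,
                "model": list("abcd") * 3,
                "dataset": ["test"] * 12,
                "p": rng.uniform(size=12),
            })
            out = fdr_layers(rec, "within_layer")
            false_hits += (out["p_adj"] < 0.05).any()
        # per-family FWER under the null is ~alpha per family; 3 families
        assert false_hits / n_rep <= 3 * 0.05 + 0.03

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            fdr_layers(self.records(), "bonferroni")


class TestSensitivity:
    def cohort(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"em_score": rng.standard_normal(104),
                           "stroke_before_test": False})
        df.loc[[5, 50, 100], "stroke_before_test"] = True
        return df

    def test_three_flagged_of_104_leaves_101(self):
        out = sensitivity_exclude(self.cohort())
        assert len(out) == 101

    def test_idempotent_and_identity_when_unflagged(self):
        c = self.cohort()
        once = sensitivity_exclude(c)
        twice = sensitivity_exclude(once)
        pd.testing.assert_frame_equal(once, twice)
        clean = c.assign(stroke_before_test=False)
        pd.testing.assert_frame_equal(sensitivity_exclude(clean), clean)

    def test_emptying_exclusion_rejected(self):
        c = self.cohort().assign(stroke_before_test=True)
        with pytest.raises(ValueError, match="empties"):
            sensitivity_exclude(c)
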