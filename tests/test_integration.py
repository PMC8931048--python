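import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from epistate.core import ValidationError
from epistate.integration import (
    fit_integration,
    lmg_shares,
    relative_importance_report,
)


def _r2(X, y):
    X = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return 1 - resid @ resid / ((y - y.mean()) ** 2).sum()


def brute_force_lmg(X, y):
    """Average sequential R^2 increments over every covariate ordering."""
    k = X.shape[1]
    shares = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        prev = 0.0
        chosen = []
        for j in order:
            chosen.append(j)
            r2 = _r2(X[:, sorted(chosen)], y)
            shares[j] += r2 - prev
            prev = r2
    return shares / len(orders)


class TestFitIntegration:
    def _design(self, rng, n=120):
        return pd.DataFrame(
            {
                "a": rng.uniform(0, 100, n),
                "b": rng.uniform(0, 100, n),
                "c": (rng.random(n) < 0.5).astype(float),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_effect_transform(self, rng):
        design = self._design(rng)
        y = 1.0 + math.log(2) * design["c"].to_numpy()
        counts = np.expm1(y)  # noiseless
        fit = fit_integration(design, counts)
        effects = dict(zip(fit.covariates, fit.effects))
        assert effects["a"] == pytest.approx(0.0, abs=1e-9)
        assert effects["c"] == pytest.approx(1.0, rel=1e-9)  # e^ln2 - 1

    def test_paper_cutoffs(self, rng):
        n, k = 100, 5
        design = pd.DataFrame(rng.normal(size=(n, k)),
                              columns=list("abcde"))
        counts = np.exp(rng.normal(size=n))
        fit = fit_integration(design, counts)
        assert 2 * k / n == pytest.approx(0.100)
        assert 4 / (n - k - 1) == pytest.approx(0.04255, abs=1e-5)
        # every excluded observation violated one of those cutoffs
        diag = fit.diagnostics
        for oid, reason in fit.excluded:
            row = diag.loc[oid]
            if reason == "leverage":
                assert row["h"] > 0.100
            else:
                assert row["cook_d"] > 4 / (n - k - 1)

    def test_planted_recovery(self, rng):
        design = self._design(rng, n=400)
        mu = 2.0 + 0.02 * design["a"] + 0.0 * design["b"] + 0.8 * design["c"]
        counts = np.expm1(mu + rng.normal(0, 0.3, len(design)))
        counts = np.maximum(counts, 0)
        fit = fit_integration(design, counts)
        betas = dict(zip(["intercept"] + fit.covariates, fit.betas))
        ses = dict(zip(["intercept"] + fit.covariates, fit.se))
        assert abs(betas["a"] - 0.02) < 3 * ses["a"]
        assert abs(betas["c"] - 0.8) < 3 * ses["c"]

    def test_rank_deficiency_rejected(self, rng):
        design = self._design(rng)
        design["dup"] = design["a"]
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_integration(design, np.ones(len(design)))

    def test_exclusion_rule_limits_outlier_influence(self, rng):
        design = self._design(rng, n=100)
        mu = 1.0 + 0.01 * design["a"]
        counts = np.expm1(mu + rng.normal(0, 0.2, 100))
        # plant one gross outlier
        counts.iloc[0] = 1e6
        fit_rule = fit_integration(design, counts, compute_lmg=False)
        assert any(oid == "g0" for oid, _ in fit_rule.excluded)
        # compare against a fit with no exclusion: the outlier drags beta
        clean = counts.copy()
        clean.iloc[0] = np.expm1(mu.iloc[0])
        fit_clean = fit_integration(design, clean, compute_lmg=False)
        b_rule = dict(zip(["i"] + fit_rule.covariates, fit_rule.betas))["a"]
        b_clean = dict(zip(["i"] + fit_clean.covariates, fit_clean.betas))["a"]
        assert abs(b_rule - b_clean) < 0.005

    def test_n_too_small(self, rng):
        design = self._design(rng, n=4)
        with pytest.raises(ValidationError):
            fit_integration(design, np.ones(4))


class TestLmg:
    def test_orthogonal_covariates(self):
        rng = np.random.default_rng(8)
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"a": a, "b": b})
        y = 2 * a + 1 * b + rng.normal(0, 0.1, n)
        shares = lmg_shares(X, y)
        r2_a = _r2(X[["a"]].to_numpy(), y)
        r2_b = _r2(X[["b"]].to_numpy(), y)
        total = _r2(X.to_numpy(), y)
        assert shares["a"] == pytest.approx(r2_a, abs=1e-6)
        assert shares["b"] == pytest.approx(r2_b, abs=1e-6)
        assert shares["a"] + shares["b"] == pytest.approx(total, abs=1e-9)

    def test_k2_closed_form(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = X["a"] + 0.5 * X["b"] + rng.normal(0, 0.5, 60)
        y = y.to_numpy()
        shares = lmg_shares(X, y)
        xa, xb = X[["a"]].to_numpy(), X[["b"]].to_numpy()
        expected_a = 0.5 * (_r2(xa, y) + (_r2(X.to_numpy(), y) - _r2(xb, y)))
        assert shares["a"] == pytest.approx(expected_a, abs=1e-10)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_all_orderings_brute_force(self, k):
        rng = np.random.default_rng(k)
        X = pd.DataFrame(rng.normal(size=(80, k)),
                         columns=[f"x{i}" for i in range(k)])
        # correlated design so ordering matters
        X["x0"] = X["x0"] + 0.8 * X["x1"]
        y = (X.to_numpy() @ rng.normal(size=k)) + rng.normal(0, 0.5, 80)
        shares = lmg_shares(X, y)
        expected = brute_force_lmg(X.to_numpy(), y)
        for j, c in enumerate(X.columns):
            assert shares[c] == pytest.approx(expected[j], abs=1e-10)

    def test_shares_sum_to_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 1, 50)
        shares = lmg_shares(X, y)
        assert sum(shares.values()) == pytest.approx(_r2(X.to_numpy(), y),
                                                     abs=1e-9)

    def test_duplicated_covariate_splits_equally(self, rng):
        a = rng.normal(size=100)
        X = pd.DataFrame({"a1": a, "a2": a + rng.normal(0, 1e-9, 100),
                          "b": rng.normal(size=100)})
        y = a + rng.normal(0, 0.3, 100)
        shares = lmg_shares(X, y)
        assert shares["a1"] == pytest.approx(shares["a2"], abs=1e-4)

    def test_sampled_matches_exact(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=[f"x{i}" for i in range(6)])
        y = X["x0"].to_numpy() * 2 + rng.normal(0, 0.5, 80)
        exact = lmg_shares(X, y)
        sampled = lmg_shares(X, y, max_exact=0, allow_sampling=True,
                             n_orderings=4000, seed=5)
        for c in X.columns:
            assert sampled[c] == pytest.approx(exact[c], abs=0.02)

    def test_k_over_bound_needs_flag(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 12)),
                         columns=[f"x{i}" for i in range(12)])
        y = rng.normal(size=40)
        with pytest.raises(ValidationError, match="sampling"):
            lmg_shares(X, y)


class TestRelativeImportance:
    def test_single_covariate_full_share(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        y = X["a"].to_numpy() + rng.normal(0, 0.2, 50)
        fit = fit_integration(X, np.expm1(np.maximum(y, 0)))
        report = relative_importance_report(fit)
        assert report["percent_of_r2"].iloc[0] == pytest.approx(100.0)

    def test_percent_sums_to_100(self, pipeline_result):
        report = relative_importance_report(pipeline_result.integration)
        assert report["percent_of_r2"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_dominant_enhancer_ranked_first(self, rng):
        n = 400
        X = pd.DataFrame({
            "active_occ": rng.uniform(0, 100, n),
            "mc_fraction": rng.uniform(0, 100, n),
            "enh_present": (rng.random(n) < 0.3).astype(float),
        })
        mu = 1 + 0.001 * X["active_occ"] + 0.001 * X["mc_fraction"] \
            + 2.5 * X["enh_present"]
        counts = np.maximum(np.expm1(mu + rng.normal(0, 0.4, n)), 0)
        fit = fit_integration(X, counts)
        report = relative_importance_report(fit)
        assert report["covariate"].iloc[0] == "enh_present"
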