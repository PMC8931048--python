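"""Multivariable log-linear model of expression on epigenetic covariates:
e^beta - 1 effect sizes, LMG relative-importance decomposition of R^2, and
leverage / Cook's-distance exclusion with a single refit."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = ["IntegrationFit", "fit_integration", "lmg_shares", "relative_importance_report"]


@dataclass
class IntegrationFit:
    covariates: list[str]
    betas: np.ndarray  # intercept first
    se: np.ndarray
    wald_z: np.ndarray
    p: np.ndarray
    effects: np.ndarray  # e^beta - 1 per covariate (no intercept)
    r2: float
    lmg: dict[str, float]
    excluded: list[tuple[object, str]]  # (observation id, reason)
    vif: dict[str, float]
    n: int
    diagnostics: pd.DataFrame = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        names = ["intercept"] + self.covariates
        effects = np.concatenate([[np.nan], self.effects])
        return pd.DataFrame(
            {"beta": self.betas, "se": self.se, "wald_z": self.wald_z,
             "p": self.p, "effect": effects},
            index=names,
        )


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via QR; returns (beta, residuals, hat diagonal, R^2, s^2)."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise ValidationError("design matrix is rank deficient")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    h = (Q**2).sum(axis=1)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 0.0
    dof = X.shape[0] - X.shape[1]
    s2 = resid @ resid / dof if dof > 0 else np.nan
    return beta, resid, h, r2, s2


def _r2_of_subset(X: np.ndarray, y: np.ndarray, subset: tuple[int, ...]) -> float:
    if not subset:
        return 0.0
    design = np.column_stack([np.ones(len(y)), X[:, list(subset)]])
    _, _, _, r2, _ = _ols(design, y)
    return r2


def lmg_shares(
    design: pd.DataFrame,
    y: Sequence[float],
    max_exact: int = 10,
    n_orderings: int = 2000,
    seed: int = 0,
    allow_sampling: bool = False,
) -> dict[str, float]:
    """LMG relative importance: per covariate, the average over covariate
    orderings of its sequential R^2 increment.

    Exact subset enumeration with multiplicity weights for k <= ``max_exact``;
    beyond that, orderings are subsampled (requires ``allow_sampling``).
    """
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    k = len(cols)
    if X.shape[0] <= k + 1:
        raise ValidationError("need n > k + 1 observations")
    if k > max_exact and not allow_sampling:
        raise ValidationError(
            f"k={k} exceeds the exact enumeration bound {max_exact}; "
            "pass allow_sampling=True to subsample orderings"
        )
    if k <= max_exact:
        r2_cache: dict[tuple[int, ...], float] = {}
        for r in range(k + 1):
            for subset in combinations(range(k), r):
                r2_cache[subset] = _r2_of_subset(X, y, subset)
        shares = {}
        for j in range(k):
            total = 0.0
            others = [i for i in range(k) if i != j]
            for r in range(k):
                w = math.factorial(r) * math.factorial(k - r - 1) / math.factorial(k)
                for subset in combinations(others, r):
                    with_j = tuple(sorted(subset + (j,)))
                    total += w * (r2_cache[with_j] - r2_cache[subset])
            shares[cols[j]] = total
        return shares
    rng = np.random.default_rng(seed)
    acc = np.zeros(k)
    for _ in range(n_orderings):
        order = rng.permutation(k)
        prev = 0.0
        chosen: list[int] = []
        for j in order:
            chosen.append(j)
            r2 = _r2_of_subset(X, y, tuple(sorted(chosen)))
            acc[j] += r2 - prev
            prev = r2
    acc /= n_orderings
    return dict(zip(cols, acc))


def fit_integration(
    design: pd.DataFrame,
    counts: Sequence[float],
    pseudocount: float = 1.0,
    compute_lmg: bool = True,
    lmg_seed: int = 0,
) -> IntegrationFit:
    """OLS of ln(count + pseudocount) on the covariate table with a single
    fit-exclude-refit pass.

    Observations with leverage h > 2k/n or Cook's D > 4/(n - k - 1) in the
    initial fit are removed once (k = number of covariates), then the model
    is refit and reported on the retained observations.
    """
    cols = list(design.columns)
    k = len(cols)
    X_full = design.to_numpy(dtype=float)
    y_full = np.log(np.asarray(counts, dtype=float) + pseudocount)
    n = len(y_full)
    if n <= k + 1:
        raise ValidationError("need n > k + 1 observations")
    if not np.all(np.isfinite(X_full)):
        raise ValidationError("covariates must be finite")

    ids = list(design.index)
    Xd = np.column_stack([np.ones(n), X_full])
    beta, resid, h, r2, s2 = _ols(Xd, y_full)
    cook = resid**2 * h / (k * s2 * (1.0 - h) ** 2)
    lev_cut = 2.0 * k / n
    infl_cut = 4.0 / (n - k - 1)
    excluded: list[tuple[object, str]] = []
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if h[i] > lev_cut:
            excluded.append((ids[i], "leverage"))
            keep[i] = False
        elif cook[i] > infl_cut:
            excluded.append((ids[i], "influence"))
            keep[i] = False
    diagnostics = pd.DataFrame(
        {"h": h, "cook_d": cook, "excluded": ~keep,
         "reason": [dict(excluded).get(i, "") for i in ids]},
        index=ids,
    )

    X, y = X_full[keep], y_full[keep]
    n_kept = len(y)
    if n_kept <= k + 1:
        raise ValidationError("too few observations remain after exclusion")
    Xd = np.column_stack([np.ones(n_kept), X])
    beta, resid, h2, r2, s2 = _ols(Xd, y)
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    effects = np.expm1(beta[1:])

    vif = {}
    for j, cname in enumerate(cols):
        others = [i for i in range(k) if i != j]
        if others:
            r2_j = _r2_of_subset(
                X, X[:, j] - X[:, j].mean(), tuple(others)
            )
            vif[cname] = 1.0 / (1.0 - r2_j) if r2_j < 1.0 else float("inf")
        else:
            vif[cname] = 1.0

    lmg = (
        lmg_shares(pd.DataFrame(X, columns=cols), y, seed=lmg_seed)
        if compute_lmg
        else {}
    )
    return IntegrationFit(
        covariates=cols, betas=beta, se=se, wald_z=z, p=p, effects=effects,
        r2=float(r2), lmg=lmg, excluded=excluded, vif=vif, n=n_kept,
        diagnostics=diagnostics,
    )


def relative_importance_report(fit: IntegrationFit) -> pd.DataFrame:
    """Covariates ranked by LMG share, with shares as percent of R^2."""
    if not fit.lmg:
        raise ValidationError("fit has no LMG shares")
    items = sorted(fit.lmg.items(), key=lambda kv: -kv[1])
    total = sum(v for _, v in items)
    return pd.DataFrame(
        {
            "covariate": [c for c, _ in items],
            "lmg_share": [v for _, v in items],
            "percent_of_r2": [100.0 * v / total if total > 0 else np.nan
                              for _, v in items],
        }
    )
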