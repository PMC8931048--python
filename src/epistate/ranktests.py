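"""Rank-based association tests: Mann-Whitney U, Cuzick's test for trend,
and the promoter-occupancy vs expression tables.

Both tests are implemented from the rank formulas (tie-corrected normal
approximation) with exact enumeration for small samples and a seeded
permutation cross-check for the trend statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .states import OCCUPANCY_BUCKETS, PromoterOccupancy, occupancy_bucket

__all__ = [
    "TrendResult",
    "mann_whitney",
    "cuzick_trend",
    "occupancy_expression_table",
]


def _tie_correction(ranks_source: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tie groups."""
    n = len(ranks_source)
    if n < 2:
        return 1.0
    _, counts = np.unique(ranks_source, return_counts=True)
    return 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U with midranks; exact when n_x + n_y <= 12.

    Returns {"U": U statistic for x, "Z": standardized statistic,
    "p_two_sided": p, "exact": bool}.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[:nx].sum()
    u = r_x - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    tie = _tie_correction(pooled)
    var = nx * ny * (nx + ny + 1) / 12.0 * tie
    if var <= 0:
        return {"U": u, "Z": 0.0, "p_two_sided": 1.0, "exact": False}
    z = (u - mu) / math.sqrt(var)
    if nx + ny <= 12:
        # exact two-sided p by enumerating every split of the pooled ranks
        us = []
        idx = range(nx + ny)
        for comb in combinations(idx, nx):
            us.append(ranks[list(comb)].sum() - nx * (nx + 1) / 2.0)
        us = np.asarray(us)
        dev = abs(u - mu)
        p = float(np.mean(np.abs(us - mu) >= dev - 1e-12))
        return {"U": u, "Z": z, "p_two_sided": min(1.0, p), "exact": True}
    p = 2.0 * stats.norm.sf(abs(z))
    return {"U": u, "Z": z, "p_two_sided": min(1.0, p), "exact": False}


@dataclass
class TrendResult:
    T: float
    E_T: float
    Var_T: float
    Z: float
    p_two_sided: float
    group_sizes: tuple[int, ...]
    scores: tuple[float, ...]
    p_permutation: float | None = None


def cuzick_trend(
    groups: Sequence[Sequence[float]],
    scores: Sequence[float] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> TrendResult:
    """Cuzick's nonparametric test for trend across ordered groups.

    T = sum_i z_i * (rank sum of group i) with midranks for ties;
    E[T] = (N+1)/2 * sum z_i n_i;
    Var[T] = (N+1)/12 * (N sum z_i^2 n_i - (sum z_i n_i)^2) * tie factor.
    Set ``n_permutations`` > 0 for a seeded permutation cross-check.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two ordered groups")
    if scores is None:
        scores = list(range(1, len(groups) + 1))
    if len(scores) != len(groups):
        raise ValidationError("scores length must match number of groups")
    sizes = [len(g) for g in groups]
    if any(n == 0 for n in sizes):
        warnings.warn("empty group present in trend test")
    pooled = np.concatenate([np.asarray(list(g), dtype=float) for g in groups])
    n_total = len(pooled)
    if n_total == 0:
        raise ValidationError("no observations")
    ranks = stats.rankdata(pooled)
    z = np.asarray(scores, dtype=float)
    n = np.asarray(sizes, dtype=float)
    group_idx = np.repeat(np.arange(len(groups)), sizes)
    rank_sums = np.bincount(group_idx, weights=ranks, minlength=len(groups))
    t_stat = float((z * rank_sums).sum())
    sum_zn = float((z * n).sum())
    e_t = (n_total + 1) / 2.0 * sum_zn
    tie = _tie_correction(pooled)
    var_t = (n_total + 1) / 12.0 * (n_total * (z**2 * n).sum() - sum_zn**2) * tie
    if var_t <= 0:
        z_stat, p = 0.0, 1.0
    else:
        z_stat = (t_stat - e_t) / math.sqrt(var_t)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z_stat)))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        dev = abs(t_stat - e_t)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ranks)
            rs = np.bincount(group_idx, weights=perm, minlength=len(groups))
            if abs(float((z * rs).sum()) - e_t) >= dev - 1e-9:
                hits += 1
        p_perm = hits / n_permutations
    return TrendResult(
        t_stat, e_t, var_t, z_stat, p, tuple(sizes), tuple(float(s) for s in z),
        p_permutation=p_perm,
    )


def occupancy_expression_table(
    occ: PromoterOccupancy,
    expr: pd.DataFrame,
    genotype_map: dict[str, str],
    genotype: str = "MT",
    states: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Presence (Mann-Whitney) and occupancy-dosage (Cuzick) tests per state.

    ``expr`` is a gene x sample count matrix; expression per gene is the
    median across the genotype's samples of log(count + 1).
    """
    samples = [s for s in expr.columns if genotype_map.get(s) == genotype]
    if not samples:
        raise ValidationError(f"no samples with genotype {genotype}")
    common = [g for g in occ.genes if g in expr.index]
    if not common:
        raise ValidationError("gene universes do not overlap")
    log_expr = np.log1p(expr.loc[common, samples]).median(axis=1)
    gene_pos = {g: i for i, g in enumerate(occ.genes)}
    rows = []
    labels = states if states is not None else sorted(set(occ.labels))
    for label in labels:
        frac = occ.label_occupancy(genotype, label)
        frac = np.array([frac[gene_pos[g]] for g in common])
        present = frac > 0
        expr_vals = log_expr.to_numpy()
        row: dict = {"state": label, "n_present": int(present.sum()),
                     "n_absent": int((~present).sum())}
        if present.any() and (~present).any():
            mw = mann_whitney(expr_vals[present], expr_vals[~present])
            row.update(U=mw["U"], Z=mw["Z"], p=mw["p_two_sided"])
        else:
            warnings.warn(f"state {label}: presence test skipped (degenerate)")
            row.update(U=np.nan, Z=np.nan, p=np.nan)
        buckets = [occupancy_bucket(f) for f in frac]
        grouped = [
            expr_vals[[b == name for b in buckets]] for name in OCCUPANCY_BUCKETS
        ]
        nonempty = [(i, g) for i, g in enumerate(grouped) if len(g)]
        if len(nonempty) >= 2:
            trend = cuzick_trend(
                [g for _, g in nonempty], scores=[i + 1 for i, _ in nonempty]
            )
            row.update(trend_Z=trend.Z, trend_p=trend.p_two_sided)
        else:
            row.update(trend_Z=np.nan, trend_p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
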