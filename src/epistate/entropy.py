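"""Entropy-based diversity and specialization of single-cell accessibility
profiles, genotype comparison by the two-sample KS test, and TF-motif
accessibility ranking.

Per-cell profile p_fj is the cell's counts normalized to sum 1.  Diversity
H_j is the Shannon entropy of the profile (bits).  Feature specificity
S_f averages (p_fj / pbar_f) * log2(p_fj / pbar_f) over cells, where
pbar_f is the mean profile; specialization delta_j = sum_f p_fj * S_f.
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

__all__ = [
    "CellFeatureMatrix",
    "EntropyProfile",
    "entropy_profiles",
    "ks_two_sample",
    "genotype_heterogeneity",
    "motif_accessibility_ranking",
]


@dataclass
class CellFeatureMatrix:
    cells: list[str]
    genotypes: dict[str, str]  # cell -> {"WT", "MT"}
    features: list[str]
    counts: np.ndarray  # (n_cells, n_features), nonnegative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        totals = self.counts.sum(axis=1)
        if np.any(totals == 0):
            n_dropped = int((totals == 0).sum())
            warnings.warn(f"dropped {n_dropped} all-zero cells")
            keep = totals > 0
            self.cells = [c for c, k in zip(self.cells, keep) if k]
            self.counts = self.counts[keep]

    @classmethod
    def from_mtx(cls, mtx_path, meta_path) -> "CellFeatureMatrix":
        """MatrixMarket cell x feature counts plus a metadata TSV with
        columns cell_id, genotype (and optionally sample_id, feature list
        in a sidecar header line)."""
        from scipy.io import mmread

        counts = np.asarray(mmread(mtx_path).todense(), dtype=float)
        meta = pd.read_csv(meta_path, sep="\t")
        cells = meta["cell_id"].astype(str).tolist()
        genotypes = dict(zip(cells, meta["genotype"].astype(str)))
        features = [f"feature_{i}" for i in range(counts.shape[1])]
        return cls(cells, genotypes, features, counts)


@dataclass
class EntropyProfile:
    cells: list[str]
    features: list[str]
    diversity: np.ndarray  # H_j bits per cell
    specificity: np.ndarray  # S_f bits per feature (nan if pbar_f = 0)
    specialization: np.ndarray  # delta_j bits per cell


def entropy_profiles(m: CellFeatureMatrix) -> EntropyProfile:
    if len(m.features) < 2:
        raise ValidationError("need at least two features")
    p = m.counts / m.counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    diversity = -plogp.sum(axis=1)
    pbar = p.mean(axis=0)
    if np.any(pbar == 0):
        warnings.warn(
            f"{int((pbar == 0).sum())} features with zero mean excluded "
            "from specificity/specialization"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / pbar
        term = np.where(p > 0, ratio * np.log2(ratio), 0.0)
    specificity = np.where(pbar > 0, term.mean(axis=0), np.nan)
    usable = pbar > 0
    specialization = p[:, usable] @ specificity[usable]
    return EntropyProfile(
        list(m.cells), list(m.features), diversity, specificity, specialization
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|; exact enumeration when
    n_x + n_y <= 12, else the asymptotic Kolmogorov distribution."""
    x = np.sort(np.asarray(list(x), dtype=float))
    y = np.sort(np.asarray(list(y), dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    nx, ny = len(x), len(y)

    def _d(xs: np.ndarray, ys: np.ndarray) -> float:
        grid = np.concatenate([xs, ys])
        cdf_x = np.searchsorted(xs, grid, side="right") / len(xs)
        cdf_y = np.searchsorted(ys, grid, side="right") / len(ys)
        return float(np.abs(cdf_x - cdf_y).max())

    d = _d(x, y)
    if nx + ny <= 12:
        pooled = np.sort(np.concatenate([x, y]))
        idx = range(nx + ny)
        hits = total = 0
        for comb in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            d_perm = _d(pooled[mask], pooled[~mask])
            total += 1
            if d_perm >= d - 1e-12:
                hits += 1
        return {"D": d, "p": hits / total, "exact": True}
    ne = nx * ny / (nx + ny)
    p = float(stats.kstwobign.sf(math.sqrt(ne) * d))
    return {"D": d, "p": min(1.0, p), "exact": False}


def genotype_heterogeneity(m: CellFeatureMatrix) -> dict:
    """Per-genotype diversity and specialization distributions with KS tests
    and the direction of the median differences."""
    prof = entropy_profiles(m)
    genos = [m.genotypes[c] for c in prof.cells]
    masks = {g: np.array([x == g for x in genos]) for g in ("WT", "MT")}
    for g, mask in masks.items():
        if not mask.any():
            raise ValidationError(f"genotype {g} absent from matrix")
    div = {g: prof.diversity[mask] for g, mask in masks.items()}
    spec = {g: prof.specialization[mask] for g, mask in masks.items()}
    return {
        "profile": prof,
        "diversity": div,
        "specialization": spec,
        "ks_diversity": ks_two_sample(div["MT"], div["WT"]),
        "ks_specialization": ks_two_sample(spec["MT"], spec["WT"]),
        "median_diversity_diff": float(np.median(div["MT"]) - np.median(div["WT"])),
        "median_specialization_diff": float(
            np.median(spec["MT"]) - np.median(spec["WT"])
        ),
    }


def motif_accessibility_ranking(
    peaks_by_genotype: dict[str, Sequence],
    motif_hits: dict[str, dict[str, Sequence[bool]]],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Per motif, count of MT peaks carrying the motif minus the WT count,
    ranked descending.

    ``motif_hits[genotype][motif]`` is a boolean vector over that genotype's
    peaks.
    """
    motifs = sorted(set(motif_hits.get("MT", {})) | set(motif_hits.get("WT", {})))
    rows = []
    for motif in motifs:
        mt = int(np.sum(motif_hits.get("MT", {}).get(motif, [])))
        wt = int(np.sum(motif_hits.get("WT", {}).get(motif, [])))
        rows.append({"motif": motif, "n_mt": mt, "n_wt": wt, "delta": mt - wt})
    df = pd.DataFrame(rows).sort_values(
        ["delta", "motif"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
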