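"""Gene-body (hydroxy)methylation quantification, the dosage-vs-threshold
expression model, and the isolated gene-body hypermethylation filter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GeneModel,
    Interval,
    ValidationError,
    promoter_window,
    union_length,
)
from .states import occupancy_bucket

__all__ = [
    "DMRRecord",
    "gene_body_fraction",
    "meth_expression_model",
    "isolated_hypermethylation_filter",
]


@dataclass(frozen=True)
class DMRRecord:
    interval: Interval
    direction: str  # {"hyper", "hypo"}
    area: float
    fdr: float

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad DMR direction {self.direction!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"DMR fdr {self.fdr} outside [0, 1]")


def read_dmr_table(path) -> list[DMRRecord]:
    """TSV with columns chrom, start, end, direction, area, fdr."""
    df = pd.read_csv(path, sep="\t")
    return [
        DMRRecord(
            Interval(str(r.chrom), int(r.start), int(r.end)),
            str(r.direction), float(r.area), float(r.fdr),
        )
        for r in df.itertuples()
    ]


def gene_body_fraction(
    mc_peaks: Sequence[Interval],
    hmc_peaks: Sequence[Interval],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Fraction of each gene body covered by consensus 5mC / 5hmC peaks.

    Covered bp = length of the union of (peaks intersected with the body).
    """
    rows = []
    for g in genes:
        body = g.body
        if len(body) == 0:
            raise ValidationError(f"{g.gene_id}: zero-length gene body")
        fracs = {}
        for key, peaks in (("mc", mc_peaks), ("hmc", hmc_peaks)):
            clipped = []
            for pk in peaks:
                if pk.chrom != body.chrom:
                    continue
                s, e = max(pk.start, body.start), min(pk.end, body.end)
                if s < e:
                    clipped.append(Interval(pk.chrom, s, e))
            fracs[key] = union_length(clipped) / len(body)
        rows.append(
            {
                "gene_id": g.gene_id,
                "mc_fraction": fracs["mc"],
                "hmc_fraction": fracs["hmc"],
                "mc_bucket": occupancy_bucket(fracs["mc"]),
                "hmc_bucket": occupancy_bucket(fracs["hmc"]),
                "hmc_present": fracs["hmc"] > 0,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def meth_expression_model(
    summary: pd.DataFrame,
    expr: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """OLS of log(count + 1) on mc_fraction, hmc_present, hmc_fraction.

    Wald z = beta / SE with two-sided normal p.  The threshold pattern is
    declared when the hmc-presence coefficient rejects at ``alpha`` while
    the hmc-fraction coefficient does not.
    """
    common = summary.index.intersection(expr.index)
    if len(common) < 10:
        raise ValidationError("need >= 10 genes with covariate data")
    y = np.log1p(expr.loc[common].to_numpy(dtype=float))
    cols = ["mc_fraction", "hmc_present", "hmc_fraction"]
    X = summary.loc[common, cols].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        flat = [c for c, s in zip(cols, X.std(axis=0)) if s == 0]
        raise ValidationError(f"zero-variance covariates: {flat}")
    design = np.column_stack([np.ones(len(y)), X])
    cond = np.linalg.cond(design)
    if cond > 1e8:
        corr = np.corrcoef(X, rowvar=False)
        i, j = divmod(np.abs(corr - np.eye(len(cols))).argmax(), len(cols))
        raise ValidationError(
            f"collinear covariates (condition number {cond:.3g}): "
            f"{cols[i]} vs {cols[j]}"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    names = ["intercept"] + cols
    table = pd.DataFrame({"beta": beta, "se": se, "wald_z": z, "p": p}, index=names)
    threshold_pattern = bool(
        table.loc["hmc_present", "p"] < alpha
        and table.loc["hmc_fraction", "p"] >= alpha
    )
    dosage_pattern = bool(table.loc["mc_fraction", "p"] < alpha)
    return {
        "table": table,
        "threshold_pattern": threshold_pattern,
        "dosage_pattern": dosage_pattern,
        "n": len(y),
    }


def isolated_hypermethylation_filter(
    dmrs: Sequence[DMRRecord],
    genes: Sequence[GeneModel],
    de_up: Sequence[str],
    fdr_cut: float = 0.05,
    flank: int = 2000,
) -> list[str]:
    """Up-regulated genes whose body carries a significant hyper DMR while
    their promoter window carries none."""
    up = set(de_up)
    sig_hyper = [d for d in dmrs if d.direction == "hyper" and d.fdr < fdr_cut]
    flagged = []
    for g in genes:
        if g.gene_id not in up:
            continue
        prom = promoter_window(g, flank)
        body_hit = any(d.interval.overlaps(g.body) for d in sig_hyper)
        prom_hit = any(d.interval.overlaps(prom) for d in sig_hyper)
        if body_hit and not prom_hit:
            flagged.append(g.gene_id)
    return flagged
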