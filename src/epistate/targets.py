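"""Basal-plus-extension regulatory-domain assignment of distal CREs to
putative target genes, TAD-boundary filtering, distance structure, and the
enhancer-expression association tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, Interval, TADSet, ValidationError
from .cre import CandidateCRE
from .ranktests import cuzick_trend, mann_whitney

__all__ = [
    "RegulatoryDomain",
    "CisInteraction",
    "DISTANCE_BINS",
    "regulatory_domains",
    "assign_targets",
    "enhancer_expression_association",
    "overlap_significance",
]

DISTANCE_BINS = ("<5kb", "5-50kb", "50-200kb", "200kb-1Mb")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: Interval
    extended: Interval


@dataclass(frozen=True)
class CisInteraction:
    cre: CandidateCRE
    gene_id: str
    tss: int
    distance: int
    same_tad: bool
    distance_bin: str


def distance_bin(distance: int) -> str:
    if distance < 5_000:
        return DISTANCE_BINS[0]
    if distance < 50_000:
        return DISTANCE_BINS[1]
    if distance < 200_000:
        return DISTANCE_BINS[2]
    return DISTANCE_BINS[3]


def regulatory_domains(
    genes: Sequence[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    cap: int = 1_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal domain (TSS-5kb .. TSS+1kb, strand-oriented) extended toward
    the nearest neighboring basal boundary in each direction, capped at
    ``cap`` bp from the TSS and clipped to chromosome bounds."""
    by_chrom: dict[str, list[GeneModel]] = {}
    seen_tss: dict[tuple[str, int], str] = {}
    for g in genes:
        key = (g.chrom, g.tss)
        if key in seen_tss:
            warnings.warn(f"duplicate TSS at {key}: {seen_tss[key]} and {g.gene_id}")
        seen_tss[key] = g.gene_id
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: g.tss)
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        basals = []
        for g in glist:
            if g.strand == "+":
                s, e = g.tss - basal_up, g.tss + basal_down
            else:
                s, e = g.tss - basal_down, g.tss + basal_up
            s = max(0, s)
            if clen is not None:
                e = min(e, clen)
            basals.append((s, e))
        for i, g in enumerate(glist):
            bs, be = basals[i]
            lo = max(0, g.tss - cap)
            hi = g.tss + cap
            if clen is not None:
                hi = min(hi, clen)
            # extend to nearest neighboring basal edge, never past the cap
            left_edges = [be2 for j, (_, be2) in enumerate(basals)
                          if j != i and be2 <= bs]
            if left_edges:
                lo = max(lo, max(left_edges))
            right_edges = [bs2 for j, (bs2, _) in enumerate(basals)
                           if j != i and bs2 >= be]
            if right_edges:
                hi = min(hi, min(right_edges))
            lo = min(lo, bs)
            hi = max(hi, be)
            domains.append(
                RegulatoryDomain(
                    g.gene_id,
                    Interval(chrom, bs, be, name=g.gene_id),
                    Interval(chrom, lo, hi, name=g.gene_id),
                )
            )
    domains.sort(key=lambda d: (d.extended.chrom, d.extended.start))
    return domains


def assign_targets(
    cres: Sequence[CandidateCRE],
    domains: Sequence[RegulatoryDomain],
    genes: Sequence[GeneModel],
    tads: TADSet,
) -> dict:
    """Associate each CRE with every gene whose extended domain it overlaps,
    keeping only pairs with the CRE midpoint and the gene TSS in one TAD."""
    tss_of = {g.gene_id: g.tss for g in genes}
    chrom_of = {g.gene_id: g.chrom for g in genes}
    interactions: list[CisInteraction] = []
    dropped_no_tad = 0
    dropped_cross_tad = 0
    for cre in cres:
        iv = cre.interval
        mid = iv.midpoint
        cre_tad = tads.tad_index_at(iv.chrom, mid)
        overlapped = [
            d for d in domains
            if d.extended.chrom == iv.chrom
            and min(d.extended.end, iv.end) - max(d.extended.start, iv.start) >= 1
        ]
        for d in overlapped:
            tss = tss_of[d.gene_id]
            if cre_tad is None:
                dropped_no_tad += 1
                continue
            if tads.tad_index_at(chrom_of[d.gene_id], tss) != cre_tad:
                dropped_cross_tad += 1
                continue
            dist = abs(mid - tss)
            interactions.append(
                CisInteraction(cre, d.gene_id, tss, dist, True, distance_bin(dist))
            )
    return {
        "interactions": interactions,
        "n_dropped_no_tad": dropped_no_tad,
        "n_dropped_cross_tad": dropped_cross_tad,
    }


def enhancer_expression_association(
    interactions: Sequence[CisInteraction],
    expr: pd.DataFrame,
    genotype_map: dict[str, str],
    universe: Sequence[str],
    genotype: str = "MT",
) -> dict:
    """Presence (Mann-Whitney), enhancer-count dosage (1 / 2 / >=3, Cuzick),
    and nearest-enhancer distance-bin trend (Cuzick) against median
    log(count + 1) expression in the genotype's samples."""
    universe = list(universe)
    targets: dict[str, list[CisInteraction]] = {}
    for it in interactions:
        targets.setdefault(it.gene_id, []).append(it)
    if not set(targets) <= set(universe):
        raise ValidationError("universe must contain all target genes")
    samples = [s for s in expr.columns if genotype_map.get(s) == genotype]
    log_expr = np.log1p(expr.loc[universe, samples]).median(axis=1)

    present = np.array([g in targets for g in universe])
    out: dict = {"n_targets": int(present.sum()), "n_universe": len(universe)}
    vals = log_expr.to_numpy()
    if present.any() and (~present).any():
        out["presence"] = mann_whitney(vals[present], vals[~present])
    else:
        warnings.warn("presence test skipped: no targets or all targets")
        out["presence"] = None
        out["count_dosage"] = None
        out["distance_trend"] = None
        return out

    counts = {g: len(its) for g, its in targets.items()}
    groups = [
        [log_expr[g] for g, c in counts.items() if c == 1],
        [log_expr[g] for g, c in counts.items() if c == 2],
        [log_expr[g] for g, c in counts.items() if c >= 3],
    ]
    nonempty = [(i, g) for i, g in enumerate(groups) if g]
    if len(nonempty) >= 2:
        out["count_dosage"] = cuzick_trend(
            [g for _, g in nonempty], scores=[i + 1 for i, _ in nonempty]
        )
    else:
        out["count_dosage"] = None

    nearest = {g: min(it.distance for it in its) for g, its in targets.items()}
    bin_groups = {name: [] for name in DISTANCE_BINS}
    for g, d in nearest.items():
        bin_groups[distance_bin(d)].append(log_expr[g])
    nonempty = [
        (i, bin_groups[name]) for i, name in enumerate(DISTANCE_BINS)
        if bin_groups[name]
    ]
    if len(nonempty) >= 2:
        out["distance_trend"] = cuzick_trend(
            [g for _, g in nonempty], scores=[i + 1 for i, _ in nonempty]
        )
    else:
        out["distance_trend"] = None
    return out


def overlap_significance(
    targets: Sequence[str], de_up: Sequence[str], universe_size: int
) -> dict:
    """Upper-tail hypergeometric p for the target / up-regulated overlap."""
    t, k = set(targets), set(de_up)
    x = len(t & k)
    if len(t) > universe_size or len(k) > universe_size:
        raise ValidationError("set sizes exceed universe size")
    if x > min(len(t), len(k)):
        raise ValidationError("overlap exceeds set sizes")
    p = float(stats.hypergeom.sf(x - 1, universe_size, len(k), len(t)))
    return {"overlap": x, "n_targets": len(t), "n_de_up": len(k),
            "universe_size": universe_size, "p": p}
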