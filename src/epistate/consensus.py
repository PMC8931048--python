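"""Multi-replicate consensus peak calling.

Peaks surviving a weak p-value threshold are cross-checked against
overlapping peaks in the other replicates; evidence is combined with
Fisher's method and referred to a chi-square null.  A peak is confirmed
either by combined evidence passing the stringent threshold with enough
replicate support, or by its own p-value alone passing the stringent
threshold.  Mutually overlapping confirmed peaks are merged by union.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Interval, ValidationError, overlap_query

__all__ = ["ConsensusPeak", "combine_replicates", "fisher_combined_p"]

_TINY_P = 5e-324  # smallest positive subnormal double


@dataclass(frozen=True)
class ConsensusPeak:
    interval: Interval
    combined_p: float
    support: int
    members: tuple[tuple[int, int], ...]  # (replicate index, peak index) refs


def fisher_combined_p(pvalues: Sequence[float]) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi2(2r) upper tail."""
    x2 = -2.0 * sum(math.log(p) for p in pvalues)
    return float(stats.chi2.sf(x2, 2 * len(pvalues)))


def combine_replicates(
    peak_sets: Sequence[Sequence[Interval]],
    weak: float = 1e-4,
    stringent: float = 1e-8,
    min_support: int | None = None,
    mode: str = "narrow",
) -> list[ConsensusPeak]:
    """Consensus peaks across replicates under a weak/stringent double threshold.

    Parameters
    ----------
    peak_sets
        One list of p-valued Intervals per replicate.
    weak, stringent
        Discard peaks with p >= weak; confirmation requires combined (or own)
        p below stringent.
    min_support
        Minimum number of replicates (the peak's own plus supporters) for
        confirmation via combined evidence.  Defaults to majority,
        ceil(R / 2).
    mode
        ``narrow`` or ``broad``; metadata only — the arithmetic is identical.
    """
    if not peak_sets:
        raise ValidationError("need at least one replicate peak set")
    if not (0.0 < stringent <= weak < 1.0):
        raise ValidationError("need 0 < stringent <= weak < 1")
    if mode not in ("narrow", "broad"):
        raise ValidationError(f"unknown mode {mode!r}")
    n_rep = len(peak_sets)
    if min_support is None:
        min_support = math.ceil(n_rep / 2)

    # weak filter, clamping p == 0
    surviving: list[tuple[int, int, Interval]] = []  # (rep, idx-in-rep, peak)
    for r, peaks in enumerate(peak_sets):
        for i, pk in enumerate(peaks):
            p = pk.pvalue
            if p is None:
                raise ValidationError(f"replicate {r} peak {i} lacks a p-value")
            if p == 0.0:
                warnings.warn("p-value of 0 clamped to smallest positive double")
                p = _TINY_P
            if p < weak:
                surviving.append((r, i, Interval(
                    pk.chrom, pk.start, pk.end, score=pk.score, pvalue=p, name=pk.name
                )))

    ivs = [s[2] for s in surviving]
    pairs = overlap_query(ivs, ivs, min_bp=1) if ivs else []
    supporters: dict[int, list[int]] = {k: [] for k in range(len(ivs))}
    for i, j in pairs:
        if i != j and surviving[i][0] != surviving[j][0]:
            supporters[i].append(j)

    confirmed: list[int] = []
    combined: dict[int, float] = {}
    for k, (r, i, pk) in enumerate(surviving):
        sup = supporters[k]
        ps = [pk.pvalue] + [surviving[s][2].pvalue for s in sup]
        cp = fisher_combined_p(ps)
        combined[k] = cp
        by_group = cp < stringent and (len(sup) + 1) >= min_support
        alone = pk.pvalue < stringent
        if by_group or alone:
            confirmed.append(k)

    # merge mutually overlapping confirmed peaks by union
    order = sorted(confirmed, key=lambda k: (ivs[k].chrom, ivs[k].start, ivs[k].end))
    out: list[ConsensusPeak] = []
    cluster: list[int] = []

    def _flush(cluster: list[int]) -> None:
        chrom = ivs[cluster[0]].chrom
        start = min(ivs[k].start for k in cluster)
        end = max(ivs[k].end for k in cluster)
        cp = min(combined[k] for k in cluster)
        reps = {surviving[k][0] for k in cluster}
        members = tuple(sorted((surviving[k][0], surviving[k][1]) for k in cluster))
        out.append(
            ConsensusPeak(
                Interval(chrom, start, end, pvalue=max(cp, _TINY_P)),
                combined_p=cp,
                support=len(reps),
                members=members,
            )
        )

    cur_chrom, cur_end = None, -1
    for k in order:
        iv = ivs[k]
        if cluster and iv.chrom == cur_chrom and iv.start < cur_end:
            cluster.append(k)
            cur_end = max(cur_end, iv.end)
        else:
            if cluster:
                _flush(cluster)
            cluster = [k]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cluster:
        _flush(cluster)
    return out
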