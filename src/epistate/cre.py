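"""Genotype-specific candidate cis-regulatory element (CRE) discovery,
catalog annotation, known-motif scanning, and interval-catalog enrichment.

A candidate CRE is an accessible (ATAC) consensus region co-marked by
H3K27ac in the mutant genotype with no counterpart in the wild type; the
element geometry is the ATAC peak.  Distal candidates avoid all promoter
windows and form the default downstream set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GeneModel, Interval, ValidationError, overlap_query, promoter_window

__all__ = [
    "CandidateCRE",
    "EnrichmentResult",
    "PWM",
    "read_jaspar_pwms",
    "genotype_specific_cres",
    "annotate_catalog",
    "pwm_scan",
    "interval_enrichment",
]


@dataclass
class CandidateCRE:
    interval: Interval
    genotype: str = "MT-specific"
    distal: bool = True
    annotated: bool = False
    super_enhancer: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    a: int  # foreground hits
    b: int  # foreground non-hits
    c: int  # background hits
    d: int  # background non-hits
    effect_size: float
    p: float


def _co_marked(atac: Sequence[Interval], k27ac: Sequence[Interval]) -> list[Interval]:
    """ATAC peaks overlapping (>= 1 bp) at least one H3K27ac peak."""
    hits = {i for i, _ in overlap_query(list(atac), list(k27ac), min_bp=1)}
    return [atac[i] for i in sorted(hits)]


def genotype_specific_cres(
    atac_mt: Sequence[Interval],
    k27ac_mt: Sequence[Interval],
    atac_wt: Sequence[Interval],
    k27ac_wt: Sequence[Interval],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    max_wt_overlap: int = 0,
) -> list[CandidateCRE]:
    """MT-specific co-marked elements with a distal flag.

    ``max_wt_overlap`` is the largest tolerated overlap (bp) with any WT
    co-marked region; 0 means strictly no overlap.
    """
    mt_co = _co_marked(list(atac_mt), list(k27ac_mt))
    if not mt_co:
        warnings.warn("no MT co-marked regions found")
        return []
    wt_co = _co_marked(list(atac_wt), list(k27ac_wt))
    if wt_co:
        excluded = {
            i for i, j in overlap_query(mt_co, wt_co, min_bp=max_wt_overlap + 1)
        }
    else:
        excluded = set()
    promoters = [promoter_window(g, flank) for g in genes]
    specific = [iv for i, iv in enumerate(mt_co) if i not in excluded]
    prox = {i for i, _ in overlap_query(specific, promoters, min_bp=1)}
    return [
        CandidateCRE(iv, distal=(i not in prox)) for i, iv in enumerate(specific)
    ]


def annotate_catalog(
    cres: Sequence[CandidateCRE],
    catalog: Sequence[Interval] | None = None,
    se_catalog: Sequence[Interval] | None = None,
) -> dict:
    """Flag CREs overlapping (>= 1 bp) catalog / super-enhancer regions."""
    ivs = [c.interval for c in cres]
    if catalog:
        hit = {i for i, _ in overlap_query(ivs, list(catalog), min_bp=1)}
        for i, c in enumerate(cres):
            c.annotated = i in hit
    if se_catalog:
        hit = {i for i, _ in overlap_query(ivs, list(se_catalog), min_bp=1)}
        for i, c in enumerate(cres):
            c.super_enhancer = i in hit
    n = len(cres)
    return {
        "n": n,
        "fraction_annotated": (sum(c.annotated for c in cres) / n) if n else 0.0,
        "fraction_super_enhancer": (sum(c.super_enhancer for c in cres) / n) if n else 0.0,
    }


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix of base probabilities with a background."""

    name: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudo: float = 1e-3) -> np.ndarray:
        p = np.clip(self.matrix, pseudo, None)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def read_jaspar_pwms(path) -> list[PWM]:
    """Read JASPAR-format motif text (count matrices) into probability PWMs."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        probs = (counts + 0.25) / (counts.sum(axis=1, keepdims=True) + 1.0)
        out.append(PWM(m.name or m.matrix_id, probs))
    return out


def _scan_one(seq: str, lo: np.ndarray) -> float:
    """Maximum log-odds score over all offsets of one strand; -inf if the
    sequence is shorter than the motif.  N scores 0 at its position."""
    w = lo.shape[0]
    n = len(seq)
    if n < w:
        return -np.inf
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    best = -np.inf
    for off in range(n - w + 1):
        window = idx[off : off + w]
        score = 0.0
        for p, b in enumerate(window):
            if b >= 0:
                score += lo[p, b]
        if score > best:
            best = score
    return best


def pwm_scan(
    sequences: Sequence[str],
    pwm: PWM,
    score_frac: float = 0.8,
) -> list[bool]:
    """Hit per sequence: max log-odds over both strands and all offsets
    reaches ``score_frac`` of the maximum attainable score."""
    if not (0.0 < score_frac <= 1.0):
        raise ValidationError("score_frac must be in (0, 1]")
    lo = pwm.log_odds()
    max_score = lo.max(axis=1).sum()
    cutoff = score_frac * max_score
    hits = []
    for seq in sequences:
        seq = seq.upper()
        rc = seq.translate(_COMPLEMENT)[::-1]
        best = max(_scan_one(seq, lo), _scan_one(rc, lo))
        hits.append(bool(best >= cutoff - 1e-9))
    return hits


def interval_enrichment(
    foreground: Sequence[Interval],
    background: Sequence[Interval],
    catalog: dict[str, Sequence[Interval]],
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of each catalog's regions in the foreground
    versus a matched background, ranked by p then descending effect size."""
    if not background:
        raise ValidationError("background must be nonempty")
    fg = list(foreground)
    bg = list(background)
    results = []
    for label, regions in catalog.items():
        regions = list(regions)
        a = len({i for i, _ in overlap_query(fg, regions, min_bp=1)})
        c = len({i for i, _ in overlap_query(bg, regions, min_bp=1)})
        b = len(fg) - a
        d = len(bg) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        fg_rate = a / len(fg) if fg else 0.0
        bg_rate = c / len(bg)
        effect = fg_rate / bg_rate if bg_rate > 0 else float("inf")
        results.append(EnrichmentResult(label, a, b, c, d, effect, float(p)))
    results.sort(key=lambda r: (r.p, -r.effect_size))
    return results
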