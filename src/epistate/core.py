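"""Genomic coordinate types, interval algebra, and BED/GFF readers and writers.

All coordinates are 0-based half-open (BED convention) internally.  GFF3
input (1-based, closed) is converted on read.  Strand affects only TSS
derivation, never interval arithmetic.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "Interval",
    "GeneModel",
    "TADSet",
    "ValidationError",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_genes_gff3",
    "write_genes_gff3",
    "overlap_query",
    "promoter_window",
    "merge_intervals",
    "union_length",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries the offending line number."""


@dataclass(frozen=True)
class Interval:
    """Genomic span with optional score / p-value / name annotations."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    pvalue: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"pvalue {self.pvalue} outside (0, 1]")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """Gene with a transcript span and strand-derived TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: Interval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValidationError(
                f"{self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body {self.body.start}-{self.body.end}"
            )


@dataclass
class GenomeLayout:
    """Chromosome names/lengths plus a fixed binning of the genome."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    bin_width: int = 200

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        for c in self.chrom_names:
            if self.chrom_lengths.get(c, 0) <= 0:
                raise ValidationError(f"chromosome {c} has non-positive length")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_width)

    def bin_index(self, pos: int) -> int:
        return pos // self.bin_width

    def bin_range(self, iv: Interval) -> tuple[int, int]:
        """Half-open bin index range covering the interval (clipped)."""
        lo = iv.start // self.bin_width
        hi = math.ceil(iv.end / self.bin_width)
        return lo, min(hi, self.n_bins(iv.chrom))

    def bin_interval(self, chrom: str, b: int) -> Interval:
        start = b * self.bin_width
        end = min(start + self.bin_width, self.chrom_lengths[chrom])
        return Interval(chrom, start, end)

    def mask_from_intervals(self, chrom: str, ivs: Iterable[Interval]) -> np.ndarray:
        mask = np.zeros(self.n_bins(chrom), dtype=bool)
        for iv in ivs:
            if iv.chrom != chrom:
                continue
            lo, hi = self.bin_range(iv)
            mask[lo:hi] = True
        return mask


class TADSet:
    """Sorted, pairwise-disjoint topologically associating domains."""

    def __init__(self, tads: Sequence[Interval]):
        self.by_chrom: dict[str, list[Interval]] = {}
        for iv in sorted(tads, key=lambda t: (t.chrom, t.start)):
            self.by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self.by_chrom.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"TADs overlap on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        self._starts = {c: [iv.start for iv in ivs] for c, ivs in self.by_chrom.items()}

    @property
    def tads(self) -> list[Interval]:
        return [iv for ivs in self.by_chrom.values() for iv in ivs]

    def tad_index_at(self, chrom: str, pos: int) -> int | None:
        """Index of the TAD containing position, or None if uncovered."""
        ivs = self.by_chrom.get(chrom)
        if not ivs:
            return None
        i = bisect_right(self._starts[chrom], pos) - 1
        if i >= 0 and ivs[i].start <= pos < ivs[i].end:
            return i
        return None

    def same_tad(self, chrom_a: str, pos_a: int, chrom_b: str, pos_b: int) -> bool:
        if chrom_a != chrom_b:
            return False
        ia = self.tad_index_at(chrom_a, pos_a)
        ib = self.tad_index_at(chrom_b, pos_b)
        return ia is not None and ia == ib


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DIALECTS = ("bed3", "bed6", "narrowpeak")


def read_bed(path, dialect: str = "bed3") -> list[Interval]:
    """Read a BED-family file into sorted Intervals.

    ``narrowpeak`` expects the standard 10-column layout whose 8th column is
    -log10(p); it is converted to a plain p-value (``10**-col``).
    """
    dialect = dialect.lower().replace("-", "")
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown BED dialect {dialect!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            if start < 0 or start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end} (or negative)"
                )
            name = cols[3] if dialect != "bed3" and len(cols) > 3 and cols[3] != "." else None
            score = None
            if dialect != "bed3" and len(cols) > 4 and cols[4] not in (".", ""):
                try:
                    score = float(cols[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad score {cols[4]!r}") from None
            pvalue = None
            if dialect == "narrowpeak":
                if len(cols) < 8:
                    raise ParseError(f"{path}:{lineno}: narrowPeak needs >= 8 columns")
                try:
                    neglog_p = float(cols[7])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad -log10(p) {cols[7]!r}") from None
                pvalue = min(1.0, 10.0 ** (-neglog_p))
                pvalue = max(pvalue, 5e-324)
            out.append(Interval(chrom, start, end, score=score, pvalue=pvalue, name=name))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(path, intervals: Sequence[Interval], dialect: str = "bed3") -> None:
    dialect = dialect.lower().replace("-", "")
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown BED dialect {dialect!r}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                continue
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            if dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")
            else:  # narrowpeak
                neglog_p = -math.log10(iv.pvalue) if iv.pvalue else 0.0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\t"
                    f"0\t{neglog_p:.6g}\t-1\t-1\n"
                )


def read_genes_gff3(path) -> list[GeneModel]:
    """Read gene features from GFF3 (1-based closed -> 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if cols[2] != "gene":
                continue
            try:
                start = int(cols[3]) - 1
                end = int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            strand = cols[6]
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene_{lineno}")
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(gene_id, cols[0], strand, tss, Interval(cols[0], start, end))
            )
    genes.sort(key=lambda g: (g.chrom, g.body.start))
    return genes


def write_genes_gff3(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.body.start)):
            fh.write(
                f"{g.chrom}\tepistate\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def overlap_query(
    a: Sequence[Interval], b: Sequence[Interval], min_bp: int = 1
) -> list[tuple[int, int]]:
    """All index pairs (i, j) with a[i], b[j] on the same chromosome and
    overlap length >= min_bp.  Sorted-sweep; output ordered by (i, j)."""
    import heapq

    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    by_chrom_a: dict[str, list[tuple[int, int, int]]] = {}
    by_chrom_b: dict[str, list[tuple[int, int, int]]] = {}
    for src, store in ((a, by_chrom_a), (b, by_chrom_b)):
        for idx, iv in enumerate(src):
            store.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    pairs: list[tuple[int, int]] = []
    for chrom, a_list in by_chrom_a.items():
        b_list = by_chrom_b.get(chrom)
        if not b_list:
            continue
        a_list.sort()
        b_list.sort()
        active: list[tuple[int, int, int]] = []  # heap keyed by end
        bp = 0
        for a_start, a_end, i in a_list:
            while bp < len(b_list) and b_list[bp][0] < a_end:
                bs, be, j = b_list[bp]
                heapq.heappush(active, (be, bs, j))
                bp += 1
            # b intervals ending at or before a_start can never overlap later
            # a's either (a's are start-sorted), unless min_bp reaches them
            while active and active[0][0] <= a_start:
                heapq.heappop(active)
            for be, bs, j in active:
                if min(a_end, be) - max(a_start, bs) >= min_bp:
                    pairs.append((i, j))
    pairs.sort()
    return pairs


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted disjoint list (annotations dropped)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def promoter_window(
    gene: GeneModel, flank: int = 2000, chrom_length: int | None = None
) -> Interval:
    """[TSS - flank, TSS + flank), clipped to chromosome bounds."""
    if flank <= 0:
        raise ValidationError("flank must be > 0")
    start = max(0, gene.tss - flank)
    end = gene.tss + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return Interval(gene.chrom, start, end, name=gene.gene_id)
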