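"""Binarization, chromatin-state model fitting/decoding, promoter occupancy,
and the genotype state contrast.

One model is learned on all samples concatenated (shared state vocabulary
across genotypes), then decoded per sample.  Semantic labels are a pure
function of the emission matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GeneModel, GenomeLayout, ValidationError, promoter_window
from .hmm import BernoulliHMM

__all__ = [
    "HMM_MARKS",
    "STATE_LABELS",
    "BinarizedTracks",
    "ChromStateModel",
    "StateMap",
    "PromoterOccupancy",
    "OCCUPANCY_BUCKETS",
    "binarize",
    "fit_hmm",
    "decode",
    "label_states",
    "genotype_contrast",
    "promoter_occupancy",
    "occupancy_bucket",
    "select_n_states",
]

HMM_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "ATAC")

STATE_LABELS = (
    "active_promoter",
    "poised_promoter",
    "active_enhancer",
    "inactive_enhancer",
    "repressed",
    "quiescent",
    "accessible_only",
)

# six labels the model must discriminate to be considered adequate
_CORE_LABELS = frozenset(STATE_LABELS[:6])

OCCUPANCY_BUCKETS = ("0", "(0-25]", "(25-50]", "(50-75]", "(75-100]")


@dataclass
class BinarizedTracks:
    """sample x bin x mark boolean matrix plus sample/genotype bookkeeping."""

    samples: list[str]
    genotypes: dict[str, str]  # sample -> {"WT", "MT"}
    marks: tuple[str, ...]
    layout: GenomeLayout
    # per sample: {chrom: (n_bins, M) bool array}
    matrix: dict[str, dict[str, np.ndarray]]

    def sequences(self) -> tuple[list[np.ndarray], list[tuple[str, str]]]:
        """Flatten to per-(sample, chrom) sequences in deterministic order."""
        seqs, keys = [], []
        for s in self.samples:
            for chrom in self.layout.chrom_names:
                seqs.append(self.matrix[s][chrom])
                keys.append((s, chrom))
        return seqs, keys


@dataclass
class ChromStateModel:
    """Fitted K-state product-Bernoulli model with semantic state labels."""

    hmm: BernoulliHMM
    marks: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def K(self) -> int:
        return self.hmm.K

    @property
    def emissions(self) -> np.ndarray:
        return self.hmm.emissions

    @property
    def loglik(self) -> float:
        return self.hmm.loglik

    def states_with_label(self, label: str) -> list[int]:
        if label not in STATE_LABELS:
            raise ValidationError(f"unknown state label {label!r}")
        return [k for k, l in enumerate(self.labels) if l == label]

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "marks": list(self.marks),
            "labels": list(self.labels),
            "emissions": self.hmm.emissions.tolist(),
            "transitions": self.hmm.transitions.tolist(),
            "initial": self.hmm.initial.tolist(),
            "loglik": self.loglik,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ChromStateModel":
        with open(path) as fh:
            d = json.load(fh)
        hmm = BernoulliHMM(
            d["K"],
            np.array(d["emissions"]),
            np.array(d["transitions"]),
            np.array(d["initial"]),
            loglik=d.get("loglik", float("nan")),
        )
        return cls(hmm, tuple(d["marks"]), tuple(d["labels"]))


@dataclass
class StateMap:
    """Decoded per-sample state paths and per-genotype state frequencies."""

    layout: GenomeLayout
    samples: list[str]
    genotypes: dict[str, str]
    K: int
    # per sample: {chrom: (n_bins,) int array}
    paths: dict[str, dict[str, np.ndarray]]
    # per genotype: {chrom: (n_bins, K) frequency array}
    freqs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.freqs:
            self.freqs = {}
            for geno in ("WT", "MT"):
                members = [s for s in self.samples if self.genotypes[s] == geno]
                if not members:
                    continue
                per_chrom = {}
                for chrom in self.layout.chrom_names:
                    stack = np.stack([self.paths[s][chrom] for s in members])
                    freq = np.zeros((stack.shape[1], self.K))
                    for k in range(self.K):
                        freq[:, k] = (stack == k).mean(axis=0)
                    per_chrom[chrom] = freq
                self.freqs[geno] = per_chrom

    def consensus_path(self, genotype: str, chrom: str) -> np.ndarray:
        """Modal state across the genotype's samples; ties to lowest index."""
        return self.freqs[genotype][chrom].argmax(axis=1)


# ---------------------------------------------------------------------------


def binarize(
    counts: dict[str, dict[str, np.ndarray]],
    layout: GenomeLayout,
    genotypes: dict[str, str],
    marks: Sequence[str] = HMM_MARKS,
    p_threshold: float = 1e-4,
) -> BinarizedTracks:
    """Poisson upper-tail binarization of per-bin counts.

    A bin is flagged iff P(X >= x) < p_threshold under a Poisson whose rate
    is that sample/mark's genome-wide mean count per bin.
    """
    if not (0 < p_threshold < 1):
        raise ValidationError("p_threshold must be in (0, 1)")
    samples = sorted(counts)
    matrix: dict[str, dict[str, np.ndarray]] = {}
    for s in samples:
        per_chrom_counts = counts[s]
        arrs = [np.asarray(per_chrom_counts[c]) for c in layout.chrom_names]
        genome = np.concatenate(arrs, axis=0)  # (total_bins, M)
        if np.any(genome < 0):
            raise ValidationError(f"sample {s}: negative counts")
        lam = genome.mean(axis=0)  # per mark
        for m, mark in enumerate(marks):
            if lam[m] == 0:
                warnings.warn(f"sample {s} mark {mark}: all-zero track")
        matrix[s] = {}
        for chrom, arr in zip(layout.chrom_names, arrs):
            flags = np.zeros(arr.shape, dtype=bool)
            for m in range(arr.shape[1]):
                if lam[m] > 0:
                    # P(X >= x) = sf(x - 1)
                    tail = stats.poisson.sf(arr[:, m] - 1, lam[m])
                    flags[:, m] = tail < p_threshold
            matrix[s][chrom] = flags
    return BinarizedTracks(samples, dict(genotypes), tuple(marks), layout, matrix)


def label_states(phi: np.ndarray, marks: Sequence[str] = HMM_MARKS,
                 high: float = 0.5) -> tuple[str, ...]:
    """Semantic label per state from emission probabilities.

    Rule order: active promoter (K4me3 & K27ac), poised promoter (K4me3 &
    K27me3), active enhancer (K4me1 & K27ac, K4me3 low), inactive enhancer
    (K4me1 alone among histone activity marks), repressed (K27me3 alone),
    accessible-only (ATAC only), quiescent (all low); otherwise nearest
    prototype by L1 distance.
    """
    idx = {m: i for i, m in enumerate(marks)}
    k4me1, k4me3 = idx["H3K4me1"], idx["H3K4me3"]
    k27ac, k27me3, atac = idx["H3K27ac"], idx["H3K27me3"], idx["ATAC"]

    prototypes = {
        "active_promoter": {k4me3: 1, k27ac: 1, atac: 1, k4me1: 0, k27me3: 0},
        "poised_promoter": {k4me3: 1, k27me3: 1, atac: 0, k4me1: 0, k27ac: 0},
        "active_enhancer": {k4me1: 1, k27ac: 1, atac: 1, k4me3: 0, k27me3: 0},
        "inactive_enhancer": {k4me1: 1, k4me3: 0, k27ac: 0, k27me3: 0, atac: 0},
        "repressed": {k27me3: 1, k4me1: 0, k4me3: 0, k27ac: 0, atac: 0},
        "accessible_only": {atac: 1, k4me1: 0, k4me3: 0, k27ac: 0, k27me3: 0},
        "quiescent": {k4me1: 0, k4me3: 0, k27ac: 0, k27me3: 0, atac: 0},
    }

    labels = []
    for row in phi:
        h = row >= high
        if h[k4me3] and h[k27ac]:
            labels.append("active_promoter")
        elif h[k4me3] and h[k27me3]:
            labels.append("poised_promoter")
        elif h[k4me1] and h[k27ac] and not h[k4me3]:
            labels.append("active_enhancer")
        elif h[k4me1] and not (h[k4me3] or h[k27ac] or h[k27me3]):
            labels.append("inactive_enhancer")
        elif h[k27me3] and not (h[k4me1] or h[k4me3] or h[k27ac]):
            labels.append("repressed")
        elif h[atac] and not (h[k4me1] or h[k4me3] or h[k27ac] or h[k27me3]):
            labels.append("accessible_only")
        elif not h.any():
            labels.append("quiescent")
        else:
            best, best_d = None, np.inf
            for name, proto in prototypes.items():
                d = sum(abs(row[m] - v) for m, v in proto.items())
                if d < best_d:
                    best, best_d = name, d
            labels.append(best)
    return tuple(labels)


def fit_hmm(
    tracks: BinarizedTracks,
    K: int = 7,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    enforce_bounds: bool = True,
) -> ChromStateModel:
    """Learn a shared K-state model from all samples' binarized sequences."""
    if enforce_bounds and not (5 <= K <= 15):
        warnings.warn(f"K={K} outside the recommended 5..15 range")
    seqs, _ = tracks.sequences()
    hmm = BernoulliHMM.fit(
        seqs, K, n_restarts=n_restarts, seed=seed, tol=tol, max_iter=max_iter
    )
    labels = label_states(hmm.emissions, tracks.marks)
    return ChromStateModel(hmm, tracks.marks, labels)


def decode(
    model: ChromStateModel, tracks: BinarizedTracks, method: str = "viterbi"
) -> StateMap:
    """Per-sample decoding (Viterbi path or per-bin posterior argmax)."""
    if model.marks != tracks.marks:
        raise ValidationError(
            f"mark order mismatch: model {model.marks} vs tracks {tracks.marks}"
        )
    if method not in ("viterbi", "posterior"):
        raise ValidationError(f"unknown decode method {method!r}")
    paths: dict[str, dict[str, np.ndarray]] = {}
    for s in tracks.samples:
        paths[s] = {}
        for chrom in tracks.layout.chrom_names:
            seq = tracks.matrix[s][chrom]
            if method == "viterbi":
                paths[s][chrom] = model.hmm.viterbi(seq)
            else:
                paths[s][chrom] = model.hmm.posterior(seq).argmax(axis=1)
    return StateMap(
        tracks.layout, list(tracks.samples), dict(tracks.genotypes), model.K, paths
    )


def _promoter_bins(
    gene: GeneModel, layout: GenomeLayout, flank: int
) -> np.ndarray | None:
    """Bin indices of the promoter window, strand-oriented (upstream first).

    The window is centered on the bin containing the TSS and spans
    flank // bin_width bins to each side, so every gene maps onto the same
    positional grid regardless of TSS phase within its bin.
    """
    w = flank // layout.bin_width
    tss_bin = gene.tss // layout.bin_width
    lo, hi = tss_bin - w, tss_bin + w + 1
    if lo < 0 or hi > layout.n_bins(gene.chrom):
        return None
    bins = np.arange(lo, hi)
    return bins if gene.strand == "+" else bins[::-1]


def genotype_contrast(
    state_map: StateMap,
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> dict:
    """Positionwise MT - WT state-frequency delta over promoter windows plus
    the WT-consensus -> MT-consensus transition count matrix."""
    layout = state_map.layout
    K = state_map.K
    width = 2 * (flank // layout.bin_width) + 1
    delta_sum = np.zeros((width, K))
    delta_n = np.zeros(width)
    transition = np.zeros((K, K), dtype=np.int64)
    skipped = 0
    for g in genes:
        bins = _promoter_bins(g, layout, flank)
        if bins is None or len(bins) != width:
            skipped += 1
            continue
        f_wt = state_map.freqs["WT"][g.chrom][bins]
        f_mt = state_map.freqs["MT"][g.chrom][bins]
        delta_sum += f_mt - f_wt
        delta_n += 1
        cons_wt = f_wt.argmax(axis=1)
        cons_mt = f_mt.argmax(axis=1)
        np.add.at(transition, (cons_wt, cons_mt), 1)
    if skipped:
        warnings.warn(f"{skipped} genes skipped (promoter outside decoded region)")
    with np.errstate(invalid="ignore"):
        delta = delta_sum / np.maximum(delta_n, 1)[:, None]
    return {"delta": delta, "transition_matrix": transition, "n_genes_skipped": skipped}


def occupancy_bucket(fraction: float) -> str:
    """Bucket a promoter-occupancy fraction into the five closed-right bins."""
    if fraction == 0:
        return OCCUPANCY_BUCKETS[0]
    for hi, name in ((0.25, "(0-25]"), (0.50, "(25-50]"), (0.75, "(50-75]")):
        if fraction <= hi:
            return name
    return "(75-100]"


@dataclass
class PromoterOccupancy:
    """Per-gene, per-genotype fraction of promoter bins in each state."""

    genes: list[str]
    K: int
    labels: tuple[str, ...]
    # genotype -> (n_genes, K) fractions
    fractions: dict[str, np.ndarray]

    def label_occupancy(self, genotype: str, label: str) -> np.ndarray:
        """Summed occupancy over all states carrying the label, per gene."""
        cols = [k for k, l in enumerate(self.labels) if l == label]
        if not cols:
            raise ValidationError(f"label {label!r} absent from model")
        return self.fractions[genotype][:, cols].sum(axis=1)

    def buckets(self, genotype: str, label: str) -> list[str]:
        return [occupancy_bucket(f) for f in self.label_occupancy(genotype, label)]


def promoter_occupancy(
    state_map: StateMap,
    genes: Sequence[GeneModel],
    model: ChromStateModel,
    flank: int = 2000,
) -> PromoterOccupancy:
    """Fraction of promoter bins in each state, averaged over samples,
    computed separately per genotype."""
    layout = state_map.layout
    K = state_map.K
    kept_genes: list[str] = []
    rows = {"WT": [], "MT": []}
    for g in genes:
        bins = _promoter_bins(g, layout, flank)
        if bins is None:
            continue
        kept_genes.append(g.gene_id)
        for geno in ("WT", "MT"):
            rows[geno].append(state_map.freqs[geno][g.chrom][bins].mean(axis=0))
    fractions = {geno: np.array(rows[geno]).reshape(len(kept_genes), K)
                 for geno in ("WT", "MT")}
    return PromoterOccupancy(kept_genes, K, model.labels, fractions)


def select_n_states(
    tracks: BinarizedTracks,
    k_range: Sequence[int] = range(5, 16),
    n_restarts: int = 2,
    seed: int = 0,
    max_iter: int = 100,
) -> dict:
    """Fit a model per K and report BIC plus semantic label coverage.

    A model "discriminates" if all six core labels are assigned to at least
    one state.  Ties in the coverage criterion resolve toward smaller K.
    """
    seqs, _ = tracks.sequences()
    report = []
    for K in k_range:
        model = fit_hmm(
            tracks, K, n_restarts=n_restarts, seed=seed + K, max_iter=max_iter,
            enforce_bounds=False,
        )
        covered = _CORE_LABELS <= set(model.labels)
        report.append(
            {
                "K": K,
                "loglik": model.loglik,
                "bic": model.hmm.bic(seqs),
                "labels": model.labels,
                "discriminates": covered,
                "model": model,
            }
        )
    discriminating = [r for r in report if r["discriminates"]]
    chosen = min(discriminating, key=lambda r: r["K"]) if discriminating else min(
        report, key=lambda r: r["bic"]
    )
    return {"report": report, "chosen": chosen}
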