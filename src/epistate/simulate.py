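"""Seeded generator for a complete toy multi-omics study with planted
ground truth.

The generator samples per-sample chromatin-state paths from a known
product-Bernoulli HMM, applies genotype-specific promoter-state overrides
for designated up/down-regulated genes (poised <-> active), plants
MT-specific distal enhancers inside the TADs of chosen target genes, and
derives every downstream input (peak sets, count tracks, methylation peaks,
DMR table, expression matrix, single-cell counts) from those latent truths,
so each pipeline stage can be scored against the planted configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomeLayout,
    Interval,
    TADSet,
    promoter_window,
)
from .hmm import BernoulliHMM
from .methylation import DMRRecord
from .states import HMM_MARKS, STATE_LABELS
from .targets import regulatory_domains

__all__ = [
    "GenerationError",
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "default_true_model",
    "simulate_study",
    "simulate_peak_pvalues",
]

# planted state order mirrors the semantic label vocabulary
TRUE_STATE_LABELS = (
    "active_promoter",
    "poised_promoter",
    "active_enhancer",
    "inactive_enhancer",
    "repressed",
    "accessible_only",
    "quiescent",
)
_ACTIVE = TRUE_STATE_LABELS.index("active_promoter")
_POISED = TRUE_STATE_LABELS.index("poised_promoter")
_QUIESCENT = TRUE_STATE_LABELS.index("quiescent")


class GenerationError(RuntimeError):
    """Raised when a planted configuration cannot be realized."""


def default_true_model() -> BernoulliHMM:
    """Planted 7-state model over (H3K4me1, H3K4me3, H3K27ac, H3K27me3, ATAC).

    Quiescent-heavy transitions keep marked states sparse so that
    cross-sample coincidence of peaks is rare.
    """
    phi = np.array(
        [
            # K4me1  K4me3  K27ac  K27me3 ATAC
            [0.30, 0.92, 0.92, 0.05, 0.90],  # active promoter
            [0.30, 0.90, 0.05, 0.85, 0.25],  # poised promoter
            [0.90, 0.10, 0.92, 0.05, 0.90],  # active enhancer
            [0.85, 0.08, 0.08, 0.10, 0.12],  # inactive enhancer
            [0.08, 0.05, 0.05, 0.90, 0.05],  # repressed
            [0.08, 0.08, 0.08, 0.05, 0.90],  # accessible only
            [0.04, 0.03, 0.03, 0.05, 0.04],  # quiescent
        ]
    )
    K = phi.shape[0]
    A = np.zeros((K, K))
    for k in range(K):
        if k == _QUIESCENT:
            A[k] = 0.03 / (K - 1)
            A[k, k] = 0.97
        else:
            A[k] = 0.005 / (K - 2)
            A[k, k] = 0.85
            A[k, _QUIESCENT] = 0.145
    pi = np.full(K, 0.02)
    pi[_QUIESCENT] = 1.0 - 0.02 * (K - 1)
    return BernoulliHMM(K, phi, A, pi)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    bin_width: int = 200
    n_genes: int = 400
    n_samples_per_genotype: int = 8
    n_up_genes: int = 80
    n_down_genes: int = 30
    n_planted_enhancers: int = 60
    enhancer_width: int = 800
    tad_width: int = 500_000
    # expression model: counts = round(exp(b0 + ba*occ% + bm*meth% + be*enh
    #                                      + bh*hmc_present + eps) - 1)
    beta0: float = 2.0
    beta_active: float = 0.02  # per percentage point of active occupancy
    beta_meth: float = 0.01  # per percentage point of gene-body 5mC coverage
    beta_enh: float = 1.0  # enhancer presence
    beta_hmc: float = 0.5  # 5hmC presence (threshold-pattern effect)
    sigma: float = 0.5
    # track / peak generation
    lam_background: float = 0.25
    lam_signal: float = 20.0
    # single cell
    cells_per_sample: int = 300
    n_sc_samples_per_genotype: int = 3
    n_features_sc: int = 200
    sc_depth: int = 2000
    sc_conc_mt: float = 5.0  # near-uniform profiles: high diversity
    sc_wt_n_archetypes: int = 10  # WT cells commit to one archetype each
    sc_wt_archetype_size: int = 6  # features per archetype
    sc_wt_alpha_in: float = 2.0  # Dirichlet weight inside the archetype
    sc_wt_alpha_out: float = 0.05  # and outside it
    n_sc_motifs: int = 20
    n_sc_peaks: int = 400
    n_sc_extra_mt_peaks: int = 120

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise GenerationError("sigma must be > 0")
        for name in ("n_chrom", "n_genes", "n_samples_per_genotype",
                     "n_planted_enhancers", "cells_per_sample", "n_features_sc"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    state_paths: dict[str, dict[str, np.ndarray]]
    planted_enhancers: list[tuple[Interval, str]]  # (interval, target gene)
    true_betas: dict[str, float]
    dmr_genes: list[str]
    up_genes: list[str]
    down_genes: list[str]
    true_design: pd.DataFrame  # per (gene, genotype) covariates
    planted_sc_motifs: list[str]

    def to_json(self, path) -> None:
        payload = {
            "planted_enhancers": [
                [iv.chrom, iv.start, iv.end, g] for iv, g in self.planted_enhancers
            ],
            "true_betas": self.true_betas,
            "dmr_genes": self.dmr_genes,
            "up_genes": self.up_genes,
            "down_genes": self.down_genes,
            "planted_sc_motifs": self.planted_sc_motifs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class StudyData:
    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    tads: TADSet
    samples: list[str]
    genotypes: dict[str, str]
    # sample -> mark -> list of p-valued Intervals
    peak_sets: dict[str, dict[str, list[Interval]]]
    # sample -> chrom -> (n_bins, n_marks) counts over HMM_MARKS
    count_tracks: dict[str, dict[str, np.ndarray]]
    expression: pd.DataFrame  # gene x sample counts
    de_up: list[str]
    de_down: list[str]
    dmr_table: list[DMRRecord]
    sc_counts: np.ndarray
    sc_cells: list[str]
    sc_genotypes: dict[str, str]
    sc_features: list[str]
    sc_peak_sets: dict[str, list[Interval]]
    sc_motif_hits: dict[str, dict[str, np.ndarray]]
    truth: GroundTruth


def _sample_paths(model: BernoulliHMM, n_seq: int, T: int, rng) -> np.ndarray:
    """Sample n_seq Markov chains of length T; returns (n_seq, T) ints."""
    K = model.K
    cum_pi = np.cumsum(model.initial)
    cum_A = np.cumsum(model.transitions, axis=1)
    paths = np.empty((n_seq, T), dtype=np.int8)
    u = rng.random((n_seq, T))
    paths[:, 0] = np.searchsorted(cum_pi, u[:, 0])
    for t in range(1, T):
        prev = paths[:, t - 1]
        paths[:, t] = (u[:, t, None] > cum_A[prev]).sum(axis=1)
    return paths


def _runs_to_intervals(mask: np.ndarray, chrom: str, bin_width: int,
                       chrom_len: int, pvals: np.ndarray) -> list[Interval]:
    """Maximal runs of True bins -> Intervals with supplied p-values."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        out.append(
            Interval(chrom, int(s) * bin_width,
                     min(int(e) * bin_width, chrom_len), pvalue=float(pvals[i]))
        )
    return out


def _log_uniform(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size)


def _place_genes(cfg: SimulationConfig, rng) -> list[GeneModel]:
    genes = []
    per_chrom = cfg.n_genes // cfg.n_chrom
    extra = cfg.n_genes - per_chrom * cfg.n_chrom
    gid = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        n = per_chrom + (1 if c < extra else 0)
        # evenly spaced slots with jitter keep promoters non-overlapping
        slot = cfg.chrom_length // (n + 1)
        for i in range(n):
            tss = (i + 1) * slot + int(rng.integers(-slot // 8, slot // 8))
            tss = int(np.clip(tss, 20_000, cfg.chrom_length - 20_000))
            body_len = int(rng.integers(3_500, 15_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                body = Interval(chrom, tss, min(tss + body_len, cfg.chrom_length))
            else:
                body = Interval(chrom, max(0, tss - body_len + 1), tss + 1)
            genes.append(GeneModel(f"gene_{gid:04d}", chrom, strand, tss, body))
            gid += 1
    return genes


def _plant_enhancers(cfg, genes, tads, layout, target_ids, rng,
                     avoid_bins: dict[str, np.ndarray] | None = None):
    """One distal enhancer per target gene inside its TAD and regulatory
    domain, avoiding every promoter window, previously planted sites, and
    (optionally) bins whose background state already carries active marks."""
    domains = {
        d.gene_id: d
        for d in regulatory_domains(genes, chrom_lengths=layout.chrom_lengths)
    }
    gene_of = {g.gene_id: g for g in genes}
    promoters = [promoter_window(g, 2000, layout.chrom_lengths[g.chrom])
                 for g in genes]
    placed: list[tuple[Interval, str]] = []
    w = cfg.enhancer_width
    for gid in target_ids:
        g = gene_of[gid]
        dom = domains[gid].extended
        tad_idx = tads.tad_index_at(g.chrom, g.tss)
        if tad_idx is None:
            raise GenerationError(f"gene {gid}: TSS not covered by any TAD")
        tad = tads.by_chrom[g.chrom][tad_idx]
        lo = max(dom.start, tad.start)
        hi = min(dom.end, tad.end) - w
        if hi <= lo:
            raise GenerationError(f"gene {gid}: enhancer cannot fit in TAD")
        def _clear(cand: Interval, check_distance: bool) -> bool:
            if check_distance:
                dist = abs(cand.midpoint - g.tss)
                if dist < 5_000 or dist > 200_000:
                    return False
            if any(cand.overlaps(p) for p in promoters if p.chrom == g.chrom):
                return False
            if any(cand.chrom == e.chrom and cand.overlaps(e, 1)
                   for e, _ in placed):
                return False
            if avoid_bins is not None:
                b_lo, b_hi = layout.bin_range(cand)
                mask = avoid_bins[g.chrom]
                if mask[max(0, b_lo - 1): b_hi + 1].any():
                    return False
            return True

        ok = None
        for check_distance in (True, False):
            for _ in range(400):
                start = int(rng.integers(lo, hi))
                cand = Interval(g.chrom, start, start + w)
                if _clear(cand, check_distance):
                    ok = cand
                    break
            if ok is not None:
                break
        if ok is None:
            raise GenerationError(f"gene {gid}: enhancer cannot fit in its TAD")
        placed.append((ok, gid))
    return placed


def simulate_study(cfg: SimulationConfig) -> StudyData:
    rng = np.random.default_rng(cfg.seed)
    model = default_true_model()
    K, M = model.K, model.n_marks

    chroms = [f"chr{c + 1}" for c in range(cfg.n_chrom)]
    layout = GenomeLayout(chroms, {c: cfg.chrom_length for c in chroms},
                          cfg.bin_width)
    tads = TADSet(
        [
            Interval(c, s, min(s + cfg.tad_width, cfg.chrom_length))
            for c in chroms
            for s in range(0, cfg.chrom_length, cfg.tad_width)
        ]
    )
    genes = _place_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]

    # designated gene sets
    perm = list(rng.permutation(len(genes)))
    up = sorted(gene_ids[i] for i in perm[: cfg.n_up_genes])
    down = sorted(
        gene_ids[i] for i in perm[cfg.n_up_genes: cfg.n_up_genes + cfg.n_down_genes]
    )
    # enhancer targets: half (where possible) from the up set
    n_from_up = min(cfg.n_planted_enhancers // 2, len(up))
    up_targets = sorted(rng.choice(up, size=n_from_up, replace=False))
    rest_pool = [g for g in gene_ids if g not in set(up_targets)]
    other_targets = sorted(
        rng.choice(rest_pool, size=cfg.n_planted_enhancers - n_from_up,
                   replace=False)
    )
    target_ids = list(up_targets) + list(other_targets)

    n_per = cfg.n_samples_per_genotype
    samples = [f"WT_{i + 1:02d}" for i in range(n_per)] + [
        f"MT_{i + 1:02d}" for i in range(n_per)
    ]
    genotypes = {s: ("WT" if s.startswith("WT") else "MT") for s in samples}

    # ---- latent state paths ----------------------------------------------
    # One background path per chromosome is shared by every sample (the
    # common chromatin landscape); genotype differences exist only where
    # planted, so genotype-specific elements are unambiguous ground truth.
    background = {
        chrom: _sample_paths(model, 1, layout.n_bins(chrom), rng)[0]
        for chrom in chroms
    }
    # bins whose background state already carries ATAC/H3K27ac signal are
    # unsafe hosts for planted MT-specific enhancers
    marked_states = [
        TRUE_STATE_LABELS.index(l)
        for l in ("active_promoter", "active_enhancer", "accessible_only")
    ]
    avoid_bins = {
        chrom: np.isin(background[chrom], marked_states) for chrom in chroms
    }
    enhancers = _plant_enhancers(cfg, genes, tads, layout, target_ids, rng,
                                 avoid_bins=avoid_bins)

    raw = {
        chrom: np.tile(background[chrom], (len(samples), 1))
        for chrom in chroms
    }
    gene_of = {g.gene_id: g for g in genes}

    def _override(paths: np.ndarray, chrom: str, sample_rows: Sequence[int],
                  gid: str, state: int) -> None:
        g = gene_of[gid]
        if g.chrom != chrom:
            return
        win = promoter_window(g, 2000, layout.chrom_lengths[chrom])
        lo, hi = layout.bin_range(win)
        for r in sample_rows:
            paths[r, lo:hi] = state

    wt_rows = [i for i, s in enumerate(samples) if genotypes[s] == "WT"]
    mt_rows = [i for i, s in enumerate(samples) if genotypes[s] == "MT"]
    for chrom in chroms:
        for gid in up:
            _override(raw[chrom], chrom, mt_rows, gid, _ACTIVE)
            _override(raw[chrom], chrom, wt_rows, gid, _POISED)
        for gid in down:
            _override(raw[chrom], chrom, mt_rows, gid, _POISED)
            _override(raw[chrom], chrom, wt_rows, gid, _ACTIVE)
    enh_state = TRUE_STATE_LABELS.index("active_enhancer")
    for iv, _ in enhancers:
        lo, hi = layout.bin_range(iv)
        raw[iv.chrom][mt_rows, lo:hi] = enh_state

    state_paths = {
        s: {chrom: raw[chrom][i].copy() for chrom in chroms}
        for i, s in enumerate(samples)
    }

    # ---- mark indicators, counts, peaks ----------------------------------
    mark_idx = {m: i for i, m in enumerate(HMM_MARKS)}
    enh_bins = {chrom: [] for chrom in chroms}
    for iv, _ in enhancers:
        lo, hi = layout.bin_range(iv)
        enh_bins[iv.chrom].append((lo, hi))

    peak_sets: dict[str, dict[str, list[Interval]]] = {s: {} for s in samples}
    count_tracks: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    for i, s in enumerate(samples):
        indicators: dict[str, np.ndarray] = {}
        for chrom in chroms:
            path = raw[chrom][i]
            probs = model.emissions[path]  # (T, M)
            ind = rng.random(probs.shape) < probs
            if genotypes[s] == "MT":
                for lo, hi in enh_bins[chrom]:
                    ind[lo:hi, mark_idx["ATAC"]] = True
                    ind[lo:hi, mark_idx["H3K27ac"]] = True
                    ind[lo:hi, mark_idx["H3K4me1"]] = True
            indicators[chrom] = ind
            lam = cfg.lam_background + ind * (cfg.lam_signal - cfg.lam_background)
            count_tracks[s][chrom] = rng.poisson(lam).astype(np.int32)
        for m, mark in enumerate(HMM_MARKS):
            peaks: list[Interval] = []
            for chrom in chroms:
                mask = indicators[chrom][:, m]
                n_runs = int(np.abs(np.diff(np.concatenate(
                    [[0], mask.astype(np.int8), [0]]))).sum()) // 2
                pv = _log_uniform(rng, 1e-7, 1e-4, n_runs)
                peaks.extend(
                    _runs_to_intervals(mask, chrom, cfg.bin_width,
                                       cfg.chrom_length, pv)
                )
            peak_sets[s][mark] = sorted(peaks, key=lambda p: (p.chrom, p.start))

    # ---- methylation ------------------------------------------------------
    mc_frac = np.where(
        rng.random(len(genes)) < 0.4, 0.0, rng.uniform(0.05, 0.9, len(genes))
    )
    hmc_present = rng.random(len(genes)) < 0.5
    hmc_frac = np.where(hmc_present, rng.uniform(0.05, 0.95, len(genes)), 0.0)
    meth_blocks: dict[str, list[Interval]] = {"5mC": [], "5hmC": []}
    for g, mf, hf in zip(genes, mc_frac, hmc_frac):
        blen = len(g.body)
        for mark, frac in (("5mC", mf), ("5hmC", hf)):
            if frac <= 0:
                continue
            w = max(cfg.bin_width, int(frac * blen))
            off = int(rng.integers(0, max(1, blen - w)))
            meth_blocks[mark].append(
                Interval(g.chrom, g.body.start + off,
                         min(g.body.start + off + w, g.body.end))
            )
    # realized coverage fractions (block clipped to the body)
    mc_pct = np.zeros(len(genes))
    hmc_pct = np.zeros(len(genes))
    blocks_by_gene: dict[str, dict[str, Interval]] = {}
    bi = {"5mC": 0, "5hmC": 0}
    for j, (g, mf, hf) in enumerate(zip(genes, mc_frac, hmc_frac)):
        blocks_by_gene[g.gene_id] = {}
        if mf > 0:
            blk = meth_blocks["5mC"][bi["5mC"]]
            bi["5mC"] += 1
            mc_pct[j] = 100.0 * blk.overlap_length(g.body) / len(g.body)
            blocks_by_gene[g.gene_id]["5mC"] = blk
        if hf > 0:
            blk = meth_blocks["5hmC"][bi["5hmC"]]
            bi["5hmC"] += 1
            hmc_pct[j] = 100.0 * blk.overlap_length(g.body) / len(g.body)
            blocks_by_gene[g.gene_id]["5hmC"] = blk
    for mark in ("5mC", "5hmC"):
        blocks = sorted(meth_blocks[mark], key=lambda p: (p.chrom, p.start))
        for s in samples:
            pv = _log_uniform(rng, 1e-12, 1e-9, len(blocks))
            peak_sets[s][mark] = [
                Interval(b.chrom, b.start, b.end, pvalue=float(p))
                for b, p in zip(blocks, pv)
            ]

    # ---- DMR table: exactly one up gene with isolated body hyper-DMR ------
    dmr_candidates = [
        g for g in genes
        if g.gene_id in set(up) and len(g.body) >= 3_500
        and g.gene_id not in set(target_ids)
    ]
    if not dmr_candidates:
        raise GenerationError("no up-regulated gene can host the planted DMR")
    dmr_gene = dmr_candidates[int(rng.integers(len(dmr_candidates)))]
    prom = promoter_window(dmr_gene, 2000, cfg.chrom_length)
    if dmr_gene.strand == "+":
        dmr_iv = Interval(dmr_gene.chrom, prom.end + 100, prom.end + 600)
    else:
        dmr_iv = Interval(dmr_gene.chrom, prom.start - 600, prom.start - 100)
    dmr_table = [DMRRecord(dmr_iv, "hyper", 1.61, 0.018)]
    # decoys: body+promoter hyper on another up gene, weak hyper, hypo DMRs
    decoy_up = [g for g in genes if g.gene_id in set(up)
                and g.gene_id != dmr_gene.gene_id]
    if decoy_up:
        g2 = decoy_up[int(rng.integers(len(decoy_up)))]
        dmr_table.append(
            DMRRecord(Interval(g2.chrom, max(0, g2.tss - 500), g2.tss + 1500),
                      "hyper", 0.9, 0.01)
        )
        g3 = decoy_up[int(rng.integers(len(decoy_up)))]
        dmr_table.append(
            DMRRecord(Interval(g3.body.chrom, g3.body.start, g3.body.end),
                      "hyper", 0.4, 0.4)  # non-significant
        )
    up_bodies = [g.body for g in genes if g.gene_id in set(up)]
    n_hypo = 0
    while n_hypo < 20:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_length - 1000))
        cand = Interval(chrom, start, start + 1000)
        dmr_table.append(DMRRecord(cand, "hypo", float(rng.uniform(0.2, 2.0)),
                                   float(rng.uniform(0.0, 0.05))))
        n_hypo += 1
    # intergenic hyper decoys that avoid every up-gene body and promoter
    up_prom = [promoter_window(g, 2000, cfg.chrom_length)
               for g in genes if g.gene_id in set(up)]
    n_decoy = 0
    while n_decoy < 10:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_length - 800))
        cand = Interval(chrom, start, start + 800)
        if any(cand.overlaps(b) for b in up_bodies + up_prom
               if b.chrom == chrom):
            continue
        dmr_table.append(DMRRecord(cand, "hyper", float(rng.uniform(0.2, 2.0)),
                                   float(rng.uniform(0.0, 0.05))))
        n_decoy += 1

    # ---- true covariates and expression -----------------------------------
    active_states = [TRUE_STATE_LABELS.index("active_promoter"),
                     TRUE_STATE_LABELS.index("active_enhancer")]
    inactive_states = [TRUE_STATE_LABELS.index("poised_promoter"),
                       TRUE_STATE_LABELS.index("repressed")]
    target_set = set(target_ids)
    rows = []
    for j, g in enumerate(genes):
        win = promoter_window(g, 2000, cfg.chrom_length)
        lo, hi = layout.bin_range(win)
        for geno, rws in (("WT", wt_rows), ("MT", mt_rows)):
            seg = raw[g.chrom][rws, lo:hi]
            occ_active = 100.0 * np.isin(seg, active_states).mean()
            occ_inactive = 100.0 * np.isin(seg, inactive_states).mean()
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "genotype": geno,
                    "active_occ": occ_active,
                    "inactive_occ": occ_inactive,
                    "mc_fraction": mc_pct[j],
                    "hmc_present": float(hmc_pct[j] > 0),
                    "enh_present": float(geno == "MT" and g.gene_id in target_set),
                }
            )
    true_design = pd.DataFrame(rows).set_index(["gene_id", "genotype"])

    expr = np.zeros((len(genes), len(samples)))
    for si, s in enumerate(samples):
        geno = genotypes[s]
        cov = true_design.xs(geno, level="genotype").loc[gene_ids]
        mu = (
            cfg.beta0
            + cfg.beta_active * cov["active_occ"].to_numpy()
            + cfg.beta_meth * cov["mc_fraction"].to_numpy()
            + cfg.beta_enh * cov["enh_present"].to_numpy()
            + cfg.beta_hmc * cov["hmc_present"].to_numpy()
        )
        eps = rng.normal(0.0, cfg.sigma, len(genes))
        expr[:, si] = np.maximum(0, np.round(np.expm1(mu + eps)))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # ---- single-cell matrices ---------------------------------------------
    n_feat = cfg.n_features_sc
    # WT cells commit to one of several sharp feature archetypes ("cell
    # types"): low per-cell diversity, high specialization.  MT cells are
    # near-uniform: high diversity, low specialization.
    n_arch = cfg.sc_wt_n_archetypes
    arch_size = min(cfg.sc_wt_archetype_size, n_feat // max(n_arch, 1))
    archetypes = [
        np.arange(a * arch_size, (a + 1) * arch_size) for a in range(n_arch)
    ]
    alpha_mt = np.full(n_feat, cfg.sc_conc_mt)
    sc_cells, sc_geno_list = [], []
    sc_counts = []
    for geno in ("WT", "MT"):
        for rep in range(cfg.n_sc_samples_per_genotype):
            if geno == "MT":
                profiles = rng.dirichlet(alpha_mt, size=cfg.cells_per_sample)
            else:
                profiles = np.empty((cfg.cells_per_sample, n_feat))
                which = rng.integers(n_arch, size=cfg.cells_per_sample)
                for ci in range(cfg.cells_per_sample):
                    a = np.full(n_feat, cfg.sc_wt_alpha_out)
                    a[archetypes[which[ci]]] = cfg.sc_wt_alpha_in
                    profiles[ci] = rng.dirichlet(a)
            counts = np.vstack(
                [rng.multinomial(cfg.sc_depth, p) for p in profiles]
            )
            for ci in range(cfg.cells_per_sample):
                sc_cells.append(f"{geno}_s{rep + 1}_c{ci + 1:04d}")
                sc_geno_list.append(geno)
            sc_counts.append(counts)
    sc_counts = np.vstack(sc_counts)
    sc_genotypes = dict(zip(sc_cells, sc_geno_list))
    sc_features = [f"motif_{i + 1:03d}" for i in range(n_feat)]

    # ---- single-cell peak sets + motif hit table --------------------------
    motifs = [f"TF_{i + 1:02d}" for i in range(cfg.n_sc_motifs)]
    planted_motifs = motifs[:3]
    base_peaks = []
    for _ in range(cfg.n_sc_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_length - 500))
        base_peaks.append(Interval(chrom, start, start + 500))
    extra_mt = []
    for _ in range(cfg.n_sc_extra_mt_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_length - 500))
        extra_mt.append(Interval(chrom, start, start + 500))
    sc_peak_sets = {"WT": base_peaks, "MT": base_peaks + extra_mt}
    hits: dict[str, dict[str, np.ndarray]] = {"WT": {}, "MT": {}}
    base_hits = {m: rng.random(len(base_peaks)) < 0.2 for m in motifs}
    for m in motifs:
        hits["WT"][m] = base_hits[m]
        extra = rng.random(len(extra_mt)) < (0.9 if m in planted_motifs else 0.1)
        hits["MT"][m] = np.concatenate([base_hits[m], extra])

    truth = GroundTruth(
        state_paths=state_paths,
        planted_enhancers=enhancers,
        true_betas={
            "beta0": cfg.beta0,
            "beta_active": cfg.beta_active,
            "beta_meth": cfg.beta_meth,
            "beta_enh": cfg.beta_enh,
            "beta_hmc": cfg.beta_hmc,
            "sigma": cfg.sigma,
        },
        dmr_genes=[dmr_gene.gene_id],
        up_genes=list(up),
        down_genes=list(down),
        true_design=true_design,
        planted_sc_motifs=planted_motifs,
    )
    return StudyData(
        config=cfg, layout=layout, genes=genes, tads=tads, samples=samples,
        genotypes=genotypes, peak_sets=peak_sets, count_tracks=count_tracks,
        expression=expression, de_up=list(up), de_down=list(down),
        dmr_table=dmr_table, sc_counts=sc_counts, sc_cells=sc_cells,
        sc_genotypes=sc_genotypes, sc_features=sc_features,
        sc_peak_sets=sc_peak_sets, sc_motif_hits=hits, truth=truth,
    )


def simulate_peak_pvalues(
    n_replicates: int,
    true_region: Interval,
    noise: int = 0,
    n_decoys: int = 0,
    weak: float = 1e-4,
    seed: int = 0,
) -> list[list[Interval]]:
    """Per-replicate peak lists jittered around a true region, with strong
    log-uniform p-values in [1e-12, 1e-3]; decoy peaks get p >= weak."""
    if n_replicates < 1:
        raise GenerationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        peaks = []
        ds = int(rng.integers(-noise, noise + 1)) if noise else 0
        de = int(rng.integers(-noise, noise + 1)) if noise else 0
        start = max(0, true_region.start + ds)
        end = max(start + 1, true_region.end + de)
        p = float(_log_uniform(rng, 1e-12, 1e-3, 1)[0])
        peaks.append(Interval(true_region.chrom, start, end, pvalue=p))
        for _ in range(n_decoys):
            off = int(rng.integers(10_000, 100_000))
            w = int(rng.integers(200, 1000))
            peaks.append(
                Interval(true_region.chrom, true_region.end + off,
                         true_region.end + off + w,
                         pvalue=float(rng.uniform(weak, 1.0)))
            )
        out.append(peaks)
    return out
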