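"""End-to-end orchestration of the analysis stages on a study in memory.

Used by the CLI and by the end-to-end recovery tests; every stage consumes
only the data products a real study would provide (peak files, count
tracks, expression matrix, DMR table, cell matrix) plus configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import consensus as cons
from . import states as st
from .core import Interval, overlap_query, promoter_window
from .cre import CandidateCRE, genotype_specific_cres
from .entropy import CellFeatureMatrix, genotype_heterogeneity, motif_accessibility_ranking
from .integration import IntegrationFit, fit_integration
from .methylation import gene_body_fraction, isolated_hypermethylation_filter, meth_expression_model
from .ranktests import occupancy_expression_table
from .simulate import StudyData
from .targets import (
    assign_targets,
    enhancer_expression_association,
    overlap_significance,
    regulatory_domains,
)

__all__ = ["PipelineResult", "run_pipeline", "consensus_by_genotype",
           "evaluate_enhancer_recovery", "build_integration_design"]


@dataclass
class PipelineResult:
    consensus: dict
    model: st.ChromStateModel | None
    state_map: st.StateMap | None
    contrast: dict | None
    occupancy: st.PromoterOccupancy | None
    state_expression: pd.DataFrame | None
    methylation_summary: pd.DataFrame
    methylation_model: dict
    flagged_genes: list[str]
    cres: list[CandidateCRE]
    distal_cres: list[CandidateCRE]
    interactions: list
    association: dict
    overlap: dict
    integration: IntegrationFit
    sc: dict
    motif_ranking: pd.DataFrame


def consensus_by_genotype(
    study: StudyData,
    marks: Sequence[str],
    weak: float = 1e-4,
    stringent: float = 1e-8,
) -> dict[str, dict[str, list[Interval]]]:
    """Per-genotype consensus peak intervals for the requested marks."""
    out: dict[str, dict[str, list[Interval]]] = {}
    for geno in ("WT", "MT"):
        members = [s for s in study.samples if study.genotypes[s] == geno]
        out[geno] = {}
        for mark in marks:
            peak_sets = [study.peak_sets[s][mark] for s in members]
            peaks = cons.combine_replicates(peak_sets, weak=weak, stringent=stringent)
            out[geno][mark] = [p.interval for p in peaks]
    return out


def evaluate_enhancer_recovery(
    study: StudyData, distal_cres: Sequence[CandidateCRE]
) -> dict:
    """Precision / recall of discovered distal CREs vs planted enhancers."""
    planted = [iv for iv, _ in study.truth.planted_enhancers]
    found = [c.interval for c in distal_cres]
    pairs = overlap_query(found, planted, min_bp=1) if found and planted else []
    hit_cres = {i for i, _ in pairs}
    hit_planted = {j for _, j in pairs}
    precision = len(hit_cres) / len(found) if found else 0.0
    recall = len(hit_planted) / len(planted) if planted else 0.0
    return {"precision": precision, "recall": recall,
            "n_found": len(found), "n_planted": len(planted)}


def build_integration_design(
    study: StudyData,
    occupancy: st.PromoterOccupancy | None,
    meth_summary: pd.DataFrame,
    interactions: Sequence,
    genotype: str = "MT",
    use_true_occupancy: bool = False,
) -> pd.DataFrame:
    """Gene x covariate table: active/inactive promoter occupancy (percent),
    gene-body 5mC coverage (percent), 5hmC presence, enhancer presence."""
    target_genes = {it.gene_id for it in interactions}
    if use_true_occupancy or occupancy is None:
        td = study.truth.true_design.xs(genotype, level="genotype")
        active = td["active_occ"]
        inactive = td["inactive_occ"]
        genes = list(td.index)
    else:
        genes = occupancy.genes

        def _occ_sum(wanted: set[str]) -> np.ndarray:
            missing = wanted - set(occupancy.labels)
            if missing:
                import warnings

                warnings.warn(f"labels absent from fitted model: {sorted(missing)}")
            total = np.zeros(len(genes))
            for label in wanted & set(occupancy.labels):
                total += occupancy.label_occupancy(genotype, label)
            return total

        active = pd.Series(
            _occ_sum({"active_promoter", "active_enhancer"}), index=genes
        ) * 100.0
        inactive = pd.Series(
            _occ_sum({"poised_promoter", "repressed"}), index=genes
        ) * 100.0
    design = pd.DataFrame(
        {
            "active_occ": active.loc[genes],
            "inactive_occ": inactive.loc[genes],
            "mc_fraction": meth_summary.loc[genes, "mc_fraction"] * 100.0,
            "hmc_present": meth_summary.loc[genes, "hmc_present"].astype(float),
            "enh_present": [float(g in target_genes) for g in genes],
        },
        index=genes,
    )
    return drop_constant_columns(design)


def drop_constant_columns(design: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance covariates (they make the design singular)."""
    import warnings

    flat = [c for c in design.columns if design[c].nunique() <= 1]
    if flat:
        warnings.warn(f"dropping constant covariates: {flat}")
    return design.drop(columns=flat)


def run_pipeline(
    study: StudyData,
    seed: int = 0,
    K: int = 7,
    fit_states: bool = True,
    n_restarts: int = 2,
    max_iter: int = 60,
    weak: float = 1e-4,
    stringent: float = 1e-8,
    flank: int = 2000,
) -> PipelineResult:
    chip_marks = list(st.HMM_MARKS) + ["5mC", "5hmC"]
    consensus = consensus_by_genotype(study, chip_marks, weak, stringent)

    model = state_map = contrast = occupancy = expr_table = None
    if fit_states:
        tracks = st.binarize(
            study.count_tracks, study.layout, study.genotypes, st.HMM_MARKS
        )
        model = st.fit_hmm(tracks, K=K, n_restarts=n_restarts, seed=seed,
                           max_iter=max_iter)
        state_map = st.decode(model, tracks, method="viterbi")
        contrast = st.genotype_contrast(state_map, study.genes, flank)
        occupancy = st.promoter_occupancy(state_map, study.genes, model, flank)
        expr_table = occupancy_expression_table(
            occupancy, study.expression, study.genotypes, genotype="MT"
        )

    # methylation from MT-genotype consensus peaks
    meth_summary = gene_body_fraction(
        consensus["MT"]["5mC"], consensus["MT"]["5hmC"], study.genes
    )
    mt_samples = [s for s in study.samples if study.genotypes[s] == "MT"]
    median_counts = study.expression[mt_samples].median(axis=1)
    meth_model = meth_expression_model(meth_summary, median_counts)
    flagged = isolated_hypermethylation_filter(
        study.dmr_table, study.genes, study.de_up
    )

    # genotype-specific distal CREs
    cres = genotype_specific_cres(
        consensus["MT"]["ATAC"], consensus["MT"]["H3K27ac"],
        consensus["WT"]["ATAC"], consensus["WT"]["H3K27ac"],
        study.genes, flank=flank,
    )
    distal = [c for c in cres if c.distal]

    # target assignment and association
    domains = regulatory_domains(
        study.genes, chrom_lengths=study.layout.chrom_lengths
    )
    assignment = assign_targets(distal, domains, study.genes, study.tads)
    interactions = assignment["interactions"]
    universe = list(study.expression.index)
    association = enhancer_expression_association(
        interactions, study.expression, study.genotypes, universe
    )
    overlap = overlap_significance(
        [it.gene_id for it in interactions], study.de_up, len(universe)
    )

    # integration model
    design = build_integration_design(
        study, occupancy, meth_summary, interactions,
        use_true_occupancy=not fit_states,
    )
    common = design.index.intersection(median_counts.index)
    integration = fit_integration(
        design.loc[common], median_counts.loc[common], lmg_seed=seed
    )

    # single cell
    cell_matrix = CellFeatureMatrix(
        list(study.sc_cells), dict(study.sc_genotypes),
        list(study.sc_features), study.sc_counts,
    )
    sc = genotype_heterogeneity(cell_matrix)
    ranking = motif_accessibility_ranking(study.sc_peak_sets, study.sc_motif_hits)

    return PipelineResult(
        consensus=consensus, model=model, state_map=state_map,
        contrast=contrast, occupancy=occupancy, state_expression=expr_table,
        methylation_summary=meth_summary, methylation_model=meth_model,
        flagged_genes=flagged, cres=cres, distal_cres=distal,
        interactions=interactions, association=association, overlap=overlap,
        integration=integration, sc=sc, motif_ranking=ranking,
    )
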