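"""Read/write a simulated study as plain-text files (BED/narrowPeak, GFF3,
TSV, MatrixMarket, JSON) so every pipeline stage can run from disk."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GenomeLayout,
    Interval,
    TADSet,
    read_bed,
    read_genes_gff3,
    write_bed,
    write_genes_gff3,
)
from .methylation import DMRRecord
from .simulate import GroundTruth, SimulationConfig, StudyData
from .states import HMM_MARKS

__all__ = ["write_study", "load_study"]

_ALL_MARKS = tuple(HMM_MARKS) + ("5mC", "5hmC")


def write_study(study: StudyData, out_dir) -> None:
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)

    layout = study.layout
    with open(out / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\tbin_width\n")
        for c in layout.chrom_names:
            fh.write(f"{c}\t{layout.chrom_lengths[c]}\t{layout.bin_width}\n")
    write_genes_gff3(out / "genes.gff3", study.genes)
    write_bed(out / "tads.bed", study.tads.tads, dialect="bed3")

    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample\tgenotype\n")
        for s in study.samples:
            fh.write(f"{s}\t{study.genotypes[s]}\n")

    for s in study.samples:
        for mark in _ALL_MARKS:
            write_bed(out / "peaks" / f"{s}_{mark}.narrowPeak",
                      study.peak_sets[s][mark], dialect="narrowpeak")
        frames = []
        for chrom in layout.chrom_names:
            df = pd.DataFrame(study.count_tracks[s][chrom], columns=HMM_MARKS)
            df.insert(0, "bin", np.arange(len(df)))
            df.insert(0, "chrom", chrom)
            frames.append(df)
        pd.concat(frames).to_csv(out / "tracks" / f"{s}.tsv", sep="\t",
                                 index=False)

    study.expression.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    (out / "de_up.txt").write_text("".join(g + "\n" for g in study.de_up))
    (out / "de_down.txt").write_text("".join(g + "\n" for g in study.de_down))

    with open(out / "dmr.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tarea\tfdr\n")
        for d in study.dmr_table:
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                     f"\t{d.direction}\t{d.area:.6g}\t{d.fdr:.6g}\n")

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(out / "sc_counts.mtx"), csr_matrix(study.sc_counts))
    with open(out / "sc_cells.tsv", "w") as fh:
        fh.write("cell_id\tgenotype\n")
        for c in study.sc_cells:
            fh.write(f"{c}\t{study.sc_genotypes[c]}\n")
    (out / "sc_features.txt").write_text(
        "".join(f + "\n" for f in study.sc_features)
    )
    for geno in ("WT", "MT"):
        write_bed(out / f"sc_peaks_{geno}.bed", study.sc_peak_sets[geno])
        hits = pd.DataFrame(
            {m: np.asarray(v, dtype=int)
             for m, v in sorted(study.sc_motif_hits[geno].items())}
        )
        hits.to_csv(out / f"sc_motif_hits_{geno}.tsv", sep="\t", index=False)

    study.truth.to_json(out / "ground_truth.json")
    study.truth.true_design.to_csv(out / "true_design.tsv", sep="\t")
    with open(out / "config.json", "w") as fh:
        json.dump(vars(study.config), fh, indent=1, sort_keys=True)


def load_study(study_dir) -> StudyData:
    d = Path(study_dir)
    with open(d / "config.json") as fh:
        cfg = SimulationConfig(**json.load(fh))

    genome = pd.read_csv(d / "genome.tsv", sep="\t")
    layout = GenomeLayout(
        genome["chrom"].tolist(),
        dict(zip(genome["chrom"], genome["length"])),
        int(genome["bin_width"].iloc[0]),
    )
    genes = read_genes_gff3(d / "genes.gff3")
    tads = TADSet(read_bed(d / "tads.bed"))
    smp = pd.read_csv(d / "samples.tsv", sep="\t")
    samples = smp["sample"].tolist()
    genotypes = dict(zip(smp["sample"], smp["genotype"]))

    peak_sets = {
        s: {
            mark: read_bed(d / "peaks" / f"{s}_{mark}.narrowPeak",
                           dialect="narrowpeak")
            for mark in _ALL_MARKS
        }
        for s in samples
    }
    count_tracks = {}
    for s in samples:
        df = pd.read_csv(d / "tracks" / f"{s}.tsv", sep="\t")
        count_tracks[s] = {
            chrom: sub[list(HMM_MARKS)].to_numpy(dtype=np.int32)
            for chrom, sub in df.groupby("chrom", sort=False)
        }

    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    de_up = (d / "de_up.txt").read_text().split()
    de_down = (d / "de_down.txt").read_text().split()
    dmr_df = pd.read_csv(d / "dmr.tsv", sep="\t")
    dmr_table = [
        DMRRecord(Interval(str(r.chrom), int(r.start), int(r.end)),
                  str(r.direction), float(r.area), float(r.fdr))
        for r in dmr_df.itertuples()
    ]

    from scipy.io import mmread

    sc_counts = np.asarray(mmread(str(d / "sc_counts.mtx")).todense())
    cells = pd.read_csv(d / "sc_cells.tsv", sep="\t")
    sc_cells = cells["cell_id"].tolist()
    sc_genotypes = dict(zip(cells["cell_id"], cells["genotype"]))
    sc_features = (d / "sc_features.txt").read_text().split()
    sc_peak_sets = {g: read_bed(d / f"sc_peaks_{g}.bed") for g in ("WT", "MT")}
    sc_motif_hits = {}
    for g in ("WT", "MT"):
        hits = pd.read_csv(d / f"sc_motif_hits_{g}.tsv", sep="\t")
        sc_motif_hits[g] = {m: hits[m].to_numpy(dtype=bool) for m in hits.columns}

    with open(d / "ground_truth.json") as fh:
        gt = json.load(fh)
    true_design = pd.read_csv(d / "true_design.tsv", sep="\t",
                              index_col=["gene_id", "genotype"])
    truth = GroundTruth(
        state_paths={},
        planted_enhancers=[
            (Interval(c, s, e), g) for c, s, e, g in gt["planted_enhancers"]
        ],
        true_betas=gt["true_betas"],
        dmr_genes=gt["dmr_genes"],
        up_genes=gt["up_genes"],
        down_genes=gt["down_genes"],
        true_design=true_design,
        planted_sc_motifs=gt["planted_sc_motifs"],
    )
    return StudyData(
        config=cfg, layout=layout, genes=genes, tads=tads, samples=samples,
        genotypes=genotypes, peak_sets=peak_sets, count_tracks=count_tracks,
        expression=expression, de_up=de_up, de_down=de_down,
        dmr_table=dmr_table, sc_counts=sc_counts, sc_cells=sc_cells,
        sc_genotypes=sc_genotypes, sc_features=sc_features,
        sc_peak_sets=sc_peak_sets, sc_motif_hits=sc_motif_hits, truth=truth,
    )
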