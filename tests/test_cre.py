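import numpy as np
import pytest
from scipy import stats

from epistate.core import GeneModel, Interval
from epistate.cre import (
    PWM,
    annotate_catalog,
    genotype_specific_cres,
    interval_enrichment,
    pwm_scan,
    read_jaspar_pwms,
)

_COMP = str.maketrans("ACGT", "TGCA")


def gene(gid, tss, chrom="chr1"):
    return GeneModel(gid, chrom, "+", tss, Interval(chrom, tss, tss + 2000))


class TestGenotypeSpecificCres:
    def test_co_marking_required(self):
        out = genotype_specific_cres(
            [Interval("chr1", 0, 500)], [Interval("chr1", 10_000, 10_500)],
            [], [], [],
        )
        assert out == []

    def test_wt_overlap_excluded(self):
        region = [Interval("chr1", 0, 500)]
        out = genotype_specific_cres(region, region, region, region, [])
        assert out == []

    def test_promoter_overlap_not_distal(self):
        atac = [Interval("chr1", 49_500, 50_500), Interval("chr1", 80_000, 80_600)]
        k27 = [Interval("chr1", 49_400, 50_400), Interval("chr1", 80_100, 80_700)]
        out = genotype_specific_cres(atac, k27, [], [], [gene("g", 50_000)])
        flags = {c.interval.start: c.distal for c in out}
        assert flags == {49_500: False, 80_000: True}

    def test_geometry_is_atac_peak(self):
        atac = [Interval("chr1", 100, 700)]
        k27 = [Interval("chr1", 650, 1500)]
        (cre,) = genotype_specific_cres(atac, k27, [], [], [])
        assert (cre.interval.start, cre.interval.end) == (100, 700)

    def test_order_independence(self, rng):
        atac = [Interval("chr1", int(s), int(s) + 300)
                for s in rng.integers(0, 50_000, 30)]
        k27 = [Interval("chr1", int(s), int(s) + 300)
               for s in rng.integers(0, 50_000, 30)]
        wt = [Interval("chr1", int(s), int(s) + 300)
              for s in rng.integers(0, 50_000, 10)]
        ref = genotype_specific_cres(atac, k27, wt, wt, [])
        perm = rng.permutation(len(atac))
        shuf = genotype_specific_cres([atac[i] for i in perm], k27[::-1],
                                      wt[::-1], wt, [])
        assert sorted((c.interval.start, c.interval.end) for c in ref) == sorted(
            (c.interval.start, c.interval.end) for c in shuf
        )

    def test_max_wt_overlap_knob(self):
        mt = [Interval("chr1", 0, 500)]
        wt = [Interval("chr1", 450, 900)]
        strict = genotype_specific_cres(mt, mt, wt, wt, [])
        assert strict == []
        tolerant = genotype_specific_cres(mt, mt, wt, wt, [], max_wt_overlap=60)
        assert len(tolerant) == 1


class TestAnnotateCatalog:
    def test_empty_catalog(self):
        from epistate.cre import CandidateCRE

        cres = [CandidateCRE(Interval("chr1", 0, 100))]
        out = annotate_catalog(cres, catalog=[], se_catalog=[])
        assert out["fraction_annotated"] == 0.0

    def test_inside_catalog(self):
        from epistate.cre import CandidateCRE

        cres = [CandidateCRE(Interval("chr1", 50, 150))]
        out = annotate_catalog(cres, catalog=[Interval("chr1", 0, 1000)])
        assert out["fraction_annotated"] == 1.0
        assert cres[0].annotated

    @pytest.mark.parametrize("trial", range(10))
    def test_fraction_matches_brute_force(self, trial):
        from epistate.cre import CandidateCRE

        rng = np.random.default_rng(trial)
        cres = [
            CandidateCRE(Interval("chr1", int(s), int(s) + 200))
            for s in rng.integers(0, 20_000, 25)
        ]
        catalog = [Interval("chr1", int(s), int(s) + 500)
                   for s in rng.integers(0, 20_000, 8)]
        out = annotate_catalog(cres, catalog=catalog)
        expected = np.mean([
            any(c.interval.overlaps(k) for k in catalog) for c in cres
        ])
        assert out["fraction_annotated"] == pytest.approx(expected)


def _consensus_pwm(motif="TGACTCA"):
    rows = []
    for b in motif:
        row = [0.02, 0.02, 0.02, 0.02]
        row["ACGT".index(b)] = 0.94
        rows.append(row)
    return PWM("test", np.array(rows))


class TestPwmScan:
    def test_consensus_hit(self):
        pwm = _consensus_pwm()
        assert pwm_scan(["AAATGACTCAGGG"], pwm, score_frac=1.0) == [True]

    def test_reverse_complement_hit(self):
        pwm = _consensus_pwm()
        rc = "TGACTCA".translate(_COMP)[::-1]
        assert pwm_scan([f"CC{rc}TT"], pwm, score_frac=1.0) == [True]

    def test_short_sequence_no_hit(self):
        assert pwm_scan(["ACG"], _consensus_pwm()) == [False]

    def test_n_contributes_zero(self):
        pwm = _consensus_pwm()
        # an N in the core cannot reach the full-score cutoff
        assert pwm_scan(["TGANTCA"], pwm, score_frac=1.0) == [False]
        assert pwm_scan(["TGANTCA"], pwm, score_frac=0.5) == [True]

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_naive_scan(self, trial):
        rng = np.random.default_rng(trial)
        pwm = _consensus_pwm("GGAAGT")
        lo = pwm.log_odds()
        cutoff = 0.8 * lo.max(axis=1).sum()
        seqs = [
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
            for _ in range(100)
        ]

        def naive_hit(seq):
            best = -np.inf
            for s in (seq, seq.translate(_COMP)[::-1]):
                for off in range(len(s) - pwm.width + 1):
                    score = sum(
                        lo[i, "ACGT".index(s[off + i])] for i in range(pwm.width)
                    )
                    best = max(best, score)
            return best >= cutoff - 1e-9

        assert pwm_scan(seqs, pwm, 0.8) == [naive_hit(s) for s in seqs]


class TestJasparReader:
    def test_read(self, tmp_path):
        text = (">MA0001.1 TEST\n"
                "A [ 10  0  0 ]\n"
                "C [  0 10  0 ]\n"
                "G [  0  0 10 ]\n"
                "T [  0  0  0 ]\n")
        p = tmp_path / "m.jaspar"
        p.write_text(text)
        (pwm,) = read_jaspar_pwms(p)
        assert pwm.width == 3
        assert pwm.consensus == "ACG"
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)


class TestIntervalEnrichment:
    def _regions(self, starts, chrom="chr1", width=100):
        return [Interval(chrom, s, s + width) for s in starts]

    def test_null_rates(self):
        fg = self._regions(range(0, 10_000, 1000))
        bg = self._regions(range(100_000, 110_000, 1000))
        catalog = {"TF": self._regions([0, 100_000])}
        (res,) = interval_enrichment(fg, bg, catalog)
        assert res.effect_size == pytest.approx(1.0)
        assert res.p >= 0.05

    def test_counts_example(self):
        # a=30, b=70, c=10, d=90 -> effect 3.0, Fisher p from hypergeometric
        fg = self._regions(range(0, 100_000, 1000))
        bg = self._regions(range(500_000, 600_000, 1000))
        catalog = {"TF": self._regions(list(range(0, 30_000, 1000))
                                       + list(range(500_000, 510_000, 1000)))}
        (res,) = interval_enrichment(fg, bg, catalog)
        assert (res.a, res.b, res.c, res.d) == (30, 70, 10, 90)
        assert res.effect_size == pytest.approx(3.0)
        _, expected = stats.fisher_exact([[30, 70], [10, 90]])
        # independent oracle: hypergeometric enumeration of the 2x2 table
        direct = sum(
            stats.hypergeom.pmf(k, 200, 40, 100)
            for k in range(0, 41)
            if stats.hypergeom.pmf(k, 200, 40, 100)
            <= stats.hypergeom.pmf(30, 200, 40, 100) * (1 + 1e-9)
        )
        assert res.p == pytest.approx(expected)
        assert res.p == pytest.approx(direct, rel=1e-6)

    def test_doubling_counts(self):
        fg1 = self._regions(range(0, 20_000, 1000))
        bg1 = self._regions(range(500_000, 520_000, 1000))
        catalog1 = {"TF": self._regions(range(0, 10_000, 1000))
                    + self._regions(range(500_000, 505_000, 1000))}
        (r1,) = interval_enrichment(fg1, bg1, catalog1)
        fg2 = self._regions(range(0, 40_000, 1000))
        bg2 = self._regions(range(500_000, 540_000, 1000))
        catalog2 = {"TF": self._regions(range(0, 20_000, 1000))
                    + self._regions(range(500_000, 510_000, 1000))}
        (r2,) = interval_enrichment(fg2, bg2, catalog2)
        assert r2.effect_size == pytest.approx(r1.effect_size)
        assert r2.p < r1.p

    def test_zero_background_hits(self):
        fg = self._regions(range(0, 5_000, 1000))
        bg = self._regions(range(500_000, 505_000, 1000))
        catalog = {"TF": self._regions([0])}
        (res,) = interval_enrichment(fg, bg, catalog)
        assert res.effect_size == np.inf
        assert 0 < res.p <= 1


class TestPlantedRecovery:
    def test_precision_recall(self, default_study, pipeline_result):
        from epistate.pipeline import evaluate_enhancer_recovery

        rec = evaluate_enhancer_recovery(default_study,
                                         pipeline_result.distal_cres)
        assert rec["precision"] >= 0.9
        assert rec["recall"] >= 0.9
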