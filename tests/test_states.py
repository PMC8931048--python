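import warnings

import numpy as np
import pytest
from scipy import stats

from epistate.core import GeneModel, GenomeLayout, Interval, ValidationError
from epistate.hmm import BernoulliHMM, viterbi_brute_force
from epistate.states import (
    HMM_MARKS,
    BinarizedTracks,
    ChromStateModel,
    StateMap,
    binarize,
    decode,
    fit_hmm,
    genotype_contrast,
    label_states,
    occupancy_bucket,
    promoter_occupancy,
)


def small_layout(n_bins=50, bin_width=200):
    return GenomeLayout(["chr1"], {"chr1": n_bins * bin_width}, bin_width)


def make_tracks(matrix_by_sample, genotypes, layout):
    return BinarizedTracks(
        sorted(matrix_by_sample), dict(genotypes), HMM_MARKS, layout,
        {s: {"chr1": m} for s, m in matrix_by_sample.items()},
    )


class TestBinarize:
    def _counts(self, arr):
        return {"s1": {"chr1": np.asarray(arr)}}

    def test_zero_observed_not_flagged(self):
        # lambda = 1, x = 0: P(X >= 0) = 1
        arr = np.ones((50, 5), dtype=int)
        arr[0, 0] = 0
        layout = small_layout()
        tracks = binarize(self._counts(arr), layout, {"s1": "WT"})
        assert not tracks.matrix["s1"]["chr1"][0, 0]

    def test_poisson_tail_oracle(self):
        # lambda = 1, x = 10: P(X >= 10) ~ 1.11e-7 < 1e-4 -> flagged
        arr = np.ones((100, 5), dtype=int)
        arr[0, 0] = 10
        tail = sum(stats.poisson.pmf(k, 1.09) for k in range(10, 200))
        layout = small_layout(100)
        tracks = binarize(self._counts(arr), layout, {"s1": "WT"})
        lam = arr[:, 0].mean()
        assert stats.poisson.sf(9, lam) == pytest.approx(
            sum(stats.poisson.pmf(k, lam) for k in range(10, 300)), rel=1e-6
        )
        assert tracks.matrix["s1"]["chr1"][0, 0]
        assert tail < 1e-3  # sanity on the hand computation

    def test_uniform_counts_all_zero(self):
        arr = np.full((50, 5), 3, dtype=int)
        tracks = binarize(self._counts(arr), small_layout(), {"s1": "WT"})
        assert not tracks.matrix["s1"]["chr1"].any()

    def test_all_zero_track_warns(self):
        arr = np.zeros((50, 5), dtype=int)
        with pytest.warns(UserWarning, match="all-zero"):
            tracks = binarize(self._counts(arr), small_layout(), {"s1": "WT"})
        assert not tracks.matrix["s1"]["chr1"].any()


class TestHMMFit:
    def test_k1_closed_form(self, rng):
        obs = (rng.random((2000, 5)) < 0.3).astype(np.int8)
        model = BernoulliHMM.fit([obs], K=1, n_restarts=1, seed=0, max_iter=50)
        freq = obs.mean(axis=0)
        assert np.allclose(model.emissions[0], freq, atol=0.01)
        phi = model.emissions[0]
        ll_expected = float(
            (obs * np.log(phi) + (1 - obs) * np.log(1 - phi)).sum()
        )
        assert model.loglik == pytest.approx(ll_expected, rel=1e-6)

    def test_planted_k2_recovery(self):
        rng = np.random.default_rng(42)
        phi = np.array([[0.9, 0.1, 0.9, 0.1, 0.9], [0.1, 0.9, 0.1, 0.9, 0.1]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        true = BernoulliHMM(2, phi, A, np.array([0.5, 0.5]))
        states = np.zeros(50_000, dtype=int)
        for t in range(1, len(states)):
            states[t] = rng.choice(2, p=A[states[t - 1]])
        obs = (rng.random((len(states), 5)) < phi[states]).astype(np.int8)
        fit = BernoulliHMM.fit([obs], K=2, n_restarts=3, seed=0, max_iter=100)
        maes = [
            np.abs(fit.emissions[list(perm)] - phi).mean()
            for perm in ([0, 1], [1, 0])
        ]
        assert min(maes) < 0.05

    def test_em_loglik_monotone(self, rng):
        obs = (rng.random((500, 5)) < 0.4).astype(np.int8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BernoulliHMM.fit([obs], K=3, n_restarts=1, seed=1,
                                     max_iter=30)
        hist = np.array(model.loglik_history)
        assert np.all(np.diff(hist) >= -1e-6 * np.abs(hist[:-1]))

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            BernoulliHMM.fit([np.zeros((10, 5), dtype=np.int8)], K=0)


class TestDecode:
    def test_k1_all_zero_states(self, rng):
        layout = small_layout(20)
        obs = (rng.random((20, 5)) < 0.5).astype(np.int8)
        tracks = make_tracks({"s1": obs}, {"s1": "WT"}, layout)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_hmm(tracks, K=1, n_restarts=1, enforce_bounds=False,
                            max_iter=20)
        smap = decode(model, tracks)
        assert (smap.paths["s1"]["chr1"] == 0).all()

    @pytest.mark.parametrize("trial", range(25))
    def test_viterbi_matches_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        K = int(rng.integers(2, 4))
        T = int(rng.integers(2, 11))
        phi = rng.uniform(0.05, 0.95, size=(K, 3))
        A = rng.dirichlet(np.ones(K), size=K)
        pi = rng.dirichlet(np.ones(K))
        model = BernoulliHMM(K, phi, A, pi)
        obs = (rng.random((T, 3)) < 0.5).astype(np.int8)
        assert np.array_equal(model.viterbi(obs), viterbi_brute_force(model, obs))

    def test_noiseless_limit(self):
        phi = np.array([[1e-9, 1e-9], [1 - 1e-9, 1 - 1e-9]])
        model = BernoulliHMM(
            2, phi, np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.5, 0.5])
        )
        states = np.array([0, 0, 1, 1, 0, 1, 1, 1, 0, 0])
        obs = np.stack([states, states], axis=1).astype(np.int8)
        assert np.array_equal(model.viterbi(obs), states)

    def test_mark_mismatch_rejected(self, rng):
        layout = small_layout(10)
        obs = (rng.random((10, 5)) < 0.5).astype(np.int8)
        tracks = make_tracks({"s1": obs}, {"s1": "WT"}, layout)
        model = ChromStateModel(
            BernoulliHMM(1, np.full((1, 5), 0.5), np.ones((1, 1)), np.ones(1)),
            tuple(reversed(HMM_MARKS)), ("quiescent",),
        )
        with pytest.raises(ValidationError, match="mark order"):
            decode(model, tracks)


class TestLabels:
    def test_semantic_rules(self):
        #            K4me1 K4me3 K27ac K27me3 ATAC
        phi = np.array([
            [0.3, 0.9, 0.9, 0.1, 0.8],   # active promoter
            [0.3, 0.9, 0.1, 0.9, 0.2],   # poised promoter
            [0.9, 0.1, 0.9, 0.1, 0.8],   # active enhancer
            [0.9, 0.1, 0.1, 0.1, 0.2],   # inactive enhancer
            [0.1, 0.1, 0.1, 0.9, 0.1],   # repressed
            [0.1, 0.1, 0.1, 0.1, 0.9],   # accessible only
            [0.1, 0.1, 0.1, 0.1, 0.1],   # quiescent
        ])
        assert label_states(phi) == (
            "active_promoter", "poised_promoter", "active_enhancer",
            "inactive_enhancer", "repressed", "accessible_only", "quiescent",
        )

    def test_permutation_stability(self, rng):
        phi = rng.uniform(0.05, 0.95, size=(7, 5))
        labels = label_states(phi)
        perm = rng.permutation(7)
        assert label_states(phi[perm]) == tuple(labels[i] for i in perm)


def _toy_statemap(paths_by_sample, genotypes, layout, K):
    return StateMap(layout, sorted(paths_by_sample), dict(genotypes), K,
                    {s: {"chr1": p} for s, p in paths_by_sample.items()})


def _toy_genes(layout, tss_list):
    return [
        GeneModel(f"g{i}", "chr1", "+", tss,
                  Interval("chr1", tss, tss + 1000))
        for i, tss in enumerate(tss_list)
    ]


class TestContrastAndOccupancy:
    def test_null_contrast(self, rng):
        layout = small_layout(100)
        path = rng.integers(0, 3, 100)
        smap = _toy_statemap(
            {"a": path.copy(), "b": path.copy()}, {"a": "WT", "b": "MT"},
            layout, 3,
        )
        genes = _toy_genes(layout, [4000, 10_000])
        out = genotype_contrast(smap, genes)
        assert np.allclose(out["delta"], 0.0)
        tm = out["transition_matrix"]
        assert tm.sum() == np.trace(tm)

    def test_delta_rows_sum_zero(self, rng):
        layout = small_layout(100)
        smap = _toy_statemap(
            {"a": rng.integers(0, 3, 100), "b": rng.integers(0, 3, 100)},
            {"a": "WT", "b": "MT"}, layout, 3,
        )
        genes = _toy_genes(layout, [4000, 10_000])
        out = genotype_contrast(smap, genes)
        assert np.allclose(out["delta"].sum(axis=1), 0.0, atol=1e-12)

    def test_planted_override_recovered(self, default_study):
        from epistate.simulate import TRUE_STATE_LABELS

        smap = StateMap(
            default_study.layout, default_study.samples,
            default_study.genotypes, len(TRUE_STATE_LABELS),
            default_study.truth.state_paths,
        )
        up = set(default_study.truth.up_genes)
        genes = [g for g in default_study.genes if g.gene_id in up]
        out = genotype_contrast(smap, genes)
        active = TRUE_STATE_LABELS.index("active_promoter")
        poised = TRUE_STATE_LABELS.index("poised_promoter")
        assert out["delta"][:, active].mean() > 0.5
        assert out["delta"][:, poised].mean() < -0.5

    def test_occupancy_all_one_state(self):
        layout = small_layout(100)
        paths = {"a": np.full(100, 2), "b": np.full(100, 2)}
        smap = _toy_statemap(paths, {"a": "WT", "b": "MT"}, layout, 3)
        genes = _toy_genes(layout, [4000])
        model = ChromStateModel(
            BernoulliHMM(3, np.full((3, 5), 0.5), np.full((3, 3), 1 / 3),
                         np.full(3, 1 / 3)),
            HMM_MARKS, ("quiescent", "repressed", "active_promoter"),
        )
        occ = promoter_occupancy(smap, genes, model)
        for geno in ("WT", "MT"):
            assert occ.fractions[geno][0, 2] == pytest.approx(1.0)
            assert occ.fractions[geno].sum(axis=1) == pytest.approx(1.0)
        assert occ.buckets("MT", "active_promoter") == ["(75-100]"]

    def test_occupancy_fraction_oracle(self):
        layout = small_layout(100)
        path = np.zeros(100, dtype=int)
        # tss at bin 20: promoter spans the 21 bins 10..30 inclusive;
        # 8 of them in state 1 -> direct count 8/21, bucket (25-50]
        path[10:18] = 1
        smap = _toy_statemap({"a": path, "b": path.copy()},
                             {"a": "WT", "b": "MT"}, layout, 2)
        genes = _toy_genes(layout, [4000])
        model = ChromStateModel(
            BernoulliHMM(2, np.full((2, 5), 0.5), np.full((2, 2), 0.5),
                         np.full(2, 0.5)),
            HMM_MARKS, ("quiescent", "active_promoter"),
        )
        occ = promoter_occupancy(smap, genes, model)
        expected = (path[10:31] == 1).sum() / 21
        assert occ.fractions["MT"][0, 1] == pytest.approx(expected)
        assert occ.buckets("MT", "active_promoter") == ["(25-50]"]


class TestFittedOverrideRecovery:
    def test_gain_state_is_active_promoter(self):
        """End-to-end through binarize -> fit -> decode -> contrast: the
        state gaining frequency at overridden promoters carries the
        active-promoter label; the losing state is the poised promoter."""
        from epistate.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(
            seed=9, n_chrom=1, chrom_length=3_000_000, n_genes=150,
            n_samples_per_genotype=4, n_up_genes=40, n_down_genes=10,
            n_planted_enhancers=20, cells_per_sample=50, n_features_sc=40,
            sc_wt_n_archetypes=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = simulate_study(cfg)
            tracks = binarize(study.count_tracks, study.layout,
                              study.genotypes)
            model = fit_hmm(tracks, K=7, n_restarts=3, seed=9, max_iter=80)
            smap = decode(model, tracks)
            up = set(study.truth.up_genes)
            genes = [g for g in study.genes if g.gene_id in up]
            out = genotype_contrast(smap, genes)
        gain = out["delta"].mean(axis=0)
        assert model.labels[int(np.argmax(gain))] == "active_promoter"
        assert model.labels[int(np.argmin(gain))] == "poised_promoter"
        assert gain.max() > 0.5


class TestBuckets:
    @pytest.mark.parametrize("frac,expected", [
        (0.0, "0"), (0.1, "(0-25]"), (0.25, "(0-25]"), (0.250001, "(25-50]"),
        (0.5, "(25-50]"), (0.75, "(50-75]"), (1.0, "(75-100]"),
    ])
    def test_edges(self, frac, expected):
        assert occupancy_bucket(frac) == expected
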