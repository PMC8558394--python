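import numpy as np
import pandas as pd
import pytest

from crpdecomp.ancestry import (
    AncestryEstimate,
    apply_ancestry_filter,
    harmonize_variants,
    infer_ancestry_nnls,
    ld_prune,
    run_pca,
    selfid_probability_curve,
)
from crpdecomp.config import ThetaParams
from crpdecomp.exceptions import InputError
from crpdecomp.synthgen import (
    assign_ethnic_identity,
    simulate_admixed_cohort,
    simulate_reference_panel,
)

from conftest import geno, make_config


# ---------------------------------------------------------------------------
# harmonize_variants
# ---------------------------------------------------------------------------

class TestHarmonize:
    def _toy_pair(self):
        # 8 samples each; variants at pos 100..103:
        #   100: identical A/G in both                       -> kept
        #   101: A stores A/G, B stores T/C (strand flip)    -> kept, B unchanged
        #   102: A stores A/G, B stores G/A (allele swap)    -> kept, B reflected
        #   103: A/T in both (strand-ambiguous)              -> dropped
        dA = np.tile([[0, 1, 2, 1], [1, 1, 0, 1]], (4, 1))
        dB = np.tile([[1, 0, 2, 1], [2, 1, 1, 1]], (4, 1))
        a = geno(dA, ref=["A", "A", "A", "A"], alt=["G", "G", "G", "T"],
                 sample_prefix="a")
        b = geno(dB, ref=["A", "T", "G", "A"], alt=["G", "C", "A", "T"],
                 sample_prefix="b")
        return a, b

    def test_flip_swap_and_ambiguity_rules(self):
        a, b = self._toy_pair()
        merged = harmonize_variants([a, b])
        assert list(merged.variants["pos"]) == [100, 101, 102]
        assert list(merged.variants["id"]) == ["1:100:A:G", "1:101:A:G",
                                               "1:102:A:G"]
        # samples a0..a7 then b0..b7
        np.testing.assert_array_equal(merged.dosages[:8], a.dosages[:, :3])
        # flipped variant: dosages unchanged; swapped variant: reflected
        np.testing.assert_array_equal(merged.dosages[8:, 1], b.dosages[:, 1])
        np.testing.assert_array_equal(merged.dosages[8:, 2], 2 - b.dosages[:, 2])

    def test_identical_datasets_fully_retained(self):
        a, _ = self._toy_pair()
        a = a.take_variants([0, 1, 2])  # drop the ambiguous one
        merged = harmonize_variants([a, a])
        assert merged.n_variants == 3

    def test_allele_mismatch_dropped_not_fatal(self):
        a = geno(np.tile([[0, 1], [1, 2]], (4, 1)), ref=["A", "A"], alt=["G", "G"])
        b = geno(np.tile([[0, 1], [1, 2]], (4, 1)), ref=["A", "A"], alt=["G", "C"],
                 sample_prefix="b")
        merged = harmonize_variants([a, b])
        assert list(merged.variants["pos"]) == [100]

    def test_rare_variant_filtered_by_pooled_maf(self):
        d = np.zeros((60, 2))
        d[:, 0] = 1.0           # common
        d[0, 1] = 1.0           # singleton: pooled MAF 1/240 < 0.01
        a = geno(d)
        b = geno(d, sample_prefix="b")
        merged = harmonize_variants([a, b])
        assert list(merged.variants["pos"]) == [100]

    def test_high_missingness_filtered(self):
        d = np.ones((20, 2))
        d[:5, 1] = np.nan       # 25% missing
        merged = harmonize_variants([geno(d), geno(d, sample_prefix="b")])
        assert list(merged.variants["pos"]) == [100]

    def test_input_order_commutes_on_variant_set(self):
        a, b = self._toy_pair()
        ab = harmonize_variants([a, b])
        ba = harmonize_variants([b, a])
        assert set(zip(ab.variants["chrom"], ab.variants["pos"])) == \
            set(zip(ba.variants["chrom"], ba.variants["pos"]))

    def test_adding_a_sample_leaves_other_dosages_unchanged(self):
        a, b = self._toy_pair()
        merged1 = harmonize_variants([a, b])
        b2 = geno(np.vstack([b.dosages, [[1, 1, 1, 1]]]),
                  ref=["A", "T", "G", "A"], alt=["G", "C", "A", "T"],
                  sample_prefix="b")
        merged2 = harmonize_variants([a, b2])
        np.testing.assert_array_equal(merged1.dosages[:16], merged2.dosages[:16])


# ---------------------------------------------------------------------------
# ld_prune
# ---------------------------------------------------------------------------

class TestLdPrune:
    def test_independent_variants_nearly_all_retained(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, (1_000, 200)).astype(float)
        g = geno(d)
        pruned = ld_prune(g, window=50, step=5, r2_max=0.1)
        assert pruned.n_variants >= 198

    def test_duplicated_variant_keeps_one_copy(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, 50).astype(float)
        g = geno(np.column_stack([col, col, rng.binomial(2, 0.4, 50)]))
        pruned = ld_prune(g)
        assert pruned.n_variants == 2
        assert 100 in list(pruned.variants["pos"])  # earlier duplicate kept

    def test_three_variant_toy_removes_later_of_correlated_pair(self):
        # 8-sample toy: v1 and v2 correlated (r2 > 0.1), v3 nearly independent
        v1 = np.array([0, 0, 1, 1, 1, 1, 2, 2], dtype=float)
        v2 = np.array([0, 1, 0, 1, 1, 2, 1, 2], dtype=float)
        v3 = np.array([2, 1, 0, 1, 2, 0, 1, 1], dtype=float)
        r = np.corrcoef(np.vstack([v1, v2, v3]))
        assert r[0, 1] ** 2 > 0.1
        assert r[0, 2] ** 2 < 0.1 and r[1, 2] ** 2 < 0.1
        g = geno(np.column_stack([v1, v2, v3]))
        assert g.maf()[0] == g.maf()[1]
        pruned = ld_prune(g, window=3, step=1, r2_max=0.1)
        assert list(pruned.variants["pos"]) == [100, 102]  # later of {v1,v2} gone

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 100), (200, 100)).astype(float)
        once = ld_prune(geno(d))
        twice = ld_prune(once)
        assert list(twice.variants["pos"]) == list(once.variants["pos"])

    def test_monomorphic_variants_kept(self):
        d = np.column_stack([np.zeros(30), np.random.default_rng(3).binomial(2, .4, 30)])
        pruned = ld_prune(geno(d.astype(float)))
        assert pruned.n_variants == 2

    def test_parameter_validation(self):
        g = geno(np.zeros((4, 3)))
        with pytest.raises(InputError):
            ld_prune(g, window=1)
        with pytest.raises(InputError):
            ld_prune(g, r2_max=1.5)


# ---------------------------------------------------------------------------
# run_pca
# ---------------------------------------------------------------------------

def patterson_standardize(d):
    p = d.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    return (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))


class TestPca:
    @pytest.fixture(scope="class")
    def two_pop_panel(self):
        cfg = make_config(fst=0.15, n_variants=5_000, n_reference_per_pop=200,
                          seed=11)
        return cfg, simulate_reference_panel(cfg)

    def test_pc1_separates_populations(self, two_pop_panel):
        _, panel = two_pop_panel
        pcs = run_pca(panel.genotypes, 10)
        indicator = (panel.population_labels == "AFR_ref").astype(float)
        r = np.corrcoef(pcs.scores[:, 0], indicator)[0, 1]
        assert abs(r) > 0.95

    def test_pc1_tracks_admixture_fraction(self, two_pop_panel):
        cfg, panel = two_pop_panel
        cfg2 = cfg.replace(n_participants=200,
                           group_proportions={"Black": 1.0},
                           group_theta={"Black": ThetaParams(0.5, 0.35)})
        g, truth = simulate_admixed_cohort(cfg2, panel)
        pcs = run_pca(g, 5)
        r = np.corrcoef(pcs.scores[:, 0], truth.theta_afr)[0, 1]
        assert abs(r) > 0.95

    def test_scores_centered_and_orthogonal(self, two_pop_panel):
        _, panel = two_pop_panel
        pcs = run_pca(panel.genotypes, 6)
        assert np.abs(pcs.scores.mean(axis=0)).max() < 1e-8
        gram = pcs.scores.T @ pcs.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8
        assert (np.diff(pcs.explained_variance) <= 1e-9).all()

    def test_matches_eigendecomposition_oracle(self):
        cfg = make_config(n_variants=400, n_reference_per_pop=40, seed=12)
        panel = simulate_reference_panel(cfg)
        pcs = run_pca(panel.genotypes, 5)
        Z = patterson_standardize(panel.genotypes.dosages)
        evals, evecs = np.linalg.eigh(Z @ Z.T)
        oracle = evecs[:, ::-1][:, :5] * np.sqrt(evals[::-1][:5])
        for k in range(5):
            dot = np.abs(np.dot(pcs.scores[:, k], oracle[:, k]))
            assert dot / (np.linalg.norm(pcs.scores[:, k])
                          * np.linalg.norm(oracle[:, k])) > 1 - 1e-6

    def test_input_validation(self):
        g = geno(np.array([[0.0, 1.0]]))
        with pytest.raises(InputError):
            run_pca(g, 1)


# ---------------------------------------------------------------------------
# NNLS ancestry + filter
# ---------------------------------------------------------------------------

class TestNnls:
    @pytest.fixture(scope="class")
    def panel_and_pcs(self):
        cfg = make_config(fst=0.15, n_variants=5_000, n_reference_per_pop=100,
                          seed=13, n_participants=200,
                          group_proportions={"Black": 1.0},
                          group_theta={"Black": ThetaParams(0.5, 0.0)})
        panel = simulate_reference_panel(cfg)
        study, truth = simulate_admixed_cohort(cfg, panel)
        merged = harmonize_variants([study, panel.genotypes])
        pcs = run_pca(merged, 10)
        labels = pd.Series(
            [panel.ancestry_groups[p] for p in panel.population_labels],
            index=panel.genotypes.sample_ids)
        return cfg, panel, study, truth, pcs, labels

    def test_held_out_reference_sample_recovers_own_group(self, panel_and_pcs):
        _, panel, _, _, pcs, labels = panel_and_pcs
        held_out = labels.drop(index="AFR_ref_0")
        est = infer_ancestry_nnls(pcs, held_out)
        row = est.fractions.iloc[list(est.sample_ids).index("AFR_ref_0")]
        assert row["African"] >= 0.99

    def test_half_admixture_estimated_within_five_points(self, panel_and_pcs):
        _, _, _, truth, pcs, labels = panel_and_pcs
        est = infer_ancestry_nnls(pcs, labels)
        afr = est.fractions["African"].to_numpy()
        assert np.nanmean(np.abs(afr - 0.5)) < 0.05

    def test_fractions_are_simplex_valued(self, panel_and_pcs):
        _, _, _, _, pcs, labels = panel_and_pcs
        est = infer_ancestry_nnls(pcs, labels)
        frac = est.fractions.to_numpy()[~est.flagged]
        assert (frac >= 0).all()
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_admixture_mean_absolute_error_small(self):
        # 200 individuals with theta ~ Uniform(0, 1), FST 0.15, 10,000 variants
        cfg = make_config(fst=0.15, n_variants=10_000, n_reference_per_pop=100,
                          seed=14)
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(14)
        theta = rng.uniform(0, 1, 200)
        f = (theta[:, None] * panel.population_freqs["AFR_ref"].to_numpy()
             + (1 - theta[:, None]) * panel.population_freqs["EUR_ref"].to_numpy())
        study = geno(rng.binomial(2, f).astype(float),
                     pos=panel.genotypes.variants["pos"],
                     ref=panel.genotypes.variants["ref"],
                     alt=panel.genotypes.variants["alt"])
        merged = harmonize_variants([study, panel.genotypes])
        pcs = run_pca(merged, 10)
        labels = pd.Series(
            [panel.ancestry_groups[p] for p in panel.population_labels],
            index=panel.genotypes.sample_ids)
        est = infer_ancestry_nnls(pcs, labels)
        afr = est.fractions["African"].to_numpy()
        order = pd.Index(study.sample_ids).get_indexer(est.sample_ids)
        ok = ~np.isnan(afr)
        assert np.abs(afr[ok] - theta[order][ok]).mean() < 0.05

    def test_group_with_too_few_references_rejected(self, panel_and_pcs):
        _, _, _, _, pcs, labels = panel_and_pcs
        thin = labels[labels == "European"].iloc[:1]
        with pytest.raises(InputError):
            infer_ancestry_nnls(pcs, pd.concat([labels[labels == "African"], thin]))


class TestAncestryFilter:
    def _estimate(self, rows, groups=("African", "European", "EastAsian")):
        frac = pd.DataFrame(rows, columns=list(groups))
        n = len(frac)
        return AncestryEstimate(
            sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            fractions=frac, groups=list(groups),
            flagged=np.zeros(n, dtype=bool),
        )

    def test_two_group_estimate_everyone_included(self):
        est = self._estimate([[0.8, 0.2], [0.1, 0.9]], groups=("African", "European"))
        kept = apply_ancestry_filter(est, {"African", "European"})
        assert len(kept) == 2

    def test_six_percent_other_excluded_five_percent_kept(self):
        est = self._estimate([[0.9, 0.04, 0.06], [0.9, 0.05, 0.05]])
        kept = apply_ancestry_filter(est, {"African", "European"}, 0.05)
        assert list(kept) == ["s1"]

    def test_flagged_samples_never_included(self):
        est = self._estimate([[1.0, 0.0, 0.0]])
        est.flagged[0] = True
        assert len(apply_ancestry_filter(est, {"African", "European"})) == 0

    def test_unknown_allowed_group_rejected(self):
        est = self._estimate([[1.0, 0.0, 0.0]])
        with pytest.raises(InputError):
            apply_ancestry_filter(est, {"Oceanian"})


# ---------------------------------------------------------------------------
# self-identification curve
# ---------------------------------------------------------------------------

class TestSelfIdCurve:
    def test_threshold_identity_crossover_within_one_bin(self, small_config):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1, 100_000)
        cfg = small_config.replace(identity_mode="threshold")
        labels = assign_ethnic_identity(theta, cfg)
        curve = selfid_probability_curve(theta, labels, span=0.3)
        assert abs(curve.crossover_estimate - 0.29) <= 0.01

    def test_all_white_labels_give_zero_curve_and_no_crossover(self):
        theta = np.linspace(0, 1, 500)
        labels = np.array(["White"] * 500, dtype=object)
        curve = selfid_probability_curve(theta, labels)
        defined = ~np.isnan(curve.p_black)
        assert (curve.p_black[defined] == 0).all()
        assert np.isnan(curve.crossover_estimate)

    def test_single_nonempty_bin_returns_curve(self):
        theta = np.full(50, 0.305)
        labels = np.array(["White"] * 40 + ["Black"] * 10, dtype=object)
        curve = selfid_probability_curve(theta, labels)
        assert np.nansum(curve.counts) == 50
        assert np.isnan(curve.crossover_estimate)

    def test_exactly_one_hundred_bins(self):
        theta = np.random.default_rng(1).uniform(0, 1, 1_000)
        labels = np.array(["Black"] * 1_000, dtype=object)
        curve = selfid_probability_curve(theta, labels)
        assert len(curve.midpoints) == 100
        assert len(curve.bin_edges) == 101
        assert (np.diff(curve.bin_edges) > 0).all()

    def test_too_few_bins_rejected(self):
        with pytest.raises(InputError):
            selfid_probability_curve(np.array([0.5]), np.array(["Black"]), n_bins=1)
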