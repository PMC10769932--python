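import numpy as np
import pandas as pd
import pytest

import indriflex as ix
from indriflex.inference import fit_distance_lmm, fit_diversity_lmm
from indriflex.simulate import CategoryParams, make_transition_matrix


@pytest.fixture(scope="module")
def effect_corpus():
    """DF/DM share a diffuse generator; non-dominants are stereotyped.

    The stereotyped matrix funnels every state into DP2 with high
    probability, so non-dominant contributions are near-identical strings of
    repeats: high between-individual similarity, low diversity.
    """
    rng = np.random.default_rng(50)
    base = make_transition_matrix(6, 3.0, rng)
    nd = np.full((6, 6), 0.03)
    nd[:, 1] = 0.85  # funnel into DP2
    params = {
        "dominant_female": CategoryParams(base, mean_length=12.0),
        "dominant_male": CategoryParams(base, mean_length=12.0),
        "non_dominant": CategoryParams(nd, mean_length=12.0),
    }
    cfg = ix.SyntheticConfig(
        n_groups=3, songs_per_group=6, n_nondominants_per_group=1,
        male_participation=1.0, nondominant_participation=1.0,
        length_model="negative_binomial", nb_dispersion=20.0,
        category_params=params, seed=51,
    )
    return ix.generate_corpus(cfg)


@pytest.fixture(scope="module")
def effect_dyads(effect_corpus):
    M = ix.pairwise_jaro_matrix(effect_corpus.contributions)
    return ix.build_dyad_dataset(M, effect_corpus.contributions, effect_corpus)


class TestDistanceLmm:
    def test_nine_levels_give_df_8_and_detects_effect(self, effect_dyads):
        rep = fit_distance_lmm(effect_dyads)
        assert len(rep.levels) == 9
        assert rep.lrt_df == 8
        assert rep.p_value < 0.05
        assert rep.lrt_chi2 > 0

    def test_stereotyped_category_most_similar(self, effect_dyads):
        """The low-entropy category's between-dyads have the highest mean
        similarity (sqrt JD)."""
        means = effect_dyads.groupby("category_factor", observed=True)["jd_sqrt"].mean()
        between = means[["BDF", "BDM", "BND"]]
        assert between.idxmax() == "BND"

    def test_posthoc_adjustment_monotone(self, effect_dyads):
        rep = fit_distance_lmm(effect_dyads)
        assert len(rep.posthoc) == 36  # all pairs of 9 levels
        assert (rep.posthoc["p_adj"] >= rep.posthoc["p_raw"] - 1e-12).all()
        assert rep.posthoc["p_adj"].between(0, 1).all()

    def test_single_level_unidentifiable(self, effect_dyads):
        sub = effect_dyads[effect_dyads["category_factor"] == "BND"]
        with pytest.raises(ValueError):
            fit_distance_lmm(sub)

    def test_dyad_only_variant_runs(self, effect_dyads):
        rep = fit_distance_lmm(effect_dyads, posthoc=False, contribution_re=False)
        assert rep.random_structure == "~1 | dyad_id"
        assert rep.lrt_df == 8


class TestDiversityLmm:
    def test_three_levels_df_2_and_detects_effect(self, effect_corpus):
        rep = fit_diversity_lmm(ix.diversity_table(effect_corpus))
        assert rep.lrt_df == 2
        assert rep.p_value < 0.05
        # the stereotyped category has the lowest diversity
        means = (
            ix.diversity_table(effect_corpus)
            .groupby("category")["log_nd"].mean()
        )
        assert means.idxmin() == "non_dominant"

    def test_posthoc_has_three_contrasts(self, effect_corpus):
        rep = fit_diversity_lmm(ix.diversity_table(effect_corpus))
        assert len(rep.posthoc) == 3
        assert (rep.posthoc["p_adj"] >= rep.posthoc["p_raw"] - 1e-12).all()


class TestSvmClassification:
    def _matrix_labels(self, concentrations, n_per_class, seed, mean_length=15.0):
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        for k, (name, conc) in enumerate(concentrations.items()):
            P = make_transition_matrix(6, conc, rng)
            pi = ix.stationary_distribution(P)
            for _ in range(n_per_class):
                L = max(int(rng.geometric(1.0 / mean_length)), 2)
                seqs.append(ix.sample_markov_sequence(P, pi, L, rng))
                labels.append(name)
        return ix.pairwise_jaro_matrix(seqs), np.array(labels)

    def test_separable_classes_near_perfect(self):
        """Nearly disjoint transition structure: one class almost always
        repeats a single phrase type, the other is near-uniform."""
        rng = np.random.default_rng(0)
        P1 = np.full((6, 6), 0.004)
        np.fill_diagonal(P1, 0.98)
        P2 = np.full((6, 6), 1 / 6)
        seqs, labels = [], []
        for name, P in (("stereo", P1), ("free", P2)):
            pi = ix.stationary_distribution(P)
            for _ in range(40):
                L = max(int(rng.geometric(1 / 15)), 3)
                seqs.append(ix.sample_markov_sequence(P, pi, L, rng))
                labels.append(name)
        M = ix.pairwise_jaro_matrix(seqs)
        rep = ix.svm_classify_categories(M, np.array(labels), seed=1)
        assert rep.test_accuracy >= 0.9

    def test_permuted_labels_at_chance(self):
        M, labels = self._matrix_labels(
            {"a": 1.0, "b": 1.0, "c": 1.0}, n_per_class=30, seed=3
        )
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(labels)
            rep = ix.svm_classify_categories(M, perm, seed=seed)
            accs.append(rep.test_accuracy)
        n_test = int(round(0.3 * len(labels)))
        se = np.sqrt((1 / 3) * (2 / 3) / n_test)
        assert np.mean(accs) < 1 / 3 + 3 * se

    def test_report_is_deterministic(self):
        M, labels = self._matrix_labels({"a": 0.2, "b": 2.0}, 15, seed=4)
        r1 = ix.svm_classify_categories(M, labels, seed=9)
        r2 = ix.svm_classify_categories(M, labels, seed=9)
        assert r1.test_accuracy == r2.test_accuracy
        assert r1.best_C == r2.best_C and r1.best_sigma == r2.best_sigma
        assert r1.confusion.equals(r2.confusion)

    def test_confusion_rows_sum_to_class_counts(self):
        M, labels = self._matrix_labels({"a": 0.2, "b": 2.0}, 20, seed=5)
        rep = ix.svm_classify_categories(M, labels, seed=2)
        row_sums = rep.confusion.sum(axis=1)
        assert int(row_sums.sum()) == int(round(0.3 * len(labels)))
        for cls in rep.classes:
            denom = row_sums[cls]
            if denom:
                assert rep.per_class_recall[cls] == pytest.approx(
                    rep.confusion.loc[cls, cls] / denom
                )

    def test_small_class_rejected(self):
        M, labels = self._matrix_labels({"a": 1.0, "b": 1.0}, 5, seed=6)
        with pytest.raises(ValueError, match="< 10"):
            ix.svm_classify_categories(M, labels, seed=0)


class TestEntropyGroupTests:
    def _entropy_frame(self, rng, n_groups=10, rho=0.0):
        z_f = rng.standard_normal(n_groups)
        z_m = rho * z_f + np.sqrt(1 - rho**2) * rng.standard_normal(n_groups)
        rows = []
        for g in range(n_groups):
            rows.append({"singer_id": f"f{g}", "category": "dominant_female",
                         "group_id": f"g{g}", "entropy_rate": 1.0 + 0.3 * z_f[g]})
            rows.append({"singer_id": f"m{g}", "category": "dominant_male",
                         "group_id": f"g{g}", "entropy_rate": 1.0 + 0.3 * z_m[g]})
            rows.append({"singer_id": f"n{g}", "category": "non_dominant",
                         "group_id": f"g{g}", "entropy_rate": 1.0 + 0.3 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_kw_df_is_categories_minus_one(self):
        rep = ix.entropy_group_tests(self._entropy_frame(np.random.default_rng(0)))
        assert rep.kw_df == 2

    def test_null_kw_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        ps = [
            ix.entropy_group_tests(self._entropy_frame(rng)).kw_p
            for _ in range(200)
        ]
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.10
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_strong_coupling_gives_positive_rho(self):
        rng = np.random.default_rng(2)
        rhos = [
            ix.entropy_group_tests(self._entropy_frame(rng, rho=0.9)).spearman_rho
            for _ in range(40)
        ]
        assert np.mean(np.array(rhos) > 0) >= 0.9

    def test_insufficient_groups_untested(self):
        df = self._entropy_frame(np.random.default_rng(3), n_groups=2)
        rep = ix.entropy_group_tests(df)
        assert not rep.spearman_tested
        assert np.isnan(rep.spearman_rho)

    def test_corpus_entropy_pipeline(self, effect_corpus):
        rep = ix.entropy_group_tests(ix.entropy_table(effect_corpus))
        assert rep.kw_df == 2
        assert 0 <= rep.kw_p <= 1
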