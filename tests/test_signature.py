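"""Signature selection, subtype clustering, EMT scoring, methylation clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from emtpath.signature import (EPI, MES, ExpressionMatrix, MarkerSet,
                               MethylationMatrix, cluster_methylation,
                               cluster_subtypes, compute_emt_score,
                               orient_clusters, select_signature_genes)
from emtpath.synthetic import CohortSpec, generate_expression_cohort


def _labels(cohort, sample_ids):
    return [cohort.true_labels[s] for s in sample_ids]


class TestSelectSignatureGenes:
    def test_marker_tracking_gene_selected_into_mes_set(self, planted_cohort):
        expr = planted_cohort.expression
        res = select_signature_genes(expr, expr.gene_ids)
        # SIG0000 is planted mesenchymal-up, hence strongly VIM-correlated
        assert "SIG0000" in res.mes_set
        assert "CDH1" in res.epi_set

    def test_independent_gene_not_selected(self):
        cohort = generate_expression_cohort(CohortSpec(n_samples=200, seed=4))
        res = select_signature_genes(cohort.expression,
                                     cohort.expression.gene_ids)
        noise = [g for g in cohort.expression.gene_ids
                 if g not in cohort.planted_signature]
        selected_noise = set(res.selected_genes) & set(noise)
        assert len(selected_noise) <= 0.05 * max(1, len(res.selected_genes))

    def test_recovery_of_planted_signature(self):
        cohort = generate_expression_cohort(CohortSpec(
            n_genes=500, n_signature_genes=63, effect_size=3.0,
            n_samples=200, seed=3))
        res = select_signature_genes(cohort.expression,
                                     cohort.expression.gene_ids,
                                     r_min=0.4, alpha=0.05)
        planted = set(cohort.planted_signature)
        selected = set(res.selected_genes)
        sensitivity = len(selected & planted) / len(planted)
        noise_frac = len(selected - planted) / max(1, len(selected))
        assert sensitivity >= 0.9
        assert noise_frac <= 0.05

    def test_lowering_r_min_is_monotone(self, planted_cohort):
        expr = planted_cohort.expression
        strict = select_signature_genes(expr, expr.gene_ids, r_min=0.6)
        loose = select_signature_genes(expr, expr.gene_ids, r_min=0.3)
        assert set(strict.selected_genes) <= set(loose.selected_genes)

    def test_missing_marker_is_an_error(self, planted_cohort):
        expr = planted_cohort.expression.subset_genes(
            [g for g in planted_cohort.expression.gene_ids if g != "VIM"])
        with pytest.raises(ValueError, match="VIM"):
            select_signature_genes(expr, expr.gene_ids)

    def test_missing_candidates_dropped_with_warning(self, planted_cohort):
        expr = planted_cohort.expression
        with pytest.warns(UserWarning, match="dropping"):
            res = select_signature_genes(expr, expr.gene_ids + ["NOT_A_GENE"])
        assert "NOT_A_GENE" not in res.selected_genes


class TestClusterSubtypes:
    def test_duplicate_samples_co_cluster(self, rng):
        x = rng.normal(size=(10, 6))
        x[:, 3] = x[:, 0]  # duplicate column
        expr = ExpressionMatrix(x, [f"g{i}" for i in range(10)],
                                [f"s{i}" for i in range(6)])
        a = cluster_subtypes(expr)
        assert a.labels["s0"] == a.labels["s3"]

    def test_planted_cohort_ari(self, planted_cohort):
        expr = planted_cohort.expression.subset_genes(
            list(planted_cohort.planted_signature))
        a = cluster_subtypes(expr)
        ari = adjusted_rand_score(_labels(planted_cohort, expr.sample_ids),
                                  [a.labels[s] for s in expr.sample_ids])
        assert ari >= 0.9

    def test_null_effect_gives_no_structure(self):
        aris = []
        for seed in range(20):
            c = generate_expression_cohort(CohortSpec(
                n_samples=40, n_genes=60, n_signature_genes=12,
                effect_size=0.0, seed=seed))
            expr = c.expression.subset_genes(list(c.planted_signature))
            a = cluster_subtypes(expr)
            aris.append(adjusted_rand_score(
                _labels(c, expr.sample_ids),
                [a.labels[s] for s in expr.sample_ids]))
        assert np.mean(aris) <= 0.1

    def test_constant_profile_is_an_error(self, rng):
        x = rng.normal(size=(5, 6))
        x[:, 2] = 1.0
        expr = ExpressionMatrix(x, [f"g{i}" for i in range(5)],
                                [f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="s2"):
            cluster_subtypes(expr)

    def test_centered_correlation_absorbs_sample_affine_shift(self, rng):
        """Rescaling one sample's profile affinely (a>0) leaves centered-
        correlation distances unchanged, while an uncentered cosine distance
        would move — centering is what buys the invariance."""
        x = rng.normal(size=(12, 8)) + 5.0
        y = x.copy()
        y[:, 0] = 3.0 * y[:, 0] + 7.0
        d_x = pdist(x.T, metric="correlation")
        d_y = pdist(y.T, metric="correlation")
        np.testing.assert_allclose(d_x, d_y, atol=1e-10)
        d_cos_x = pdist(x.T, metric="cosine")
        d_cos_y = pdist(y.T, metric="cosine")
        assert not np.allclose(d_cos_x, d_cos_y, atol=1e-6)
        ids = [f"g{i}" for i in range(12)], [f"s{i}" for i in range(8)]
        a = cluster_subtypes(ExpressionMatrix(x, *ids))
        b = cluster_subtypes(ExpressionMatrix(y, *ids))
        assert adjusted_rand_score([a.labels[s] for s in ids[1]],
                                   [b.labels[s] for s in ids[1]]) == 1.0


class TestOrientClusters:
    def test_marker_contrast_names_mes(self, planted_cohort):
        expr = planted_cohort.expression.subset_genes(
            list(planted_cohort.planted_signature))
        oriented = orient_clusters(cluster_subtypes(expr),
                                   planted_cohort.expression)
        pred = [oriented.labels[s] for s in expr.sample_ids]
        truth = _labels(planted_cohort, expr.sample_ids)
        assert np.mean([p == t for p, t in zip(pred, truth)]) >= 0.95

    def test_orientation_correct_across_seeds(self):
        for seed in range(20):
            c = generate_expression_cohort(CohortSpec(
                n_samples=60, effect_size=2.0, seed=seed))
            expr = c.expression.subset_genes(list(c.planted_signature))
            oriented = orient_clusters(cluster_subtypes(expr), c.expression)
            pred = [oriented.labels[s] for s in expr.sample_ids]
            truth = _labels(c, expr.sample_ids)
            agree = np.mean([p == t for p, t in zip(pred, truth)])
            assert agree > 0.9, f"seed {seed}: agreement {agree}"

    def test_mes_cluster_scores_higher_emt(self, planted_cohort):
        c = planted_cohort
        expr = c.expression.subset_genes(list(c.planted_signature))
        oriented = orient_clusters(cluster_subtypes(expr), c.expression)
        epi_set = [g for g, d in c.planted_signature.items()
                   if d == "epithelial-up"]
        mes_set = [g for g, d in c.planted_signature.items()
                   if d == "mesenchymal-up"]
        scores = compute_emt_score(c.expression, epi_set, mes_set).scores
        mes_mean = np.mean([scores[s] for s, lab in oriented.labels.items()
                            if lab == MES])
        epi_mean = np.mean([scores[s] for s, lab in oriented.labels.items()
                            if lab == EPI])
        assert mes_mean > epi_mean


def _brute_force_emt(values, is_mes):
    """Exhaustive signed-KS: evaluate both ECDF differences at every rank."""
    from scipy.stats import rankdata

    ranks = rankdata(-np.asarray(values, dtype=float), method="average")
    d_plus = d_minus = 0.0
    for t in ranks:
        f_mes = np.mean(ranks[is_mes] <= t)
        f_epi = np.mean(ranks[~is_mes] <= t)
        d_plus = max(d_plus, f_mes - f_epi)
        d_minus = max(d_minus, f_epi - f_mes)
    return max(0.0, d_plus) - max(0.0, d_minus)


class TestEMTScore:
    def _score_single(self, values, epi, mes):
        genes = epi + mes
        expr = ExpressionMatrix(np.asarray(values, dtype=float)[:, None],
                                genes, ["s"])
        return compute_emt_score(expr, epi, mes).scores["s"]

    def test_fully_mesenchymal_sample_scores_plus_one(self):
        epi = [f"e{i}" for i in range(10)]
        mes = [f"m{i}" for i in range(10)]
        values = list(range(10, 0, -1)) + list(range(20, 10, -1))
        assert self._score_single(values, epi, mes) == pytest.approx(1.0)

    def test_fully_epithelial_sample_scores_minus_one(self):
        epi = [f"e{i}" for i in range(10)]
        mes = [f"m{i}" for i in range(10)]
        values = list(range(20, 10, -1)) + list(range(10, 0, -1))
        assert self._score_single(values, epi, mes) == pytest.approx(-1.0)

    def test_interleaved_four_gene_example(self):
        # g3=10 > g1=8 > g4=6 > g2=4 with epi={g1,g2}, mes={g3,g4}
        expr = ExpressionMatrix(np.array([[8.0], [4.0], [10.0], [6.0]]),
                                ["g1", "g2", "g3", "g4"], ["s"])
        sv = compute_emt_score(expr, ["g1", "g2"], ["g3", "g4"])
        assert sv.scores["s"] == pytest.approx(0.5)
        assert sv.d_plus["s"] == pytest.approx(0.5)
        assert sv.d_minus["s"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_small_sets(self, rng):
        for _ in range(50):
            n_epi = int(rng.integers(2, 5))
            n_mes = int(rng.integers(2, 5))
            values = rng.choice(np.arange(10.0), size=n_epi + n_mes,
                                replace=True)  # ties included
            epi = [f"e{i}" for i in range(n_epi)]
            mes = [f"m{i}" for i in range(n_mes)]
            is_mes = np.array([False] * n_epi + [True] * n_mes)
            expected = _brute_force_emt(values, is_mes)
            assert self._score_single(list(values), epi, mes) == \
                pytest.approx(expected)

    @given(st.lists(st.integers(min_value=-50, max_value=50),
                    min_size=8, max_size=8),
           st.floats(min_value=0.5, max_value=3.0))
    @settings(max_examples=50, derandomize=True)
    def test_bounds_and_monotone_invariance(self, values, power):
        epi = [f"e{i}" for i in range(4)]
        mes = [f"m{i}" for i in range(4)]
        values = [float(v) for v in values]
        score = self._score_single(values, epi, mes)
        assert -1.0 <= score <= 1.0
        # strictly increasing transform preserves ranks hence the score
        transformed = [np.sign(v) * abs(v) ** power + 3.0 for v in values]
        assert self._score_single(transformed, epi, mes) == \
            pytest.approx(score)

    def test_overlapping_sets_error(self, planted_cohort):
        with pytest.raises(ValueError, match="overlap"):
            compute_emt_score(planted_cohort.expression,
                              ["CDH1", "VIM"], ["VIM", "FN1"])

    def test_small_sets_error(self, planted_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            compute_emt_score(planted_cohort.expression, ["CDH1"],
                              ["VIM", "FN1"])


class TestClusterMethylation:
    def _matrix(self, beta):
        beta = np.asarray(beta, dtype=float)
        return MethylationMatrix(beta, [f"p{i}" for i in range(beta.shape[0])],
                                 [f"s{i}" for i in range(beta.shape[1])])

    def test_identical_samples_co_cluster(self, rng):
        base = rng.uniform(size=(20, 1))
        beta = np.hstack([base, base, rng.uniform(size=(20, 3))])
        a = cluster_methylation(self._matrix(beta))
        assert a.labels["s0"] == a.labels["s1"]

    def test_beta_exactly_cutoff_is_hypermethylated(self):
        # a column of exactly-0.3 betas groups with the hypermethylated side
        beta = np.column_stack([np.full(10, 0.3), np.full(10, 0.9),
                                np.full(10, 0.95),
                                np.full(10, 0.05), np.full(10, 0.0),
                                np.full(10, 0.02)])
        beta[0, 3:] = 0.9  # avoid an all-zero binary vector oddity
        a = cluster_methylation(self._matrix(beta))
        assert a.labels["s0"] == a.labels["s1"] == a.labels["s2"]
        assert a.labels["s3"] == a.labels["s4"] == a.labels["s5"]
        assert a.labels["s0"] != a.labels["s3"]

    def test_planted_two_block_structure(self, rng):
        probes, samples = 100, 40
        truth = np.array([0] * 20 + [1] * 20)
        block = np.zeros((probes, samples), dtype=bool)
        block[:50, truth == 0] = True
        block[50:, truth == 1] = True
        flips = rng.random((probes, samples)) < 0.05
        binary = block ^ flips
        beta = np.where(binary, 0.8, 0.1)
        a = cluster_methylation(self._matrix(beta))
        pred = [a.labels[f"s{i}"] for i in range(samples)]
        assert adjusted_rand_score(list(truth), pred) >= 0.9

    def test_no_hypermethylated_probes_error(self):
        with pytest.raises(ValueError, match="hypermethylated"):
            cluster_methylation(self._matrix(np.full((5, 6), 0.1)))

    def test_beta_out_of_range_error(self):
        with pytest.raises(ValueError, match="beta"):
            self._matrix(np.full((3, 4), 1.2))


def test_marker_set_validation():
    with pytest.raises(ValueError, match="overlap"):
        MarkerSet(epithelial_markers=("CDH1",), mesenchymal_markers=("CDH1",))
    with pytest.raises(ValueError, match="nonempty"):
        MarkerSet(epithelial_markers=(), mesenchymal_markers=("VIM",))
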