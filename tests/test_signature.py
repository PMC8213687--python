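import itertools
import math

import numpy as np
import pytest
from scipy import stats

from permdeg import (
    GeneSet,
    NormalizedMatrix,
    ValidationError,
    cluster_mt_signature,
    compare_groups_wilcoxon,
    ddct_fold,
    fisher_exact_2x2,
    genomic_copy_ratio,
    linear_assoc,
    signature_score,
    spearman_assoc,
)
from permdeg.signature import MT_SIGNATURE_GENES, extreme_score_samples


def make_norm(cpm, gene_ids=None, sample_ids=None):
    cpm = np.asarray(cpm, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(cpm.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(cpm.shape[1])]
    return NormalizedMatrix(gene_ids, sample_ids, cpm, np.ones(cpm.shape[1]))


class TestSignatureScore:
    def test_exact_sum(self):
        norm = make_norm(np.full((8, 3), 1000.0), gene_ids=list(MT_SIGNATURE_GENES))
        scores = signature_score(norm)
        assert [s.score for s in scores] == [8000.0] * 3

    def test_missing_gene_listed(self):
        norm = make_norm(np.ones((2, 2)))
        with pytest.raises(ValidationError, match="MT-ND1"):
            signature_score(norm)

    def test_additivity(self):
        rng = np.random.default_rng(1)
        norm = make_norm(rng.gamma(2, 100, size=(6, 4)))
        s_ab = signature_score(norm, GeneSet("ab", ("G0", "G1", "G2", "G3")))
        s_a = signature_score(norm, GeneSet("a", ("G0", "G1")))
        s_b = signature_score(norm, GeneSet("b", ("G2", "G3")))
        for ab, a, b in zip(s_ab, s_a, s_b):
            assert ab.score == pytest.approx(a.score + b.score)

    def test_block_elevation_detected(self):
        from permdeg import MtBlockSpec, SimulationConfig, cpm_normalize, simulate_cohort

        config = SimulationConfig(
            seed=7,
            n_genes=100,
            group_sizes={("male", "control"): 20, ("male", "Eex"): 20},
            mt_block=MtBlockSpec(gene_indices=tuple(range(8)), fold=2.0, subgroup="Eex"),
        )
        counts, metadata, truth = simulate_cohort(config)
        norm = cpm_normalize(counts)
        mt_ids = tuple(truth.loc[truth.kind == "mt_block", "gene_id"])
        scores = {s.sample_id: s.score for s in signature_score(norm, GeneSet("mt", mt_ids))}
        eex = [scores[m.sample_id] for m in metadata if m.subphenotype == "Eex"]
        ctl = [scores[m.sample_id] for m in metadata if m.disease_status == "control"]
        assert np.mean(eex) / np.mean(ctl) == pytest.approx(2.0, rel=0.15)


class TestWilcoxon:
    def test_extreme_small_sample(self):
        assert compare_groups_wilcoxon([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert compare_groups_wilcoxon([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            ours = compare_groups_wilcoxon(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_large_n_null_uniform(self):
        rng = np.random.default_rng(3)
        ps = [
            compare_groups_wilcoxon(rng.normal(size=25), rng.normal(size=25))
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups_wilcoxon([], [1.0])


class TestCluster:
    def test_two_blocks_recovered(self):
        rng = np.random.default_rng(11)
        base = rng.gamma(5, 200, size=(8, 1))
        high = base * 3 * rng.lognormal(0, 0.05, size=(8, 6))
        low = base * 1 * rng.lognormal(0, 0.05, size=(8, 6))
        cpm = np.hstack([high, low])
        norm = make_norm(cpm, gene_ids=list(MT_SIGNATURE_GENES))
        assignments, tree = cluster_mt_signature(norm)
        labels = {a.sample_id: a.cluster for a in assignments}
        assert all(labels[f"S{j}"] == "high" for j in range(6))
        assert all(labels[f"S{j}"] == "low" for j in range(6, 12))
        assert tree.shape == (11, 4)

    def test_every_sample_assigned_once_into_two_clusters(self):
        rng = np.random.default_rng(12)
        norm = make_norm(rng.gamma(2, 50, (8, 10)), gene_ids=list(MT_SIGNATURE_GENES))
        assignments, _ = cluster_mt_signature(norm)
        assert len(assignments) == 10
        assert {a.cluster for a in assignments} == {"high", "low"}

    def test_all_identical_samples_degenerate(self):
        norm = make_norm(np.full((8, 5), 100.0), gene_ids=list(MT_SIGNATURE_GENES))
        with pytest.raises(ValidationError), pytest.warns(UserWarning):
            cluster_mt_signature(norm)

    def test_zero_variance_row_dropped_with_warning(self):
        rng = np.random.default_rng(13)
        cpm = rng.gamma(2, 50, (8, 8))
        cpm[3] = 42.0
        norm = make_norm(cpm, gene_ids=list(MT_SIGNATURE_GENES))
        with pytest.warns(UserWarning, match="MT-ND5"):
            assignments, _ = cluster_mt_signature(norm)
        assert len(assignments) == 8

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(14)
        cpm = rng.gamma(2, 50, (8, 9))
        cpm[:, :4] *= 4
        norm = make_norm(cpm, gene_ids=list(MT_SIGNATURE_GENES))
        a1, _ = cluster_mt_signature(norm)
        perm = rng.permutation(9)
        norm2 = make_norm(
            cpm[:, perm],
            gene_ids=list(MT_SIGNATURE_GENES),
            sample_ids=[f"S{j}" for j in perm],
        )
        a2, _ = cluster_mt_signature(norm2)
        m1 = {a.sample_id: a.cluster for a in a1}
        m2 = {a.sample_id: a.cluster for a in a2}
        assert m1 == m2

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(15)
        cpm = rng.gamma(2, 50, (8, 9))
        cpm[:, :4] *= 4
        norm = make_norm(cpm, gene_ids=list(MT_SIGNATURE_GENES))
        a1, _ = cluster_mt_signature(norm)
        scale = rng.uniform(0.5, 5, size=(8, 1))
        a2, _ = cluster_mt_signature(
            make_norm(cpm * scale, gene_ids=list(MT_SIGNATURE_GENES))
        )
        # per-gene scaling is removed by row z-scoring; cluster naming may
        # follow the rescaled scores but the partition must be identical
        part1 = {a.sample_id for a in a1 if a.cluster == "high"}
        part2 = {a.sample_id for a in a2 if a.cluster == "high"}
        assert part2 in (part1, {a.sample_id for a in a1} - part1)

    def test_extreme_score_subsets(self):
        from permdeg.signature import SignatureScore

        scores = [SignatureScore(f"S{i}", float(i)) for i in range(10)]
        top, bottom = extreme_score_samples(scores, k=3)
        assert top == ["S9", "S8", "S7"]
        assert bottom == ["S2", "S1", "S0"]


def brute_force_fisher(table):
    """Enumerate all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    probs = {}
    for k in range(max(0, c1 - (c + d)), min(r1, c1) + 1):
        probs[k] = (
            math.comb(r1, k)
            * math.comb(n - r1, c1 - k)
            / math.comb(n, c1)
        )
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_one_nine_table(self):
        expected = brute_force_fisher([[1, 9], [9, 1]])
        assert fisher_exact_2x2([[1, 9], [9, 1]]) == pytest.approx(expected)
        # reference value cross-checked against R's fisher.test
        assert expected == pytest.approx(0.001093334, abs=1e-8)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_agrees_with_enumeration_totals_up_to_30(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() == 0 or t.sum() > 30:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(brute_force_fisher(t.tolist()))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            ref = stats.fisher_exact(t, alternative="two-sided")[1]
            assert fisher_exact_2x2(t) == pytest.approx(float(ref), rel=1e-6)


class TestSpearman:
    def test_monotone_increasing(self):
        rho, p = spearman_assoc([1, 2, 3, 4, 5], [10, 20, 25, 70, 90])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman_assoc([1, 2, 3, 4], [9, 7, 5, 3])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 9.0, 2.5, 3.0]
        rho, p = spearman_assoc(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(stats.pearsonr(rx, ry)[0])
        hits = sum(
            abs(stats.pearsonr(rx, perm)[0]) >= obs - 1e-9
            for perm in itertools.permutations(ry)
        )
        assert p == pytest.approx(hits / math.factorial(5))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic), rel=1e-9)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestLinearAssoc:
    def test_near_deterministic_positive_slope(self):
        rng = np.random.default_rng(40)
        s = rng.uniform(0, 10, 30)
        table = linear_assoc(s, {"cov": 2 * s + rng.normal(0, 1e-9, 30)})
        row = table.iloc[0]
        assert row.slope_sign == "positive"
        assert row.slope == pytest.approx(2.0, rel=1e-6)
        assert row.p_value < 1e-12

    def test_independent_covariate_null_uniform(self):
        rng = np.random.default_rng(41)
        ps = []
        for _ in range(150):
            s = rng.normal(size=20)
            ps.append(float(linear_assoc(s, {"c": rng.normal(size=20)}).p_value.iloc[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_three_point_line_closed_form(self):
        s = np.array([0.0, 1.0, 2.0])
        cov = np.array([1.0, 2.9, 5.2])  # not exactly linear -> 1 df t-test
        table = linear_assoc(s, {"c": cov})
        fit = stats.linregress(s, cov)
        assert table.slope.iloc[0] == pytest.approx(fit.slope)
        assert table.p_value.iloc[0] == pytest.approx(fit.pvalue)

    def test_missing_values_dropped_pairwise(self):
        s = [1.0, 2.0, 3.0, 4.0]
        table = linear_assoc(s, {"c": [2.0, None, 6.0, 8.0]})
        assert table.n.iloc[0] == 3

    def test_fdr_across_covariates(self):
        rng = np.random.default_rng(42)
        s = rng.uniform(0, 1, 25)
        table = linear_assoc(
            s, {"a": 3 * s + rng.normal(0, 0.01, 25), "b": rng.normal(size=25)}
        )
        assert (table.fdr >= table.p_value - 1e-15).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            linear_assoc([1.0, 2.0, 3.0], {"c": [5.0, 5.0, 5.0]})


class TestQpcrArithmetic:
    def test_integer_exponent(self):
        assert ddct_fold(16.0, 24.0) == 256.0

    def test_equal_ct(self):
        assert ddct_fold(21.5, 21.5) == 1.0

    def test_inverts_log2(self):
        fold = 379.0
        assert ddct_fold(24.0 - math.log2(fold), 24.0) == pytest.approx(fold, rel=1e-9)

    def test_copy_ratio_worked_example(self):
        assert genomic_copy_ratio(440.0, 379.0) == 1.2

    def test_copy_ratio_identity(self):
        assert genomic_copy_ratio(123.4, 123.4) == 1.0

    def test_copy_ratio_double(self):
        assert genomic_copy_ratio(200.0, 100.0) == 2.0

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            genomic_copy_ratio(0.0, 10.0)
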