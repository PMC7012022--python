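import numpy as np
import pandas as pd
import pytest

from repairscore import (
    CohortParams,
    ExpressionParams,
    classify_pathways,
    compute_scores,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    per_gene_association,
    preranked_gsea,
    size_factors,
    subsample_robustness,
)
from repairscore.enrichment import enrichment_score


def brute_force_es(metric: pd.Series, members, weight=1.0):
    """Independent literal walk of the weighted KS running sum."""
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    in_set = set(members) & set(order)
    n, k = len(order), len(in_set)
    r_sum = sum(abs(metric[g]) ** weight for g in in_set)
    running, best = 0.0, 0.0
    for g in order:
        if g in in_set:
            running += (abs(metric[g]) ** weight / r_sum) if r_sum > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def extremum_is_tied(metric, members, weight=1.0, tol=1e-9):
    """True when the running sum's max and min have (nearly) equal magnitude.

    At an exact magnitude tie the ES sign is a pure tie-break convention,
    so equality checks between independent implementations skip such draws.
    """
    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    in_set = set(members) & set(order)
    n, k = len(order), len(in_set)
    if k == n:
        return False
    r_sum = sum(abs(metric[g]) ** weight for g in in_set)
    running, lo, hi = 0.0, 0.0, 0.0
    for g in order:
        if g in in_set:
            running += (abs(metric[g]) ** weight / r_sum) if r_sum > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        lo, hi = min(lo, running), max(hi, running)
    return min(abs(lo), abs(hi)) > 0 and abs(abs(lo) - abs(hi)) < tol


class TestSizeFactors:
    def test_identical_samples(self):
        c = pd.DataFrame({"a": [5, 8, 2], "b": [5, 8, 2]}, index=["g1", "g2", "g3"])
        np.testing.assert_allclose(size_factors(c), [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        f = size_factors(c)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_single_sample(self):
        c = pd.DataFrame({"a": [3, 4, 5]}, index=list("pqr"))
        np.testing.assert_allclose(size_factors(c), [1.0])

    def test_no_common_gene_raises(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="filter"):
            size_factors(c)


class TestPerGeneAssociation:
    def _covariates(self, rng, n):
        return pd.DataFrame(
            {
                "age": rng.normal(60, 8, n),
                "sex": rng.choice(["male", "female"], n),
                "smoking": rng.choice(["past", "current"], n),
            }
        )

    def test_constant_gene_gets_exact_zero(self):
        rng = np.random.default_rng(0)
        n = 30
        counts = pd.DataFrame(
            {f"s{i}": [50, int(v)] for i, v in enumerate(rng.poisson(100, n))},
            index=["flat", "noisy"],
        )
        unit = pd.Series(np.ones(n), index=counts.columns)
        gs = per_gene_association(counts, rng.normal(4, 1, n), None, min_mean=0,
                                  factors=unit)
        row = gs.table.loc["flat"]
        assert row.slope == pytest.approx(0.0, abs=1e-9)
        assert row.t == 0.0 and not np.isnan(row.t)

    def test_noiseless_constructed_slope(self):
        """Counts built so log2(count + 0.5) = 12 - 0.5*score exactly:
        recovered slope -0.5 to 1e-8, |t| hits the noiseless-fit cap."""
        rng = np.random.default_rng(1)
        n = 40
        score = rng.normal(4, 1, n)
        vals = 2.0 ** (12 - 0.5 * score) - 0.5  # cancels the pseudo-count
        counts = pd.DataFrame(
            np.vstack([vals, np.full(n, 2.0**12)]),
            index=["signal", "ref"],
            columns=[f"s{i}" for i in range(n)],
        )
        unit = pd.Series(np.ones(n), index=counts.columns)
        gs = per_gene_association(counts, score, None, min_mean=0, factors=unit)
        row = gs.table.loc["signal"]
        assert row.slope == pytest.approx(-0.5, abs=1e-8)
        assert 1e5 <= abs(row.t) <= 1e6

    def test_null_p_values_calibrated(self):
        """All betas zero: p-values approximately uniform over 2000 genes."""
        rng = np.random.default_rng(7)
        cohort = generate_cohort(CohortParams(n_controls=60, n_cases=0), seed=3)
        s = compute_scores(cohort)
        ep = ExpressionParams(n_genes=2000, n_immune_genes=0, n_cellcycle_genes=0,
                              beta_immune_case=0.0, beta_cellcycle=0.0, seed=5)
        counts, batch = generate_expression(cohort, s, ep)
        cov = pd.DataFrame({"age": cohort.age.to_numpy(), "sex": cohort.sex.to_numpy(),
                            "smoking": cohort.smoking.to_numpy(), "batch": batch.to_numpy()})
        gs = per_gene_association(counts, np.asarray(s), cov)
        from scipy.stats import kstest

        ks = kstest(gs.table.p, "uniform").statistic
        assert ks < 0.05
        frac = (gs.table.p < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_sign_recovery_planted_negative_slope(self):
        """Noiseless immune signal in cases: every immune slope negative."""
        cohort = generate_cohort(CohortParams(n_controls=0, n_cases=50), seed=9)
        s = compute_scores(cohort)
        ep = ExpressionParams(n_genes=100, n_immune_genes=30, n_cellcycle_genes=0,
                              beta_immune_case=-0.5, dispersion=0.0,
                              library_size_log_sd=0.0, batch_effect_sd=0.0, seed=2)
        counts, _ = generate_expression(cohort, s, ep)
        gs = per_gene_association(counts, np.asarray(s), None, min_mean=0)
        from repairscore.expression_sim import immune_genes

        imm = [g for g in immune_genes(ep) if g in gs.table.index]
        assert len(imm) > 20
        assert (gs.table.loc[imm, "slope"] < 0).all()

    def test_too_few_samples_raises(self):
        counts = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="samples"):
            per_gene_association(counts, np.arange(3.0), None)


class TestDegenerateExpression:
    def test_zero_dispersion_counts_equal_rounded_means(self):
        cohort = generate_cohort(CohortParams(n_controls=5, n_cases=5), seed=1)
        s = compute_scores(cohort)
        ep = ExpressionParams(n_genes=50, n_immune_genes=10, n_cellcycle_genes=5,
                              dispersion=0.0, library_size_log_sd=0.0,
                              batch_effect_sd=0.0, seed=4)
        c1, _ = generate_expression(cohort, s, ep)
        c2, _ = generate_expression(cohort, s, ep)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.to_numpy() >= 0).all()

    def test_alignment_error(self):
        cohort = generate_cohort(CohortParams(n_controls=5, n_cases=5), seed=1)
        with pytest.raises(ValueError, match="aligned"):
            generate_expression(cohort, np.arange(3.0), ExpressionParams(n_genes=10,
                                n_immune_genes=2, n_cellcycle_genes=2))


class TestGeneSets:
    def test_construction_counts_and_names(self):
        ep = ExpressionParams(n_genes=500, n_immune_genes=150, n_cellcycle_genes=80)
        sets = generate_gene_sets(ep, n_immune_sets=5, n_cellcycle_sets=2,
                                  n_neutral_sets=3, set_size=20, seed=0)
        imm = [n for n in sets if "IMMUNE" in n]
        assert len(imm) == 5 and all(len(sets[n]) == 20 for n in imm)
        assert classify_pathways(list(sets)) == (
            ["immune"] * 5 + ["cell_cycle"] * 2 + ["other"] * 3
        )
        # pairwise disjoint
        all_members = sum((sets[n] for n in sets), [])
        assert len(all_members) == len(set(all_members))

    def test_zero_neutral_sets(self):
        ep = ExpressionParams(n_genes=500, n_immune_genes=150, n_cellcycle_genes=80)
        sets = generate_gene_sets(ep, n_immune_sets=2, n_cellcycle_sets=2,
                                  n_neutral_sets=0, set_size=20, seed=0)
        assert all("NEUTRAL" not in n for n in sets)

    def test_oversized_set_raises(self):
        ep = ExpressionParams(n_genes=500, n_immune_genes=150, n_cellcycle_genes=80)
        with pytest.raises(ValueError, match="exceed"):
            generate_gene_sets(ep, set_size=600, seed=0)


class TestPrerankedGsea:
    METRIC5 = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                        index=["g1", "g2", "g3", "g4", "g5"])

    def test_hand_walk_es(self):
        """Running sum 0.75, 0.4167, 0.6667, 0.3333, 0 -> ES 0.75."""
        assert enrichment_score(self.METRIC5, {"g1", "g3"}) == pytest.approx(0.75)

    def test_full_set_es_one(self):
        assert enrichment_score(self.METRIC5, set(self.METRIC5.index)) == 1.0

    def test_brute_force_equality_small_lists(self):
        """ES matches an independent literal running-sum walk on all
        random lists of <= 10 genes."""
        rng = np.random.default_rng(17)
        for trial in range(300):
            n = rng.integers(3, 11)
            metric = pd.Series(np.round(rng.normal(size=n), 3),
                               index=[f"g{i}" for i in range(n)])
            k = rng.integers(1, n)
            members = set(rng.choice(metric.index, size=k, replace=False))
            if extremum_is_tied(metric, members):
                continue
            assert enrichment_score(metric, members) == pytest.approx(
                brute_force_es(metric, members), abs=1e-12
            )

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(3)
        metric = pd.Series(rng.normal(size=9), index=[f"g{i}" for i in range(9)])
        members = {"g1", "g4", "g7"}
        es = enrichment_score(metric, members)
        es_neg = enrichment_score(-metric, members)
        assert es_neg == pytest.approx(-es, abs=1e-12)

    def test_null_permutation_p_uniform(self):
        """Random sets against a null ranking give ~uniform permutation p."""
        rng = np.random.default_rng(23)
        metric = pd.Series(rng.standard_normal(300),
                           index=[f"g{i:04d}" for i in range(300)])
        ps = []
        for rep in range(150):
            members = rng.choice(metric.index, size=20, replace=False)
            res = preranked_gsea(metric, {"S": list(members)}, n_perm=200,
                                 seed=rep, min_size=15)
            ps.append(res.table.p.iloc[0])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.1

    def test_size_bounds_and_overlap_skipping(self):
        metric = pd.Series(np.arange(50.0, 0, -1), index=[f"g{i}" for i in range(50)])
        sets = {
            "tiny": ["g1", "g2"],
            "alien": ["x1", "x2", "x3"],
            "ok": [f"g{i}" for i in range(0, 40, 2)],
        }
        res = preranked_gsea(metric, sets, n_perm=100, seed=0, min_size=15, max_size=30)
        assert res.table.set.tolist() == ["ok"]
        reasons = dict(zip(res.skipped.set, res.skipped.reason))
        assert "min_size" in reasons["tiny"]
        assert "overlap" in reasons["alien"]

    def test_invalid_inputs(self):
        metric = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="n_perm"):
            preranked_gsea(metric, {}, n_perm=10)
        dup = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            preranked_gsea(dup, {}, n_perm=100)
        zero = pd.Series([0.0, 0.0], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            preranked_gsea(zero, {}, n_perm=100)


class TestClassifyPathways:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("GO_T_CELL_ACTIVATION", "immune"),
            ("GO_MITOTIC_NUCLEAR_DIVISION", "cell_cycle"),
            ("GO_LIPID_TRANSPORT", "other"),
        ],
    )
    def test_default_keywords(self, name, expected):
        assert classify_pathways([name]) == [expected]

    def test_immune_precedence_on_double_match(self):
        assert classify_pathways(["IMMUNE_CHECKPOINT_PATHWAY"]) == ["immune"]

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            classify_pathways(["X"], {"immune": [], "cell_cycle": ["m"]})


class TestSubsampleRobustness:
    def _setup(self, seed=0):
        cohort = generate_cohort(CohortParams(n_controls=0, n_cases=60), seed=seed)
        s = compute_scores(cohort)
        ep = ExpressionParams(n_genes=150, n_immune_genes=80, n_cellcycle_genes=20,
                              beta_immune_case=-0.5, beta_cellcycle=0.0, seed=seed)
        counts, batch = generate_expression(cohort, s, ep)
        sets = generate_gene_sets(ep, n_immune_sets=3, n_cellcycle_sets=1,
                                  n_neutral_sets=2, set_size=16, seed=seed)
        cov = pd.DataFrame({"batch": batch.to_numpy()})
        return counts, np.asarray(s), cov, sets

    def test_fraction_one_reproduces_full_result(self):
        counts, s, cov, sets = self._setup()
        runs = subsample_robustness(counts, s, cov, sets, fraction=1.0,
                                    n_repeats=5, seed=11, n_perm=100, min_size=10)
        assert runs.drop(columns="repeat").nunique().max() == 1

    def test_planted_case_signal_recovered_across_subsamples(self):
        counts, s, cov, sets = self._setup(seed=2)
        runs = subsample_robustness(counts, s, cov, sets, fraction=0.8,
                                    n_repeats=10, seed=5, n_perm=200, min_size=10)
        assert (runs.immune >= 2).sum() >= 8

    def test_invalid_fraction(self):
        counts, s, cov, sets = self._setup()
        with pytest.raises(ValueError):
            subsample_robustness(counts, s, cov, sets, fraction=0.0, n_repeats=5)
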