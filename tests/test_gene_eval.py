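import numpy as np
import pytest

from divtime.gene_eval import (
    GeneComparison,
    RateEstimate,
    ci_overlap,
    ci_width_table,
    compare_gene,
    kendall_tau,
    kruskal_wallis,
    mean_ci_widths,
    rate_based_root_age,
    saturation_table,
)
from divtime.summaries import NodeAgeSummary

from conftest import balanced_quartet, caterpillar


def summary(split, median, lower, upper, pp=1.0):
    return NodeAgeSummary(split=frozenset(split), pp=pp, mean=median,
                          median=median, lower=lower, upper=upper)


class TestKendallTau:
    def test_identical_rankings(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_reversed_rankings(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=8), rng.normal(size=8)
        tau, _ = kendall_tau(x, y)
        concordant = discordant = 0
        for i in range(8):
            for j in range(i + 1, 8):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                concordant += s > 0
                discordant += s < 0
        expected = (concordant - discordant) / (8 * 7 / 2)
        assert tau == pytest.approx(expected)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            kendall_tau([1], [2])

    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(1)
        for n in (3, 6, 12):
            x = rng.normal(size=n)
            assert kendall_tau(x, x)[0] == pytest.approx(1.0)


class TestKruskalWallis:
    def test_worked_example(self):
        # ranks 1..4; R1=3, R2=7; H = (12/20)(9/2 + 49/2) - 15 = 2.4
        h, p = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert h == pytest.approx(2.4)
        assert 0 < p < 1

    def test_label_permutation_symmetry(self):
        g1, g2 = np.array([1.0, 5.0, 2.0]), np.array([4.0, 3.0, 6.0])
        h1, _ = kruskal_wallis([g1, g2])
        h2, _ = kruskal_wallis([g2, g1])
        assert h1 == pytest.approx(h2)

    def test_identical_observations_zero(self):
        h, p = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert h == 0.0 and p == 1.0

    def test_matches_direct_formula_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 6, size=k).astype(float) for k in (5, 7, 6)]
        h, _ = kruskal_wallis(groups)
        # direct rank-sum recomputation with tie correction
        pooled = np.concatenate(groups)
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        n = len(pooled)
        start, hsum = 0, 0.0
        for g in groups:
            r = ranks[start : start + len(g)]
            hsum += r.sum() ** 2 / len(g)
            start += len(g)
        hraw = 12.0 / (n * (n + 1)) * hsum - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
        assert h == pytest.approx(hraw / tie)


class TestCiOverlap:
    def test_identical_intervals(self):
        overlap, joint = ci_overlap([(10.0, 20.0), (10.0, 20.0)])
        assert overlap[0, 1] == 1.0 and joint

    def test_disjoint_intervals(self):
        overlap, joint = ci_overlap([(0.0, 5.0), (6.0, 9.0)])
        assert overlap[0, 1] == 0.0 and not joint

    def test_partial_overlap_jaccard(self):
        overlap, joint = ci_overlap([(0.0, 10.0), (5.0, 15.0)])
        assert overlap[0, 1] == pytest.approx(1 / 3)
        assert joint

    def test_joint_flag_three_intervals(self):
        _, joint = ci_overlap([(0, 10), (5, 15), (8, 20)])
        assert joint
        _, joint2 = ci_overlap([(0, 10), (5, 15), (12, 20)])
        assert not joint2


class TestCiWidths:
    def test_single_node(self):
        table = ci_width_table({"g": {frozenset("ab"): summary("ab", 45, 40, 50)}})
        assert table["width"].tolist() == [10.0]

    def test_missing_node_excluded_from_mean(self):
        combined = {
            frozenset("ab"): summary("ab", 45, 40, 50),
            frozenset("cd"): summary("cd", 30, 25, 35),
        }
        gene = {frozenset("ab"): summary("ab", 44, 38, 52)}
        comp = compare_gene("g1", gene, combined)
        assert len(comp.matched) == 1 and len(comp.missing) == 1
        widths = mean_ci_widths({"g1": gene})
        assert widths["g1"] == pytest.approx(14.0)

    def test_means_equal_recomputation(self):
        rng = np.random.default_rng(0)
        per_gene = {}
        for g in ("g1", "g2"):
            per_gene[g] = {}
            for k in range(5):
                lo = rng.uniform(10, 20)
                w = rng.uniform(1, 10)
                per_gene[g][frozenset({f"x{k}", f"y{k}"})] = summary(
                    {f"x{k}", f"y{k}"}, lo + w / 2, lo, lo + w
                )
        means = mean_ci_widths(per_gene)
        for g in per_gene:
            expected = np.mean([s.width for s in per_gene[g].values()])
            assert means[g] == pytest.approx(expected)


class TestGeneComparison:
    def test_matched_and_missing_partition_the_combined_set(self):
        combined = {
            frozenset("ab"): summary("ab", 45, 40, 50),
            frozenset("cd"): summary("cd", 30, 25, 35),
            frozenset("abcd"): summary("abcd", 70, 60, 80),
        }
        gene = {k: combined[k] for k in [frozenset("ab"), frozenset("abcd")]}
        comp = compare_gene("g", gene, combined)
        assert set(comp.matched) | set(comp.missing) == set(combined)
        assert not set(comp.matched) & set(comp.missing)
        table = comp.table()
        assert table["gene_median"].isna().sum() == 1


class TestSaturation:
    def test_star_like_tree_shares_root_age(self):
        from divtime.alignment import MultiGeneAlignment

        tree = balanced_quartet(ages=(49.99, 49.99, 50.0))
        mat = np.array([list("ACGT"), list("ACGA"), list("TCGT"), list("ACTT")])
        aln = MultiGeneAlignment(tree.taxa, {"g": mat})
        table = saturation_table(aln, tree)
        deep_pairs = table[table["mrca_age"] > 49.999]
        assert len(deep_pairs) == 4  # cross-cherry pairs hit the root
        assert set(np.round(table["mrca_age"], 2)) == {49.99, 50.0}

    def test_identical_sequences_zero_distance(self):
        from divtime.alignment import MultiGeneAlignment

        tree = balanced_quartet(ages=(0.01, 0.01, 50.0))
        mat = np.array([list("AAAA")] * 4)
        aln = MultiGeneAlignment(tree.taxa, {"g": mat})
        table = saturation_table(aln, tree)
        assert (table["p_distance"] == 0).all()

    def test_saturated_gene_flattens_at_depth(self):
        """A fast-evolving gene's distance-vs-age curve must flatten at
        large ages relative to a slow gene (saturation plateau)."""
        from divtime.clocks import ClockModel
        from divtime.simulate import FixtureSpec, simulate_alignment
        from divtime.substitution import jc_model
        from divtime.calibrations import Calibration, CalibrationSet

        taxa = [f"t{i}" for i in range(10)]
        ages = [10.0, 25.0, 45.0, 70.0, 100.0, 150.0, 220.0, 320.0, 450.0]
        tree = caterpillar(taxa, ages)
        cals = CalibrationSet(root=Calibration.uniform(52, 85))
        spec = FixtureSpec(
            n_taxa=10, gene_names=["slow", "fast"], gene_lengths=[2000, 2000],
            coding_flags=[False, False], clock=ClockModel("strict", c=0.001),
            calibrations=cals, models=[jc_model(), jc_model()],
            multipliers=np.array([0.2, 1.8]), seed=0,
        )
        rng = np.random.default_rng(0)
        aln = simulate_alignment(tree, np.full(tree.n_nodes, 0.001), spec, rng=rng)
        table = saturation_table(aln, tree)

        def late_over_early_slope(gene):
            sub = table[table["gene"] == gene]
            young = sub[sub["mrca_age"] <= 100]
            old = sub[sub["mrca_age"] >= 300]
            s_young = young["p_distance"].mean() / young["mrca_age"].mean()
            s_old = (old["p_distance"].mean() - young["p_distance"].mean()) / (
                old["mrca_age"].mean() - young["mrca_age"].mean()
            )
            return s_old / s_young

        assert late_over_early_slope("fast") < late_over_early_slope("slow")


class TestPrecisionGrowsWithData:
    """Mean credibility-interval widths must shrink as a gene gets longer
    (3 site-count levels x 5 seeds, monotone trend of the level means)."""

    @staticmethod
    def _mean_width(seed, length):
        from divtime.calibrations import Calibration, CalibrationSet
        from divtime.clocks import ClockModel, sample_branch_rates
        from divtime.mcmc import LognormalPrior, McmcConfig, run_mcmc
        from divtime.posterior import PhyloDatingModel
        from divtime.simulate import FixtureSpec, sample_calibrated_tree, simulate_alignment
        from divtime.substitution import SubstitutionModel
        from divtime.summaries import summarize_node_ages

        rng = np.random.default_rng(seed)
        cals = CalibrationSet(root=Calibration.uniform(52, 85))
        clock = ClockModel("IGR", c=0.002, nu=1.5e-3)
        sub = SubstitutionModel(np.array([1, 4, 1, 1, 4, 1.0]),
                                np.array([0.3, 0.2, 0.2, 0.3]), alpha=1.5, p_inv=0.1)
        spec = FixtureSpec(n_taxa=8, gene_names=["g"], gene_lengths=[length],
                           coding_flags=[False], clock=clock, calibrations=cals,
                           models=[sub], multipliers=np.array([1.0]), seed=seed)
        tree = sample_calibrated_tree(cals, 8, rng)
        rates = sample_branch_rates(clock, tree, rng)
        aln = simulate_alignment(tree, rates, spec, rng=rng)
        model = PhyloDatingModel(aln, spec.scheme, cals, clock_kind="IGR",
                                 clock_rate_prior=LognormalPrior(0.002, 1.0),
                                 topology=tree, topology_moves=False)
        init = model.state_from_truth(tree, clock, rates, [sub], np.array([1.0]))
        trace = run_mcmc(model, McmcConfig(n_generations=1500, sample_every=5),
                         np.random.default_rng([seed, length]), init_state=init)
        summaries = summarize_node_ages(trace.discard_burn_in(0.3))
        return np.mean([s.width for s in summaries.values()])

    def test_monotone_trend(self):
        level_means = [
            np.mean([self._mean_width(seed, length) for seed in range(5)])
            for length in (150, 600, 2400)
        ]
        assert level_means[0] > level_means[1] > level_means[2]


class TestRateBasedRootAge:
    def test_point_estimate(self):
        age, interval = rate_based_root_age(0.5, 1.0, RateEstimate("RAG1", 0.01))
        assert age == pytest.approx(50.0)
        assert interval is None

    def test_interval_propagation(self):
        age, interval = rate_based_root_age(
            0.5, 1.0, RateEstimate("RAG1", 0.01, interval=(0.008, 0.0125))
        )
        assert interval == pytest.approx((40.0, 62.5))

    def test_multiplier_linearity(self):
        a1, _ = rate_based_root_age(0.5, 1.0, RateEstimate("g", 0.01))
        a2, _ = rate_based_root_age(0.5, 2.0, RateEstimate("g", 0.01))
        assert a2 == pytest.approx(2 * a1)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            RateEstimate("g", 0.0)
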