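import math

import numpy as np
import pytest
from scipy import stats

from divtime.calibrations import (
    Calibration,
    CalibrationSet,
    TreeAgePrior,
    calibration_log_density,
    log_free_age_volume,
    sample_node_ages,
    tree_age_log_prior,
)
from divtime.trees import TimeTree

from conftest import balanced_quartet, caterpillar


def three_taxon(root_age=10.0, cherry_age=5.0):
    return caterpillar(["a", "b", "c"], [cherry_age, root_age])


class TestCalibrationDensities:
    def test_uniform_window(self):
        cal = Calibration.uniform(52.0, 85.0)
        assert calibration_log_density(cal, 60.0) == pytest.approx(math.log(1 / 33))
        assert calibration_log_density(cal, 51.9) == -math.inf
        assert calibration_log_density(cal, 85.1) == -math.inf

    def test_offset_exponential_at_offset(self):
        cal = Calibration.offset_exponential(18.0, 58.0)
        assert calibration_log_density(cal, 18.0) == pytest.approx(math.log(1 / 40))
        assert calibration_log_density(cal, 17.0) == -math.inf

    def test_offset_exponential_integrates_to_one(self):
        cal = Calibration.offset_exponential(16.3, 58.0)
        from scipy.integrate import quad

        val, _ = quad(lambda x: math.exp(calibration_log_density(cal, x)), 16.3, 2000)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            Calibration.uniform(85.0, 52.0)
        with pytest.raises(ValueError):
            Calibration.offset_exponential(58.0, 18.0)

    def test_overlapping_non_nested_clades_rejected(self):
        with pytest.raises(ValueError, match="nest"):
            CalibrationSet(
                root=Calibration.uniform(52, 85),
                nodes=[
                    Calibration.offset_exponential(10, 58, clade=["a", "b"]),
                    Calibration.offset_exponential(10, 58, clade=["b", "c"]),
                ],
            )


def root_only_cals(lo=10.0, hi=10.0):
    return CalibrationSet(root=Calibration.uniform(lo, hi))


class TestTreeAgePrior:
    def test_three_taxon_fixed_root(self):
        # single free age uniform on (0, 10): density 1/10
        tree = three_taxon()
        lp = tree_age_log_prior(tree, root_only_cals())
        assert lp == pytest.approx(math.log(1 / 10))

    def test_four_taxon_caterpillar_fixed_root(self):
        # two ordered free ages in (0,10): density 2/10^2
        tree = caterpillar(list("abcd"), [2.0, 5.0, 10.0])
        lp = tree_age_log_prior(tree, root_only_cals())
        assert lp == pytest.approx(math.log(2 / 100))

    def test_balanced_quartet_fixed_root(self):
        # two independent free ages in (0,10): density 1/100
        tree = balanced_quartet(ages=(3.0, 7.0, 10.0))
        lp = tree_age_log_prior(tree, root_only_cals())
        assert lp == pytest.approx(math.log(1 / 100))

    def test_monophyly_violation_is_minus_inf(self):
        tree = balanced_quartet(ages=(3.0, 7.0, 10.0))
        cals = CalibrationSet(
            root=Calibration.uniform(10, 10),
            nodes=[Calibration.offset_exponential(1.0, 5.0, clade=["a", "c"])],
        )
        assert tree_age_log_prior(tree, cals) == -math.inf

    def test_age_below_offset_is_minus_inf(self):
        tree = balanced_quartet(ages=(3.0, 7.0, 10.0))
        cals = CalibrationSet(
            root=Calibration.uniform(10, 10),
            nodes=[Calibration.offset_exponential(4.0, 20.0, clade=["a", "b"])],
        )
        assert tree_age_log_prior(tree, cals) == -math.inf

    def test_age_order_violation_is_minus_inf(self):
        tree = balanced_quartet(ages=(3.0, 7.0, 10.0))
        tree.ages[4] = 12.0  # older than the root
        assert tree_age_log_prior(tree, root_only_cals()) == -math.inf

    def test_volume_matches_rejection_oracle(self):
        # 6-taxon caterpillar, one internal node fixed: volume of the
        # remaining free-age region vs Monte-Carlo box sampling
        tree = caterpillar(list("abcdef"), [1.0, 3.0, 5.0, 7.0, 10.0])
        root_age = 10.0
        fixed = {8: 5.0}  # third internal node pinned
        logv = log_free_age_volume(tree, fixed, root_age)
        rng = np.random.default_rng(0)
        n = 400_000
        draws = rng.uniform(0, root_age, size=(n, 3))  # nodes 6, 7, 9
        t6, t7, t9 = draws[:, 0], draws[:, 1], draws[:, 2]
        ok = (t6 < t7) & (t7 < 5.0) & (t9 > 5.0) & (t9 < root_age)
        mc = ok.mean() * root_age**3
        assert math.exp(logv) == pytest.approx(mc, rel=0.02)

    def test_normalisation_by_grid_integration(self):
        # integrating the prior over the free ages recovers the product of
        # the root and node calibration densities (root here is a point
        # calibration, so only the fossil density should remain)
        tree = caterpillar(list("abcde"), [1.0, 3.0, 6.0, 9.0])
        cals = CalibrationSet(
            root=Calibration.uniform(9.0, 9.0),
            nodes=[Calibration.offset_exponential(2.0, 10.0, clade=["a", "b", "c"])],
        )
        prior = TreeAgePrior(cals)
        # calibrated node: clade abc = node 6, age 3.0; free ages: nodes 5, 7
        ncell = 201  # 9/201 divides the feasibility boundary at age 3 exactly
        h = 9.0 / ncell
        grid = (np.arange(ncell) + 0.5) * h
        total = 0.0
        for t5 in grid:
            for t7 in grid:
                tree.ages[5] = t5
                tree.ages[7] = t7
                lp = prior.log_density(tree)
                if np.isfinite(lp):
                    total += math.exp(lp) * h * h
        expected = math.exp(calibration_log_density(cals.nodes[0], 3.0))
        assert total == pytest.approx(expected, rel=1e-3)


class TestSampleNodeAges:
    def test_three_taxon_free_age_uniform(self):
        cals = root_only_cals()
        tree = three_taxon()
        rng = np.random.default_rng(1)
        ages = []
        for _ in range(10_000):
            sample_node_ages(tree, cals, rng)
            ages.append(tree.ages[3])
        ages = np.array(ages)
        assert ages.mean() == pytest.approx(5.0, abs=0.1)
        assert stats.kstest(ages, "uniform", args=(0, 10)).pvalue > 0.01

    def test_root_marginal_recovers_window(self):
        cals = CalibrationSet(root=Calibration.uniform(52.0, 85.0))
        tree = caterpillar(list("abcdef"), [1, 2, 3, 4, 60.0])
        rng = np.random.default_rng(2)
        roots = []
        for _ in range(5_000):
            sample_node_ages(tree, cals, rng)
            roots.append(tree.ages[tree.root])
        assert stats.kstest(np.array(roots), "uniform", args=(52, 33)).pvalue > 0.01

    def test_quartet_marginals_match_rejection_oracle(self):
        # balanced quartet, root fixed: the two cherry ages should be
        # independent uniforms; compare to a rejection sampler that draws
        # in the bounding box and keeps order-consistent vectors
        cals = root_only_cals()
        tree = balanced_quartet(ages=(3.0, 7.0, 10.0))
        rng = np.random.default_rng(3)
        ours = []
        for _ in range(4_000):
            sample_node_ages(tree, cals, rng)
            ours.append((tree.ages[4], tree.ages[5]))
        ours = np.array(ours)
        box = rng.uniform(0, 10, size=(8_000, 2))
        keep = box  # both ages only need to be < root: all draws feasible
        for dim in range(2):
            assert stats.ks_2samp(ours[:, dim], keep[:, dim]).pvalue > 0.01

    def test_sampled_trees_satisfy_calibrations(self):
        cals = CalibrationSet(
            root=Calibration.uniform(52, 85),
            nodes=[Calibration.offset_exponential(16.3, 58.0, clade=["a", "b", "c"])],
        )
        tree = caterpillar(list("abcdef"), [1, 2, 3, 4, 60.0])
        rng = np.random.default_rng(4)
        prior = TreeAgePrior(cals)
        for _ in range(200):
            sample_node_ages(tree, cals, rng)
            assert 52 <= tree.ages[tree.root] <= 85
            node = tree.find_clade(["a", "b", "c"])
            assert tree.ages[node] >= 16.3
            assert np.isfinite(prior.log_density(tree))
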