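import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divtime.alignment import MultiGeneAlignment, build_partition_scheme
from divtime.calibrations import Calibration, CalibrationSet
from divtime.likelihood import PatternData, log_likelihood
from divtime.mcmc import (
    LognormalPrior,
    McmcConfig,
    Trace,
    asdsf,
    effective_sample_size,
    empirical_bayes_clock_prior,
    heat,
    run_mcmc,
    split_frequencies,
)
from divtime.posterior import DatingState, PhyloDatingModel
from divtime.substitution import jc_model
from divtime.trees import random_constrained_topology

from conftest import balanced_quartet, caterpillar


def random_alignment(n_taxa=8, length=50, seed=0):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT"))
    taxa = [f"t{i}" for i in range(n_taxa)]
    return MultiGeneAlignment(taxa, {"g": chars[rng.integers(0, 4, (n_taxa, length))]})


class TestHeat:
    def test_cold_chain(self):
        assert heat(1, 0.1) == 1.0

    def test_fourth_chain(self):
        assert heat(4, 0.1) == pytest.approx(1 / 1.3)

    def test_zero_temperature_all_equal(self):
        assert all(heat(i, 0.0) == 1.0 for i in range(1, 5))

    def test_invalid(self):
        with pytest.raises(ValueError):
            heat(0, 0.1)
        with pytest.raises(ValueError):
            heat(1, -0.1)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        params = pd.DataFrame(
            {"generation": [10, 20, 30], "log_likelihood": [-5.0, -4.5, -4.8],
             "log_prior": [0.1, 0.2, 0.3], "root_age": [60.0, 61.0, 59.0]}
        )
        trees = [balanced_quartet(), balanced_quartet(), balanced_quartet()]
        trace = Trace(params, trees, run_id=1)
        trace.write(tmp_path / "run1")
        back = Trace.read(tmp_path / "run1", run_id=1)
        pd.testing.assert_frame_equal(back.params, params)
        assert len(back.trees) == 3
        assert back.trees[0].splits() == trees[0].splits()

    def test_non_increasing_generations_rejected(self):
        with pytest.raises(ValueError):
            Trace(pd.DataFrame({"generation": [10, 10]}))


@pytest.fixture(scope="module")
def prior_trace():
    aln = random_alignment()
    scheme = build_partition_scheme(["g"], [50], [False])
    cals = CalibrationSet(root=Calibration.uniform(52.0, 85.0))
    model = PhyloDatingModel(
        aln, scheme, cals, clock_kind="IGR",
        clock_rate_prior=LognormalPrior(0.002, 1.0),
    )
    cfg = McmcConfig(n_generations=100_000, sample_every=100, prior_only=True)
    return run_mcmc(model, cfg, 11).discard_burn_in(0.25)


class TestPriorRecovery:
    """Data-free runs must reproduce the joint prior marginals: the
    engine-wide detailed-balance check."""

    def test_root_age_uniform(self, prior_trace):
        roots = prior_trace.params["root_age"].to_numpy()
        assert stats.kstest(roots, "uniform", args=(52, 33)).pvalue > 0.01

    def test_clock_rate_lognormal(self, prior_trace):
        logc = np.log(prior_trace.params["clock_rate"].to_numpy())
        assert stats.kstest(logc, "norm", args=(math.log(0.002), 1.0)).pvalue > 0.01

    def test_clock_variance_exponential(self, prior_trace):
        nu = prior_trace.params["clock_var"].to_numpy()
        assert stats.kstest(nu, "expon", args=(0, 0.1)).pvalue > 0.01

    def test_gamma_shape_exponential(self, prior_trace):
        alpha = prior_trace.params["alpha_0"].to_numpy()
        assert stats.kstest(alpha, "expon").pvalue > 0.01

    def test_pinv_uniform(self, prior_trace):
        pinv = prior_trace.params["pinv_0"].to_numpy()
        assert stats.kstest(pinv, "uniform").pvalue > 0.01


class TestGridOracle:
    def test_strict_clock_rate_posterior_matches_grid(self):
        """Fixed tree, JC, strict clock: the 1-D clock-rate posterior from
        MCMC must match fine-grid numerical integration."""
        from divtime.clocks import ClockModel
        from divtime.simulate import FixtureSpec, simulate_alignment

        tree = caterpillar(list("abcde"), [10.0, 20.0, 40.0, 68.0])
        cals = CalibrationSet(root=Calibration.uniform(68.0, 68.0))
        spec = FixtureSpec(
            n_taxa=5, gene_names=["g"], gene_lengths=[400], coding_flags=[False],
            clock=ClockModel("strict", c=0.002), calibrations=cals,
            models=[jc_model()], multipliers=np.array([1.0]), seed=0,
        )
        aln = simulate_alignment(tree, np.full(tree.n_nodes, 0.002), spec,
                                 rng=np.random.default_rng(5))
        prior = LognormalPrior(0.002, 1.0)
        model = PhyloDatingModel(
            aln, spec.scheme, cals, clock_kind="strict", clock_rate_prior=prior,
            topology=tree, topology_moves=False,
            fixed=frozenset({"ages", "root", "scale_all", "topology",
                             "alpha", "pinv", "freqs", "exch", "mults"}),
        )
        init = DatingState(tree=tree.copy(), rates=None, c=0.002, nu=0.0,
                           models=[jc_model()], mult_weights=np.array([1.0]))
        trace = run_mcmc(model, McmcConfig(n_generations=20_000, sample_every=10),
                         3, init_state=init)
        cs = trace.discard_burn_in(0.25).params["clock_rate"].to_numpy()

        data = PatternData.from_matrix(aln.genes["g"])
        dur = tree.durations()
        grid = np.exp(np.linspace(math.log(5e-4), math.log(1e-2), 400))
        logpost = np.array(
            [prior.log_density(c) + log_likelihood(tree, c * dur, jc_model(), data)
             for c in grid]
        )
        w = np.exp(logpost - logpost.max()) * grid  # log-spaced grid: dc = c dlog c
        w /= w.sum()
        grid_mean = float((w * grid).sum())
        mc_se = cs.std() / math.sqrt(effective_sample_size(cs))
        assert abs(cs.mean() - grid_mean) < 4 * mc_se


def make_topology_trace(newicks):
    from divtime.trees import TimeTree

    trees = [TimeTree.from_newick(n) for n in newicks]
    params = pd.DataFrame({"generation": np.arange(1, len(trees) + 1) * 10,
                           "log_likelihood": np.zeros(len(trees)),
                           "log_prior": np.zeros(len(trees))})
    return Trace(params, trees)


class TestAsdsf:
    quartets = {
        "ab": "((a:1,b:1):1,(c:1,d:1):1);",
        "ac": "((a:1,c:1):1,(b:1,d:1):1);",
    }

    def test_identical_traces_zero(self):
        t = make_topology_trace([self.quartets["ab"]] * 4)
        assert asdsf([t, t]) == 0.0

    def test_two_point_sd(self):
        # one split at frequencies 1.0 and 0.0 -> SD 0.5 (n denominator)
        t1 = make_topology_trace([self.quartets["ab"]] * 3)
        t2 = make_topology_trace([self.quartets["ac"]] * 3)
        # every involved split has frequencies (1, 0) across the two runs
        assert asdsf([t1, t2]) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(6)]
        traces = []
        for _ in range(3):
            trees = [random_constrained_topology(taxa, [], rng) for _ in range(20)]
            params = pd.DataFrame({"generation": np.arange(1, 21),
                                   "log_likelihood": 0.0, "log_prior": 0.0})
            traces.append(Trace(params, trees))
        got = asdsf(traces, min_freq=0.1)
        # brute force: tally every split by scanning trees again
        all_splits = set()
        for tr in traces:
            for tree in tr.trees:
                all_splits |= tree.splits()
        freqs = {
            s: [sum(s in t.splits() for t in tr.trees) / len(tr.trees) for tr in traces]
            for s in all_splits
        }
        keep = [s for s, f in freqs.items() if max(f) >= 0.1]
        expected = np.mean([np.std(freqs[s]) for s in keep])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_trace_rejected(self):
        t = make_topology_trace([self.quartets["ab"]])
        with pytest.raises(ValueError):
            asdsf([t])


class TestEss:
    def test_iid_near_n(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert effective_sample_size(x) > 1000

    def test_correlated_much_smaller(self):
        rng = np.random.default_rng(1)
        x = np.zeros(2000)
        for i in range(1, 2000):
            x[i] = 0.95 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 500


class TestEmpiricalBayesClockPrior:
    def test_median_is_height_over_mean_root_age(self):
        prior = empirical_bayes_clock_prior(0.685, Calibration.uniform(52, 85))
        assert prior.median == pytest.approx(0.685 / 68.5)
        assert prior.median == pytest.approx(0.01)

    def test_quantile_ratio_lognormal(self):
        prior = empirical_bayes_clock_prior(0.5, Calibration.uniform(52, 85))
        ratio = prior.quantile(0.975) / prior.quantile(0.025)
        assert ratio == pytest.approx(math.exp(2 * 1.959964), rel=1e-4)

    def test_degenerate_height_rejected(self):
        with pytest.raises(ValueError):
            empirical_bayes_clock_prior(0.0, Calibration.uniform(52, 85))


class TestSplitFrequencies:
    def test_counts(self):
        t = make_topology_trace(
            [TestAsdsf.quartets["ab"]] * 3 + [TestAsdsf.quartets["ac"]]
        )
        freqs = split_frequencies(t)
        assert freqs[frozenset(("a", "b"))] == pytest.approx(0.75)
        assert freqs[frozenset(("a", "c"))] == pytest.approx(0.25)
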