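# divtime

Bayesian relaxed-clock divergence-time estimation for partitioned
multi-gene nucleotide alignments, with fossil and vicariance calibrations
under the calibrated uniform tree prior, stepping-stone clock-model
selection, and per-gene congruence/precision evaluation.

The package targets the kind of dating study done for the major passerine
lineages: a handful of nuclear genes (coding genes split into codon
positions 1+2 vs 3, introns kept whole), a root age bracketed by a
geological vicariance window, a few fossils that provide hard minimum ages
for well-supported clades, and the question of how sensitive the inferred
time-scale is to the root calibration and to individual genes.  It is
aimed at molecular systematists who want a transparent, fully scriptable
and testable implementation of that workflow, including a synthetic-data
generator so every stage can be exercised without any sequence downloads.

## Model

Sequences evolve on a rooted binary chronogram with node ages `t` in My
(tips at 0) under per-partition GTR+Γ₄+I substitution models with
partition rate multipliers `m_i` (length-weighted mean 1).  A clock model
maps time to expected substitutions per site on each branch:

* **strict** — rate `c` on every branch (`c` in substitutions/site/My);
* **IGR** (independent gamma rates, white noise) — the effective branch
  length is gamma distributed with mean `c·Δt` and variance `ν·c·Δt`,
  i.e. the branch rate has mean `c` and variance `c·ν/Δt`;
* **TK02** — rates evolve as an autocorrelated lognormal process: a
  branch's rate is lognormal with expectation equal to its parent's rate
  and log-variance `ν·Δt`.

Node ages get the uniform tree prior extended to calibrated clock trees:
the root age has a uniform window (the vicariance calibration), each
fossil-calibrated node an offset-exponential density `λ e^{−λ(t−x₀)}`
with hard minimum `x₀` and `λ = 1/(mean − x₀)`, and the remaining ages
are uniform over the order polytope they admit — normalised *exactly* by
recursive piecewise-polynomial integration over the tree.  Priors follow
the usual choices: lognormal on `c` (median set empirically from a
strict-clock relative-height run, log-SD 1), Exponential(10) on `ν`,
Exponential(1) on each gamma shape `α`, Uniform(0,1) on each invariant
fraction, flat Dirichlets on frequencies, exchangeabilities and
multipliers.

Inference is Metropolis-coupled MCMC (heats `1/(1+(i−1)T)`), with
prior-only (data-free) runs to expose the *realized* calibration priors,
ASDSF and ESS convergence diagnostics, and stepping-stone sampling
(`β` ladder of Beta(0.4, 1) quantiles) for marginal likelihoods and
`2·ln BF` clock-model comparison.

## Worked example

Simulate a seven-gene study at one tenth of the real gene lengths
(622, 504, 419, 800, 749, 2947, 1152 bp → 719 sites total) for 14 taxa,
then date it under the three root-calibration scenarios:

```python
from divtime.simulate import make_passerine_fixture
from divtime.pipeline import ScenarioConfig, run_scenario

fx = make_passerine_fixture(scale=0.1, seed=1, n_taxa=14)
report = run_scenario(ScenarioConfig(
    alignment=fx.alignment,
    coding_genes=["MOS", "MYC", "RAG1", "RAG2"],
    calibrations=fx.calibrations,
    root_scenario="wide",          # root age ~ Uniform(52, 85) My
    clock="IGR",
    n_generations=2500, n_runs=2,
    topology=fx.tree,              # condition on the generating topology
    seed=1,
))
print(report["posterior"]["root_age_median"])
```

With seed 1 this data set has a true root age of 82.3 My, and the three
scenarios give (from `scripts/acceptance.py --seed 1`):

| root scenario            | posterior median (My) | 95% CI width (My) |
|--------------------------|----------------------:|------------------:|
| narrow, Uniform(82, 85)  | 83.50                 | 2.9               |
| wide, Uniform(52, 85)    | 70.76                 | 28.4              |
| uncalibrated, U(20, 4000)| 222.74                | 558.3             |

which is the qualitative signature the method is built to expose: the
narrow window pins the root; widening it makes the estimate younger and
less precise; removing it altogether lets the fossil minima alone carry
the analysis, and the posterior inflates dramatically.  The same run
reports per-gene Kendall's τ against the combined analysis (e.g. 0.82
for the RAG1-sized gene over 13 shared nodes), mean 95% CI widths per
gene (19.2 My for RAG1-sized vs 24.4 My for MYC-sized — longer genes
date more precisely), and a stepping-stone `2·ln BF` of ≈ 73 in favour of
the IGR clock on rate-variable data.

A thin CLI wraps the same pipeline:

```bash
divtime simulate --scale 0.1 --n-taxa 14 --seed 1 --outdir fixture/
divtime date --alignment fixture/alignment.nex \
             --calibrations fixture/calibrations.yaml \
             --coding MOS --coding MYC --coding RAG1 --coding RAG2 \
             --scenario wide --clock IGR --outdir out/ --seed 1
```

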