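# Methods

This note documents the models, priors, numerical choices and known
limitations of `divtime`, in the package's own terms.

## Data model and partitioning

A `MultiGeneAlignment` is an ordered taxon set with one character matrix
per gene over IUPAC nucleotide codes, gap `-` and missing `?`.  Gap and
missing are both treated as fully ambiguous for likelihood purposes
(partial likelihood of 1 over all four states) but preserved distinctly
when files are round-tripped.  A taxon absent from one gene's file is
filled with `?` — multi-gene concatenations routinely mix congeneric
individuals, so per-gene missingness must be tolerated rather than
rejected.

Partitioning is by gene and codon position: each protein-coding gene
contributes two partitions (positions 1+2 combined, position 3), each
intron one; the seven-gene template (4 coding + 3 intron) therefore has
11 partitions.  Reading frames default to 1 and may be declared per gene.
Substitution models are unlinked across partitions; overall rates differ
by partition multipliers `m_i > 0` constrained to length-weighted mean 1
(internally a flat-Dirichlet-distributed weight vector divided by the
partitions' length shares).

## Substitution model

GTR with six exchangeabilities and four stationary frequencies,
normalised so one unit of branch length is one expected substitution per
site.  Among-site rate variation is a discrete gamma with four
equal-probability categories using the mean-of-bin rule (the dominant
convention), plus a proportion of invariant sites.  Γ+I is kept jointly
despite the known weak identifiability of (α, p_inv); the Exponential(1)
and Uniform(0,1) priors regularise it.  Transition probabilities come
from the symmetrised eigendecomposition (exact for reversible models);
likelihoods use Felsenstein pruning with exact site-pattern compression
and per-node/pattern rescaling with accumulated log-scalers, so ~7 kb on
trees of up to a couple hundred taxa evaluates without underflow.  The
pruning kernel is JIT-compiled with numba.

## Clock models and units

Branch rates `r_b` convert durations (My) into branch lengths
(substitutions/site), `len_b = r_b Δt_b`:

* **strict**: `r_b = c` everywhere.
* **IGR** (white noise): effective branch lengths are independent gamma
  variates with mean `c Δt` and variance `ν c Δt`; equivalently `r_b` is
  gamma with mean `c` and variance `c ν / Δt`.  The `1/Δt` scaling means
  long branches average over more rate fluctuation.  The variance
  parameter `ν` carries substitution units.  This convention matters: an
  Exponential(10) prior on `ν` then spans everything from effectively
  strict clocks to branch-length coefficients of variation well above 1.
  A parametrisation of the rate variance in absolute rate-squared units
  would push the gamma shape `c²Δt/ν` to ~10⁻⁴ over most of that prior
  (draws underflow to zero in double precision and the realized prior
  becomes truncated), while a purely relative parametrisation `c²ν/Δt`
  concentrates the same prior so tightly around the strict clock that
  model comparison can never favour strict over IGR.  The
  substitution-units convention avoids both failure modes; tiny-shape
  gamma draws are additionally generated in log space (shape-boosting
  identity) with a floor at 10⁻²⁹⁰ whose prior mass is negligible.
* **TK02** (autocorrelated lognormal): each branch's rate is lognormal
  with *expectation* equal to the parent branch's rate (so
  `μ_log = log r_parent − νΔt/2`) and log-variance `νΔt`; branches at the
  root start from `c`.

## Calibrations and the tree prior

Calibrations are densities on clade ages bound to monophyly constraints:
a uniform window for the root (a vicariance event provides both a minimum
and a maximum) and offset exponentials for fossils (hard minimum `x₀` at
the youngest bound of the fossil's stratigraphic interval — the
conservative reading of "provides a minimum age" — with `λ = 1/(mean −
x₀)` so that the *mean of the full distribution* sits at the chosen
anchor age; whether the anchor should instead be the mean of the
exponential part is genuinely ambiguous, so the parametrisation is
explicit and configurable).  The default template uses minima 10.4, 16.3,
16.3, 16.3 and 18.0 My with a common mean of 58 My, a root window of
(52, 85) My, and a rooting constraint separating one taxon from all
others.

Given root and calibrated-node ages, the remaining internal ages are
uniform over their order polytope (children younger than parents, tips at
zero).  The polytope volume is computed exactly by a recursion over the
tree: tips contribute 1; a calibrated node at age `a` contributes a step
function at `a` times its children's values there; a free node
contributes the running integral of the product of its children's
functions.  All functions are piecewise polynomials in root-age-scaled
coordinates, where every coefficient is non-negative (no cancellation)
and degrees are bounded by the number of free nodes; the volume in My^n
is recovered as `V_scaled · R^{n_free}`.  Because the density is properly
normalised conditional on the root and calibrated ages, the marginal
prior of the root equals its calibration exactly when no internal
calibration truncates it — the property the prior-recovery tests pin
down.  With internal calibrations the *realized* marginals deviate from
the specified densities; prior-only (data-free) MCMC runs report exactly
that deviation.

The same recursion gives an exact sampler: root and calibrated ages are
drawn from their calibrations (with rejection for nesting order), then
free ages top-down by inverse-CDF on the piecewise polynomials (root
solved by Brent's method).  This is how the synthetic-data generator
draws time-trees; no approximate MCMC is involved in fixture generation.

## MCMC

A generic Metropolis-coupled engine targets `likelihood^β × prior` with
chain heats `1/(1+(i−1)T)` (default T = 0.1), random-pair state swaps
each generation, and `β = 0` for prior-only runs.  The dating model's
proposal mixture: uniform-window node-age slides within the
neighbour-feasible interval (exactly symmetric), multiplicative root-age
moves, a whole-tree scale move that multiplies all internal ages by `f`
and divides `c` and all branch rates by `f` (branch lengths, hence the
likelihood, are invariant — it walks along the rate–time ridge), log-scale
walks on `c`, `ν`, `α` and individual branch rates, a reflected walk on
`p_inv`, Dirichlet-centred re-draws for frequencies, exchangeabilities
and multiplier weights, an uncle-swap topology move constrained to
respect monophyly (selection over nodes-with-grandparents, a set whose
size the move preserves, so it is symmetric), and two independence
kernels that redraw branch rates from the clock prior and scalar
parameters (with rates) from their priors — their Hastings terms cancel
the corresponding prior factors exactly, making prior-only sampling mix
essentially instantly and providing long-range jumps in posterior runs.
Every kernel's correctness is checked globally: a 10⁵-generation
prior-only run must reproduce each parameter's prior marginal
(Kolmogorov–Smirnov), and a fixed-tree strict-clock posterior must match
fine-grid numerical integration.

Runs are seeded from one master seed with per-run streams
(`default_rng([seed, run])`).  Convergence reporting: ESS of the
log-likelihood (initial-positive-sequence estimator) and, with ≥ 2
independent runs and topology sampling, the average standard deviation
of split frequencies (population-`n` denominator, splits at frequency
≥ 0.1 in at least one run), warned against the 0.01 threshold.  Per-run
burn-in defaults to 25% before pooling.

## Model selection

Stepping-stone marginal likelihoods with a `β` ladder of Beta(0.4, 1)
quantiles (the conventional schedule shape), samples drawn at the lower
power of each rung, log-sum-exp stabilised contributions, and the first
(posterior) rung used only as burn-in.  With a single sampler per rung,
a within-step split-frequency SD between the two halves of the rung's
tree sample is compared against the 0.04 per-step threshold when
topology is sampled.  Bayes factors are reported as `2·ln BF` with
Kass–Raftery interpretation bands.  The estimator is validated against a
Beta-Bernoulli toy with an analytic marginal; ~32 rungs suffice for the
discretisation bias to fall below Monte-Carlo error at desk scale.

## Empirical-Bayes clock-rate prior

A strict-clock run on *relative* time (root pinned at 1, fossil
calibrations dropped but their monophyly kept) estimates the tree height
in substitutions; dividing its posterior median by the mean root age
under the root calibration gives the median of a lognormal prior on `c`
with log-SD 1 — weakly informative, but enough to stabilise the
rate–time ridge.  Tree height in substitutions is defined as the
tip-averaged root-to-tip path (equal to `c × root age` under a strict
clock; the average avoids the upward bias of a max-path definition under
relaxed clocks).

## Summaries and gene evaluation

Nodes are identified across samples by their taxon clade.  The consensus
is majority-rule (clades at frequency > 0.5; lower-frequency compatible
clades are not added, so polytomies can remain); ages are summarised per
clade over the samples containing it with central (equal-tailed) 95%
intervals, 2.5–97.5 percentiles by linear interpolation between order
statistics.  Central intervals rather than HPD match the reported
"credibility interval" convention.  Chronograms are written as NEXUS
trees with `[&pp=…,median=…,ci_lower=…,ci_upper=…]` node comments and
branch lengths in My, and round-trip through the package's reader.

Per-gene evaluation matches single-gene summaries to the combined
consensus by clade: congruence is Kendall's τ_b over shared node medians
(exact two-sided p for n ≤ 10 without ties, normal approximation
otherwise), precision is the mean 95% CI width over matched nodes only,
differences among genes are tested by tie-corrected Kruskal–Wallis,
interval agreement by pairwise Jaccard overlap and a joint-intersection
flag, and saturation by tabulating uncorrected p-distances against MRCA
ages from a chronogram (median ages when it is a consensus).  Root ages
can be back-calculated from an external gene-specific substitution rate
as `(tree height in substitutions × gene multiplier) / rate`, with the
interval propagated from the rate interval's endpoints.

## Synthetic data

The generator emulates the seven-gene study design: gene lengths
scale×(622, 504, 419, 800, 749, 2947, 1152) rounded half-up (scale 1 →
7,193 sites), codon partitioning for the four coding genes, a root
window of (52, 85) My, the five offset-exponential fossil calibrations
above placed on clades of 2–4 taxa, a rooting constraint, an IGR clock
with base rate 0.002 substitutions/site/My (a realistic average for
nuclear loci at these time depths) and `ν = 1.5×10⁻³` (branch-rate CVs of
roughly 20–40% on mid-length branches), and per-partition GTR+Γ+I
parameters chosen once to mimic coding positions 1+2 (slow,
transition-rich, high invariant fraction), position 3 (fast) and introns
(intermediate), with multipliers normalised to length-weighted mean 1.
Topologies are random resolved rooted trees honouring the constraint
clades; ages come from the exact calibrated-prior sampler; sites are
i.i.d. given partition, with invariant sites copying the root state and
root states drawn from the stationary frequencies.  Everything is
byte-reproducible given a seed.

What the generator does *not* emulate: indels and alignment error,
among-gene tree discordance (all genes evolve on one species tree, as
the concatenation analysis assumes), base-composition heterogeneity
across lineages, and sequencing missingness patterns.  Passing tests
therefore demonstrate internal correctness and calibrated behaviour of
the inference machinery under its own assumptions, not robustness to
real-data violations of them.

## Problem sizes used in the test suite and acceptance script

All checks run at desk scale, chosen as the smallest sizes at which each
property is decisive: likelihood oracles on 4–5 taxa with exhaustive
enumeration; tree-prior oracles on 4–6 taxa against rejection sampling
and exact grid integration; prior recovery from ~10⁵ prior-only
generations; parameter recovery on 20 replicates of 20-taxon,
quarter-length (≈1,800-site) fixtures with the topology conditioned on
truth and chains initialised at the generating values (coverage of a 95%
interval is a property of the posterior, not of the starting point);
clock-model recovery on 10-taxon, 1,200-site single-gene simulations
with substitution parameters held at their generating values so the
marginal-likelihood comparison isolates the clock hierarchy; and the
root-prior sensitivity contrast on 12-taxon, ≈580-site fixtures over
five seeds.  The acceptance script runs the full pipeline on a 14-taxon,
719-site bundle.  A full-scale reproduction (55 taxa, 7,193 sites,
≥3×10⁷ generations, four heated chains, four runs) is supported by the
same code paths via the CLI's `--full` profile but takes days of CPU
time.

## Known limitations

* Topology sampling uses a single constrained NNI-type move; tree-space
  mixing on large trees is far below that of specialised samplers, so
  topology is usually conditioned on a constraint-compatible estimate.
* No reversible-jump averaging over GTR submodels; GTR is fixed.
* The TK02 process is parameterised per branch against the parent
  branch's rate (the root's children start at `c`), one of several
  conventions for autocorrelated clocks.
* Stepping-stone runs within a scenario use one sampler per rung;
  independent duplicate ladders are the caller's responsibility when
  tighter error control is needed.
* The calibrated-prior volume recursion is exact but recomputed when
  root or calibrated ages move; on trees beyond a few hundred taxa this
  becomes a noticeable fraction of runtime.
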