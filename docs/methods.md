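# Methods

This note records the statistical models implemented in `msbra`, the
numerical choices behind them, and the points where the design was
genuinely open.

## Decision model

The three treatment alternatives share one sub-tree.  Serious adverse
effect–outcome combinations are modelled as mutually exclusive branches
(each is individually rare, so the joint-occurrence mass is negligible),
followed by a binary non-serious/no-adverse-event split on the
no-serious-effect branch.  Two structural conventions are worth making
explicit:

* Serious-risk values are drawn once per alternative and combination, and
  used identically on the reduced- and standard-relapse branches; nothing
  in the model makes serious toxicity depend on whether the relapse
  improved.
* The trial-estimated non-serious risk r is applied as the conditional
  probability given no serious effect, without rescaling by 1 − Σq.  The
  serious risks sum to at most ~0.14 (uniform case, high dose), so the
  discrepancy with an unconditional reading is below the Monte-Carlo noise
  of any reported quantity.

Outcome order is deterministic (effects alphabetically, outcomes in the
death > persistent > life-threatening hierarchy, reduced branch first), so
all array-indexed results are reproducible bit-for-bit given seeds.

## Hierarchical beta-binomial meta-analysis

Arm counts x_i out of n_i are modelled with study-level probabilities
p_i ~ Beta(μM, (1 − μ)M); p_i is integrated out analytically, leaving the
marginal likelihood Π_i B(μM + x_i, (1 − μ)M + n_i − x_i) / B(μM, (1 − μ)M)
(the x-only binomial coefficient is constant in the hyperparameters and
dropped).  Two printed counts are fractional (39.25/94, 9.2/13, both unit
conversions made by the source tables); evaluating the Beta functions
through log-gamma makes these exact, not special-cased.

**Prior.**  μ uniform on (0, 1); 1/(1 + M) uniform on (0, 1), i.e.
p(M) = (1 + M)^(−2).  This is a standard weakly-informative choice for
hierarchical binomial models: proper, heavy-tailed in M, and favouring
neither complete pooling nor none.  It is deliberately isolated in one
function (`effectiveness_meta._log_target`) so it can be swapped.

**Sampler.**  Random-walk Metropolis–Hastings on (logit μ, ln M) with
independent Gaussian steps, scales (0.7, 1.2), 55,000 iterations, 5,000
burn-in, no thinning.  On the packaged tables all five fits accept 24–47 %
of proposals.  The log-posterior includes the Jacobian
log(μ(1 − μ)) + log M of the transformation.  Convergence is unproblematic:
the target is two-dimensional and unimodal on these data; doubling the
chain length moves posterior medians by < 0.01.

**Estimand.**  The population mean μ is what enters the evaluation, not a
study-level predictive draw: the assessment concerns a representative
patient of the population the studies sample, and the between-study spread
is trial-context heterogeneity rather than patient-level uncertainty.  A
predictive alternative would widen all probability distributions and lower
every preference rate's distance from 1/3.

**No-treatment proxy.**  Placebo arms stand in for no treatment, for both
effectiveness and non-serious risk.  The low-dose non-serious risk is
uniformly sampled between paired placebo and high-dose posterior draws,
reflecting only the ordering assumption placebo ≤ low ≤ high.

## Serious-risk limits and interval distributions

The reporting-ratio upper limit for a combination is
(qualifying reports carrying it) / (all reports listing the drug).
Numerator qualification: role suspected or interacting, or concomitant with
no other drug implicated; onset within 180 days of drug initiation, waived
for osteonecrosis (hard to date).  A report missing its onset date is
excluded from the numerator — the conservative direction for the bound is
a large denominator and a *valid* numerator, and an undated report cannot
be shown to satisfy the onset rule.  This choice is switchable via the
onset-exemption flag.

The packaged limit table is consumed as authoritative (percent →
proportion).  Two printed high-dose cells are 0.00 and flagged as not
genuine upper bounds; the corresponding low-dose limits are substituted
when the evaluation's risk set is built.  The printed "Total" rows are
reproducible from the cells only to ≤ 0.02 percentage points (they were
computed on unrounded data) and are therefore neither shipped nor asserted.

Risk values over [0, L]: uniform, or exponential with rate λ = k/L
truncated to [0, L], drawn by inverse CDF.  The truncated mean
1/λ − L·e^(−λL)/(1 − e^(−λL)) equals 0.19 L, 0.020 L and 0.0020 L for
k = 5, 50, 500, and tends to L/2 as k → 0.  Draws are independent across
the 26 combinations and across the two active alternatives; the
no-treatment value π(q_low + q_high)/2 then induces the intended coupling
with both.  Within an iteration, effectiveness and non-serious draws are
paired across alternatives by index; all comparative quantities are formed
within an iteration before aggregating.

## Utility sampling

The 16 utility classes (2 benefit states × 8 adverse-event classes) carry
i.i.d. standard-uniform utilities conditioned on the qualitative relations,
which is exactly the uniform distribution on the resulting polytope.  The
relations are: a total vertical order of the adverse-event classes within
each benefit state; reduced preferred to standard at the same class; a
reduced relapse with a non-serious event preferred to a standard relapse
with none; a block gap of at least δ between all 12 non-lethal and all 4
lethal class utilities; and severity-specific diagonals (two at EDSS 4, one
at EDSS 5).  Diagonal relations beyond those directly narrated are not
invented; the implemented edge set is the narrated one.

Three sub-choices were open and are exposed as configuration:

* lethal outcomes of diabetes, hepatotoxicity and seizure are grouped with
  the protracted/painful deaths (their clinical course is extended, unlike
  anaphylaxis or cardiac arrest);
* the life-threatening class sits above the mild-persistent class in the
  vertical order;
* the δ gap is enforced between the full non-lethal and lethal blocks
  (12 vs 4 classes), which is what a single separating margin between the
  two groups means once both benefit states are present.

**Sampler.**  Coordinate-wise Gibbs: each class utility is resampled
uniformly on the interval allowed by its graph neighbours and the block
gap — the exact conditional of the uniform-on-polytope target, so no
accept/reject step is needed.  Defaults: start at a deterministic feasible
point (topological spacing with the lethal block compressed under the δ
gap), 1,000 burn-in sweeps, thinning 5, one fresh chain per scenario
stream.  Against plain rejection sampling on small systems the
per-coordinate Kolmogorov–Smirnov distance is < 0.02 at n = 20,000.
Feasibility is checked up front (cycle detection plus no non-lethal class
ordered below the lethal block); δ ≤ 0.99 always leaves a non-empty
polytope.

The minimum utility difference has a behavioural reading via a standard
gamble: at δ = 0.5 the sampled utilities imply indifference between the
status-quo outcome and a gamble carrying about a 5 % chance of the worst
lethal outcome (about 1 % at δ = 0.9) — a proxy for population risk
aversion.

## Evaluation and sensitivity machinery

Scenarios run 10,000 iterations by default.  Preference rates use argmax
with exact ties split equally (a measure-zero event under continuous
draws; the rule exists for determinism).  The grid driver derives each
stochastic stream's seed from the master seed plus the components the
stream actually depends on — utility draws from (δ, EDSS), serious-risk
draws from the interval family — so cells sharing those settings share
draws by construction and the cache is an optimisation, not an
approximation.  The default grid (352 cells) is evaluated at 2,000
iterations per cell in the shipped acceptance run, which keeps the whole
sweep in seconds while leaving the per-cell Monte-Carlo error on a
preference rate near one percentage point; the reference scenario itself
always uses the full 10,000.

Median fixation replaces every draw of a named variable class
(probabilities, utilities, all, or one of effectiveness / non-serious /
serious) by its per-variable median and re-evaluates.  On the packaged
inputs, fixing the probability variables sharpens preference rates far more
than fixing the utility variables — the residual uncertainty is dominated
by the probability side.

## Synthetic data: what it does and does not show

The arm simulator draws from exactly the hierarchical model the fitter
assumes; recovery tests therefore validate the fitter and sampler, not the
model's adequacy for real trial heterogeneity.  With the reference
conditions (μ = 0.6, M = 10, eight arms of 30) the sampling standard error
of the population mean is ≈ 0.06, and the recovery test requires the
posterior median to land within two such standard errors in 18 of 20
replicates.

The report simulator generates the regime in which the reporting-ratio
bound is provably conservative: every true case reported, drug suspected,
onset within the window, and padding reports that enlarge only the
denominator.  Real spontaneous-report collections violate these
assumptions in both directions (under-reporting of cases, numerator
contamination), so the bound-validity simulations demonstrate internal
correctness of the counting rules, not the real-world coverage of the
limits.  Neither generator models MedDRA coding, term-mapping noise, or
dose misclassification.

## Known limitations

* The low-dose alternative rests on three trial arms (62 patients) and an
  interpolated non-serious risk; its results are the least data-driven.
* The qualitative utility relations encode one clinical reviewer's
  population-level judgements; individual-patient use requires replacing
  them.
* Effectiveness cannot be stratified by relapse severity even though the
  utility relations are, so the EDSS-4/EDSS-5 contrast isolates preference
  structure only.
* The six-month horizon is a label on the utility scale, not a simulated
  timeline; no QALY-style time aggregation is attempted, by design.
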