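# Methods

This note documents the models, algorithms and numerical choices behind
`accumaint`, and what the synthetic-data experiments do and do not show.

## Task and design

The simulated study is a two-alternative forced-choice face/house
discrimination at four phase-coherence levels (two "easy", two "hard"),
run in two response modes: a reaction-time (RT) condition in which the
response is given during a 1 s stimulus window, and a delayed-response
(DR) condition with a 500 ms cued delay followed by a 500 ms response
window. The default design has 18 participants and three 112-trial runs
(RT, DR, RT). Trial tables carry subject, condition, coherence level,
stimulus, choice, correctness and response time, and round-trip through
CSV.

## Firing-rate forward model (`neural_bold`)

Decision neurons are modelled schematically: firing ramps linearly from a
baseline BL (default 5 Hz) to a threshold T (default 50 Hz) over a
difficulty-dependent time-to-threshold (hard slower than easy). Two
hypotheses differ in what happens at threshold. An
*accumulate-and-maintain* population holds threshold firing until the
response cue in the DR condition; an *accumulate-only* population returns
to baseline immediately. Firing deviations from baseline are convolved
with the canonical double-gamma HRF (positive lobe peaking at 6 s,
undershoot at 16 s, dispersions 1, peak:undershoot 6:1, 32 s kernel,
unit-peak normalized — the standard parameterization) to predict BOLD.

The testable signature is the integrated-amplitude interaction:
maintenance predicts hard > easy under RT but easy > hard under DR (the
easy decision reaches threshold sooner and is maintained longer), while
accumulate-only predicts hard > easy in both modes. `crossover_summary`
integrates each curve over time; the time-integral is used because a
GLM-style activation effect scales with integrated activity. A
property-based sweep verifies the flag is determined by the firing mode
for any valid parameter set (hard slower than easy, cue after both
crossings). Post-threshold decay is instantaneous by default (an
exponential tail is available); the prediction depends on time at
threshold, not decay shape.

## Drift-diffusion simulation (`synthetic_data`)

Choices and RTs are simulated from a two-boundary drift diffusion:
evidence starts at z = a/2 (no bias), accumulates with drift v and unit
diffusion (s = 1, the standard scale convention), and absorbs at 0 or a;
the upper boundary codes the correct response. Integration is
Euler-Maruyama with dt = 0.5 ms (configurable); at this step the hit
probability is indistinguishable from the closed form
(1−e^{−2vz})/(1−e^{−2va}) within Monte-Carlo error at n = 3000 (checked
over nine (v, a) pairs). RT-condition trials unresolved at the stimulus
deadline are recorded as missed with missing RT; censoring produces a
missed-trial rate of a few percent under moderate difficulty, rising for
slow-drift/wide-boundary settings.

The DR simulator continues accumulation through the stimulus window plus
delay and reads the choice out at the cue: the boundary already reached,
or else the sign of the evidence state relative to the start point (ties
broken at random). This is the simplest mechanism consistent with the
observation that delayed responses are more accurate — extra
accumulation time helps. The recorded DR response time is a motor
latency, normal (0.25 s, 0.04 s) truncated positive and censored at the
response window, drawn independently of difficulty.

The hierarchical behavioral generator draws exactly the structure the
behavior fitters assume: subject accuracy rates from a beta around the
group mean (default between-subject sd 0.05), subject mean RTs from a
normal around the group mean (default sd 0.05 s, truncated positive),
trial RTs gamma with the subject mean and trial sd (default 0.10 s), and
correctness Bernoulli. Default group accuracies per level are
0.92/0.84/0.72/0.64 and mean RTs 0.60/0.64/0.72/0.76 s, a separation
typical of phase-coherence manipulations. Accuracy and RT are generated
independently, matching the separate accuracy and RT models.

The corpus generator emulates a merged coordinate-based meta-analysis
database: articles carry Bernoulli term annotations and Poisson-many
uniform background foci inside a brain bounding box; planted
associations place a focus inside a sphere around a chosen center with
probability 0.8 given the term and 0.1 otherwise (the recovery-test
conditions).

## Hierarchical behavior models (`behavior_bayes`)

Response times: gamma likelihood per trial with subject-level mean and
variance, transformed to shape = mu²/sigma² and rate = mu/sigma². Subject
means and variances are gamma-distributed around group means/sds (same
transform), and every positive hyperparameter has a uniform(0.01, 30)
prior — applied at all hyper-levels. Accuracy: binomial counts with
subject rates beta-distributed around a group mean (flat Beta(1,1)
prior); the beta is moment-parameterized (kappa = m(1−m)/var − 1,
alpha = m·kappa, beta = (1−m)·kappa, requiring var < m(1−m)) and the
group variance carries a gamma prior whose mean/sd have the same uniform
hyperpriors. Both models factor over coherence levels and are fit
separately per response condition; missed trials are excluded.

Sampling is adaptive Metropolis-within-Gibbs: log-scale random walks for
positive parameters, a logit-scale walk for the group accuracy mean, and
conjugate beta draws for subject rates. Group-level accuracy moves use
the collapsed beta-binomial likelihood (subject rates integrated out);
without this, a collapsing group variance pins the subject rates to the
group mean and the sampler funnels. The group variance is floored at
1e-7, below which the model is numerically binomial. Proposal scales
adapt toward 44% acceptance during burn-in only, so kept samples come
from a fixed kernel. Defaults: 3 chains, 5000 kept after 2000 burn-in,
thinning 1.

Reporting follows the Bayesian-estimation conventions: grouped chains as
sample-by-sample means over the constituent level chains with equal
weight (easy = levels 1-2, hard = levels 3-4; condition = all four),
orderings as the proportion of paired posterior-difference samples above
zero, uncertainty as the 95% highest density interval (narrowest
contiguous window of ceil(0.95 n) sorted samples; ties resolve to the
first window), and convergence as the classic Gelman-Rubin factor
sqrt((((n−1)/n)W + B/n)/W), requiring at least two chains and nonzero
within-chain variance.

## Hierarchical drift-diffusion estimation (`ddm`)

The likelihood is the Wiener first-passage-time density with the
standard dual-series evaluation: the drift-free factor has small-time
and large-time expansions, and the representation needing fewer terms
for a truncation error of 1e-7 is selected per evaluation; the two agree
to 1e-6 on their overlap. The upper-boundary density follows from the
reflection (v, w) → (−v, 1−w). Between-trial drift variability (normal,
sd sv) is integrated in closed form; non-decision-time variability
(uniform of width st) by 3-point midpoint quadrature. With sv = st = 0
the likelihood reduces exactly to the plain density.

Four variants differ in which parameters track difficulty: both drift
and boundary (the full model), neither, drift only, boundary only. The
hierarchy is v_cj ~ Normal(mu_c, sd_c), log a_cj and log t_j normal
(i.e., log-normal on the natural scale), with sv and st estimated at the
group level only; the start point stays at a/2 and no contaminant
mixture is included. Hyperpriors are weakly informative: N(0, 10²) on
group means, inverse-gamma(1, 0.01) on group variances, half-normal on
sv (sd 2) and st (sd 0.25).

One chain is a numba-compiled sweep: random-walk Metropolis on subject
parameters (per-parameter scales adapted toward 44% acceptance during
burn-in, then frozen), conjugate normal/inverse-gamma Gibbs for group
means and variances, and reflective random walks on [0, ∞) for sv and
st with five sub-updates each per sweep — these global moves dominate
the chain autocorrelation because they re-weigh every trial. Chains are
initialized from per-cell EZ-diffusion moment estimates (edge-corrected
accuracies, clipped to sane ranges) with per-chain jitter, which removes
most burn-in transients. Non-decision times are constrained by the data
support: proposals implying rt ≤ t − st/2 have zero likelihood and are
rejected.

DIC uses the plug-in effective-parameter count: pD = mean deviance minus
the deviance at the posterior means of the subject-level parameters (and
sv, st, with log-normal parameters averaged on the natural scale);
DIC = mean deviance + pD. Model recovery on data generated with
difficulty-dependent drift and boundary selects the full model over the
three restricted variants in ≥ 9/10 replicates at desk scale. Posterior
predictive simulation redraws joint posterior samples and simulates
fresh trials, coding error RTs negative for the usual correct/error
overlay.

Parameter recovery is evaluated on datasets without deadline censoring
(a 3 s window): the fitted likelihood does not model censoring, and a
1 s deadline at slow-drift settings discards the slow tail, which biases
boundary and non-decision estimates and inflates st. Under the censored
design the qualitative orderings (drift easy > hard, P = 1) are
unchanged.

## Reverse-inference meta-analysis (`meta_inference`)

Articles are annotated by stemmed occurrence: title+abstract+keywords
are lower-cased, stop-word-filtered (list shipped with the package) and
Porter-stemmed (full 1980 algorithm, implemented in-package); a one- or
two-word term matches iff its stemmed form occurs, two-word terms as
consecutive tokens of the filtered stream. Terms in fewer than 15
articles are dropped, as are the excluded generic terms ("face*" as a
literal prefix pattern, "house", "picture", "actor").

Foci databases merge by article id with exact-duplicate foci stored
once. Activation masks rasterize each article's foci onto the grid: a
voxel is active iff its center lies within 10 mm of any focus (2 mm
isotropic MNI-like grids by default; tests use coarser grids). The
voxelwise posterior p(Term|Actv.) applies Bayes' rule to the activation
fractions among with-term and without-term articles with a fixed prior
p(Term) = 0.5 by default (weighting both classes equally regardless of
term frequency; an empirical-frequency prior is available). Voxels where
no article is active are undefined (NaN). Association strength is the
signed z from the Pearson chi-square (no continuity correction) of the
2×2 term-by-activation count table — |z| = sqrt(chi2) at 1 df — positive
when the with-term activation fraction is higher; degenerate margins are
NaN. The chi-square is computed on counts, not on probabilities, the
unambiguous reading of a "chi-square statistic" for a 2×2 association.

Contrast interpretation: local maxima are suprathreshold (z > 2.3)
26-connected maxima accepted greedily in descending z with a 30 mm
minimum separation (the "3 cm" convention, configurable — a 3 mm reading
is supported by passing it); clusters are 26-connected components. Around
each peak, each term's posterior z is averaged over a 5 mm sphere with
weights proportional to the contrast z clamped at zero (weights must
form a convex combination; negative-contrast voxels get zero weight, and
if no voxel has positive contrast the mean is unweighted), dropping NaN
posterior voxels with renormalization. The evidence score is peak
contrast z × ROI-averaged posterior z; per contrast each term keeps its
best peak, and the top 8 terms are reported (top 3 when the contrast has
a single cluster).

## Problem sizes and reproducibility

`scripts/acceptance.py` runs the behavioral fits at the full study size
(18 participants, 84 trials per level, 3 chains × 5000 kept after 2000
burn-in) and the drift-diffusion fit at 18 participants × 100 trials per
level at the same sampler budget, on deadline-free data (see above). The
test suite exercises
the same claims at reduced sizes (typically 6-10 subjects, shorter
chains) chosen so each property is still decided far from its threshold.
Every stochastic stage takes an explicit seed; identical seeds give
bit-identical trial tables, corpora, chains and reports.

## What the synthetic experiments do not show

The generators realize the fitted models' own assumptions (gamma RTs,
beta-binomial accuracy, pure diffusion with stationary parameters), so
green recovery tests certify the estimation machinery, not the models'
adequacy for real behavior — no fast errors from starting-point
variability, no lapses/contaminants, no learning or fatigue drift, no
correlation between accuracy and RT beyond what the DDM induces. The
synthetic corpus has independent term assignments and spatially uniform
background foci, unlike real literature databases with correlated topics
and anatomically clustered reporting. BOLD predictions are schematic
ramps through a fixed canonical HRF; no HRF variability or nonlinearity
is modelled. Printed DIC values and fMRI cluster tables from real data
are out of reach by construction; only orderings, convergence behavior
and planted-effect recovery are testable here.
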