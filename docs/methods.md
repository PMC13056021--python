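# Methods

This note documents the models implemented in `batcolony`, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would want to know about.

## Data model and conventions

Sessions live on a common clock in seconds. Positions are metres in the
room frame (origin at a room corner); the two landing nets are axis-aligned
rectangles near the ceiling (large 0.80 × 0.40 m, small 0.40 × 0.40 m) with
net-local coordinates measured from one net corner. Zone labels
(`large_net`, `small_net`, `food_bowl_region`, `room`) are a pure function
of position and configured geometry and are recomputed on load, so stored
labels can never drift from the positions. Head direction is allocentric,
degrees in [0, 360), 0 along the room +x axis, and defined only on nets.
The egocentric bearing of a conspecific is wrapped to [−180°, 180°) with 0
directly ahead and positive to the left; the front hemicircle is
|θ| < 90°. The default tracking rate is 25 Hz and is configurable; the
simulation-heavy tests and the acceptance script run generators at 5–10 Hz,
which leaves dozens of frames per analysis bin and keeps runtimes in
minutes.

## Social networks

The affiliation network takes, for every pair co-present on the same net
for at least one frame, the **median** frame-wise distance as the edge
weight (medians are robust to flight excursions). Interaction networks are
stars around the focal bat — only interactions involving the recorded bat
are annotated — with weight = events/hour of the selected types. Closeness
uses these weights as lengths directly (affiliation) or 1/rate
(interaction; zero-rate edges absent): c(v) = (n_reachable − 1)/Σ d. On a
disconnected graph values are computed and normalized per component, with
a warning. Stability compares each day's centrality vector with the
element-wise median across days, restricted to bats common to all days of
a group; days with fewer than 3 common bats are dropped because a
correlation over fewer points is meaningless. Annotator matching is greedy
nearest-onset within a 1.0-s tolerance (configurable) requiring equal
types, with the symmetric Dice denominator 2m/(|a|+|b|); both the window
and the denominator are explicit parameters since annotation protocols
vary.

## Dominance

Elo uses the logistic expected score with base 10 and scale 400, K = 32,
initial rating 1000, and no draws — the conventional defaults, exposed in
the API. Within a week, races are processed in (week, bat_a, bat_b) order;
sequential Elo is order-sensitive, so this deterministic order is part of
the definition of the output (exact label-permutation equivariance holds
when races occupy distinct weeks). Triad transitivity recomputes Elo from
each triad's own contests; a triad is transitive when that local Elo order
agrees with the majority-win relation on all three pairs. Pairs with equal
head-to-head wins defer to the local Elo order; if that order is itself a
near-tie (|Δ| < 1e-9) the triad counts as nontransitive — nontransitivity
between closely matched individuals is the expected failure mode.

## Food and sleep

A food-bowl visit is a maximal run of frames inside the bowl region; runs
separated by less than 5 s merge into one visit (bats shuffle at the
bowl). Bowl radius defaults to 0.20 m. Normalized time/visits are each
bat's share of the session total, summing to 1. Sleep clustering is
frame-wise single linkage with a 0.15-m threshold (about one bat body
length): touching chains of bats form one huddle. The largest cluster's
convex hull defines periphery (hull vertices) versus middle (strictly
interior; a cluster of ≤ 3 or a collinear cluster has no interior). The
per-bat middle fraction averages over the frames in which the bat belonged
to the largest cluster. A `median_positions=True` mode instead classifies
once per night on per-bat median positions, since per-frame and
median-position readings of "the" sleeping arrangement are both
defensible; the frame-wise mode is the default and the two agree on tight,
stable huddles. Class comparisons (top/intermediate/bottom by Elo) use
Wilcoxon rank-sum tests with a Bonferroni factor of 2 applied to each
comparison, capped at 1.

## Statistical tests

Kuiper's V = D⁺ + D⁻ against the uniform circular CDF is rotation
invariant; p-values use the asymptotic series
Q(λ) = 2Σⱼ(4j²λ²−1)e^(−2j²λ²) at λ = V(√n + 0.155 + 0.24/√n), truncated
when terms fall below 1e-12. Below n = 8 the asymptotic approximation is
poor and a seeded 10,000-resample Monte-Carlo null is used instead. The
two-sample variant uses the effective size n₁n₂/(n₁+n₂). The Wilcoxon
rank-sum statistic is reported as the **smaller rank sum** (other
conventions rescale W; printed W values are therefore convention-dependent
and not comparable across software). Exact p-values are used up to n = 25
per group when there are no ties, the tie-corrected normal approximation
otherwise. Type-I error of Kuiper, χ²-uniformity (12 bins), KS and the
rank-sum test is verified by simulation at n = 73 in the test suite
(rejection rate in [0.03, 0.07] at α = 0.05).

## Encoding models

Analysis bins are 0.5 s; a bin qualifies when the host is on the large net
with a defined head direction throughout and at least 3 conspecifics share
the net. Inclusion requires ≥ 600 s of qualifying time and ≥ 100
qualifying spikes (closed thresholds). Within a bin, angles are circular
means and distances/positions plain means; a conspecific absent during a
bin is masked and its basis columns are zero there, so absence maps onto
the baseline rate.

The encoding model is an additive Poisson regression with log link and
the bin width as exposure: baseline = intercept + a 3 × 3 Gaussian grid
over the host's own net position; per conspecific, either circular
harmonics (sin/cos up to order 3, 6 columns) on the bearing plus 5 cubic
B-splines on the distance (egocentric variables), or a 3 × 3 Gaussian
grid on the conspecific's net position (allocentric variable). B-spline
knots sit on quantiles of the pooled observed distances, so every basis
function carries data even when bats huddle at short range. All
non-intercept columns are standardized and carry a ridge penalty; the
penalty is parameterized per observation (total penalty λ·n·‖β‖²,
glmnet-style) with λ = 1.0, so its strength is independent of session
length. This choice matters: it shrinks the effective degrees of freedom
of uninformative variables enough that the egocentric and allocentric
candidates — which have different raw dimensions — are compared fairly,
and an untuned neuron lands inside the ±10 DIC band instead of drifting
toward the smaller model. Fitting is Newton/IRLS with backtracking line
search on the penalized log-likelihood (tolerance 1e-8, max 50
iterations; non-convergence raises). EDF is the trace of the ridge
influence matrix tr[(XᵀWX + 2λP)⁻¹XᵀWX] at the optimum, and
DIC = deviance + 2·EDF — a plug-in approximation to the Bayesian quantity
that is standard for penalized likelihood fits. Classification requires
DIC_ego < DIC_allo − 10 (egocentric) or the reverse (allocentric),
strictly; ties and small margins stay unclassified.

Shapley attribution uses the explained-deviance fraction
v(S) = max(0, 1 − dev(S)/dev(baseline)) as the characteristic function,
with the baseline always containing the intercept and own position so the
attribution isolates social variables. All 2ⁿ subsets (n = 2 × number of
conspecifics, refused above n = 14) are fitted and the exact
subset-weight Shapley formula applied; efficiency (Σφ = v(full)) is
asserted at 1e-9 on every run. Tuning curves are empirical binned rates —
12 circular 30° bins, 12 equal distance bins up to the net diagonal
(0.894 m, matching 11 degrees of freedom for the distance χ²) — and the
preferred value is the peak bin centre. The front/back population test
feeds (90° − |preferred angle|) to a signed-rank test against zero; the
exact construction of such a test is not canonical, so this definition is
declared rather than inferred.

## Synthetic colony

The generator is the package's ground-truth instrument, not a behavioral
model of record. Movement is a two-state semi-Markov schedule (exponential
dwell epochs on a net, mean 600 s; short flights, mean 4 s; 85% of dwells
on the large net) with an Ornstein–Uhlenbeck walk on the net plane
(reversion 0.8 s⁻¹ to the net centre, noise 0.15 m/√s) plus pairwise
attraction k·Σⱼ aᵢⱼ(xⱼ−xᵢ) with k = 2 s⁻¹, which makes expected pairwise
distance decrease monotonically in affinity. Group formation is emulated
by mixing a fresh random affinity matrix into the final one over the
first k sessions. Interaction events are frame-wise Bernoulli
approximations of inhomogeneous Poisson processes, active only during
same-net co-presence: affiliative rate 6/h per unit affinity, aggressive
4/h per unit |rank gap| (the higher-ranked bat is the aggressor), joining
and leaving 1.5/h — order-of-magnitude defaults for a small colony,
exposed in `InteractionRates`. Races are weekly round robins with
P(A beats B) = logistic(slope·(rank_A − rank_B)). Sleep sessions place
peripheral bats on an ellipse (ring radius 0.10 m) and designated middle
bats near the centre with 5-mm frame jitter. Spike trains follow
λ(t) = baseline·exp(gain·(f_angle + f_dist)) with a von Mises bump
(peak-normalized) on the egocentric bearing and a Gaussian bump on the
distance, realized by exact thinning against the per-frame rate; the peak
rate baseline·e^(2·gain) is checked against a 200-Hz cap up front. The
default tuning (preferred angle +45°, κ = 4, preferred distance 0.30 m,
SD 0.12 m, baseline 2 Hz, gain 1) places the preferred angle at a tuning-
curve bin centre and the preferred distance mid-range of the observed
distances.

What the generator does **not** emulate: realistic flight kinematics,
tracking dropouts and identity swaps, vocal communication, circadian
structure beyond the dark/light flag, non-stationary tuning, bursting or
refractory spike statistics, and theta-scale temporal structure. Passing
recovery tests therefore shows the estimators invert the stated generative
models at realistic sizes and noise levels — not that real colony data
meet those assumptions.

## Problem sizes and determinism

Recovery protocols use 5-bat colonies: 30-minute sessions at 10 Hz for
encoding (20 seeded runs per mode), 10-minute sessions at 5 Hz across 13
days for stability (10 seeds), 50-week race logs for Elo (50 seeds), and
5 sleep nights. Every generator is a pure function of (config, seed), and
all randomness flows through `numpy.random.default_rng`; identical seeds
give byte-identical sessions, spike trains and downstream reports.

## Known limitations

Closeness on interaction stars depends on the 1/rate length convention;
alternative normalizations would rescale centralities (correlation-based
stability is unaffected). The DIC plug-in penalty approximates the
Bayesian DIC; only DIC *differences* between the two candidates are used.
Shapley fitting cost grows as 2ⁿ — five conspecifics (10 variables, 1024
fits) is comfortable, the hard cap is 14 variables. The annotator
agreement rate depends on both the matching window and the denominator
convention; both are parameters, not facts about the data.
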