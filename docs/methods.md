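# Methods

This note documents the models, estimators and design choices behind
`famdrift`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

The corpus is a flat table of **subsystem records**: one row per
grammatical subsystem of one language, with a binary trait value (ergative
marker present/absent), the language's family under two genealogical
taxonomies (autotyp, glottolog), and one of five geo-linguistic areas
(Africa, Eurasia, Pacific, South America, Rest of the Americas). Each
subsystem is treated as an independent evolutionary trial in its family's
history; a language without attested subsystem splits carries exactly one
"whole-language" trial. Families whose members span two areas are split
into per-area sub-families before any testing, so that every family-level
quantity is computed within one contact area.

Family trees are built from the taxonomy's nested subgroup classification
when one is supplied and are star trees otherwise — both taxonomies are
rank-based classifications, not resolved phylogenies, so polytomies are the
honest default. Every edge gets length 1: under a punctuated view of
structural change, each node (language birth) is one opportunity for a type
change, and within-branch lexical change does not add opportunities.
Externally supplied Newick trees (with real branch lengths) are accepted
and pruned to the family's languages; pruning suppresses unifurcations so
path lengths stay additive, and an external tree covering less than half
the family is rejected.

## Set-based detector

For a family with `k` trait-positive trials out of `n`, an exact two-sided
binomial test against p₀ = 0.5 at α = .05. Significance assigns the
direction of the majority value; the bias **strength** is `max(k, n−k)/n`.
An exactly balanced family has p = 1, so a significant tie is impossible
and no tie rule is needed. Because the binomial is discrete, the attained
size is at or below the nominal level — the test is conservative, never
anticonservative; the suite checks exactly that rather than equality
with .05. No multiple-testing correction is applied across families: each
family is its own hypothesis and downstream aggregation uses the full set
of decisions, not a selected subset.

## Tree-based detector

The trait follows a two-state CTMC with gain rate `q01` and loss rate `q10`
per unit branch length. Transition probabilities use the closed form
(with `q = q01 + q10`, stationary masses `π1 = q01/q`, `π0 = q10/q`):
`P00(t) = π0 + π1·e^(−qt)`, `P01(t) = π1·(1 − e^(−qt))`, etc. — cheaper and
more stable than a generic matrix exponential. Likelihoods come from
postorder pruning with per-node rescaling; polytomies are products over all
children; a polymorphic tip (language whose subsystems disagree) carries
partial likelihood 1 for both states — an uncertainty, not an extra trial.
The root is closed with the stationary distribution by default (the common
default of rate-estimation tools; a uniform prior is a config switch).
The pruning kernel and the Metropolis chain are numba-compiled: the
calibration and recovery batteries need ~10⁶ likelihood evaluations at up
to 200 tips.

*ML engine.* L-BFGS-B on log-rates, bounds [1e−6, 100] per unit branch,
five seeded multi-starts (the scalar equal-rates problem uses a bounded
scalar search). The LRT statistic `2·(llₐ − ll₀)` is referred to χ²(1)
without boundary correction — both rates are interior under the null; the
suite verifies the resulting size empirically (≈ .05 at 50 tips, 500
replicates). A negative statistic beyond tolerance triggers a 20-start
refit before erroring.

*MCMC engine.* Metropolis random walk on log-rates with independent
Exponential(mean 1) priors (log-scale density `log q − q` per rate). Step
size adapts toward ~30% acceptance during burn-in only, so the kept sample
is a valid fixed-kernel chain; proposal noise is pre-drawn from a seeded
generator, making chains bit-reproducible. Marginal likelihoods use
stepping-stone sampling with 32 power posteriors at
`β_k = (k/K)^(1/0.3)` (prior-heavy spacing), warm-started rung to rung.
The model comparison reports `logBF = ln ML(unequal) − ln ML(equal)` with a
positive-evidence threshold of 2. Note the original estimation tools'
convention is `2·Δln`; the plain difference adopted here is the more
conservative detector, and the suite's calibration (equal-rates data stay
below threshold ≥ 90% of the time) and power checks pass under it.

A family whose trials are all one value is uninformative about rates; the
tree classifier falls back to the set-based test there and records the path
in the estimate's `method` field. Two-tip variable families are accepted
but flagged low-information. For all engines the strength fed to Step 2 is
the empirical majority proportion of trials, keeping deviation
probabilities commensurable across engines (deriving a "strength" from
fitted rates would make the extrapolation engine-dependent in an
uncontrolled way).

On *star* trees the two detectors legitimately diverge in sensitivity: a
tip majority on a star tree is equally explicable by the root state as by
rate asymmetry, so the CTMC engine calls fewer biases than the binomial
test. They never contradict each other's direction (a suite property);
with resolved internal structure, repeated independent losses become
visible and the engines converge.

## Extrapolation to small families

Per area: `Pr(bias) = (k+1)/(n+2)` by Laplace's rule over the `n` large
families of which `k` were called biased (½ on an empty area);
`Pr(deviation) = 1 − mean strength`, the mean taken over *biased* large
families only (strength is not a bias property of unbiased families); if
none are biased the deviation probability defaults to 0 with a warning.
Each replicate draws per small family: biased ~ Bernoulli(Pr(bias));
if unbiased → `none`; otherwise the direction is the survivors' majority
trial value (majorities over trials, not languages; a fair coin on exact
ties, redrawn each replicate), flipped when deviate ~ Bernoulli(Pr(deviation))
fires. Deviation flips the family's inferred *direction* rather than
individual member values — equivalent for isolates and the simplest
consistent reading for multi-member small families. Every replicate's
`none + A + E` equals the area's family count exactly (a suite invariant),
and an area with no trait occurrences and zero deviation probability
yields E counts of exactly 0.

Replicates use independent RNG streams spawned from the master seed
(`numpy` `SeedSequence`), so results are bit-reproducible and independent
of iteration order. Defaults: 10,000 replicates (standard errors
`sd/√reps` land below .03 at corpus scale), large-family cutoff 5; both
are config values and the CLI exposes them for sensitivity sweeps. Fewer
than 100 replicates is refused unless forced.

## Area analysis

Large families enter the count table deterministically by their estimated
direction; small-family counts enter as extrapolation means, with the SEs
carried from the Monte-Carlo component. Families with direction `none` are
excluded from the directional tests. The mean counts are rounded half-up
to integers before testing (this is the convention under which the
published statistics for this analysis reproduce exactly; a flag lets the
non-integer means enter the Poisson deviance directly). Poisson log-linear
fits via statsmodels GLM give the deviances of `{area}`,
`{area + direction}` and the saturated `{area × direction}` model (deviance
0 by construction); the interaction test is the additive model's deviance
(4 df), the direction test the area-only model's deviance (5 df). Zero
cells are permitted — `O·log(O/E)` terms vanish at `O = 0`. The per-area
binomial tests are one-sided on the minority direction's tail (the
probability of a split at least as lopsided toward the observed majority);
a two-sided option exists and the choice is recorded in the run manifest.

## Synthetic worlds

The generator emulates exactly the statistical structure the estimators
assume: per-family Bernoulli trials at a stated strength (0.5 when
unbiased), family inventories per area with sizes, bias directions and
glottolog merges fixed deterministically by the config (only trial values
are random), plus random rooted trees by sequential uniform joins — the
coalescent process, under which balanced labeled shapes are twice as
probable as each caterpillar — and Gillespie forward simulation of the
CTMC. Ground truth ships in a sidecar table, never in the database, so the
pipeline cannot see labels. The benchmark config mirrors the case-marking
corpus's marginal shape — 705 records, 617 languages, 156/144 families,
80 isolates, five areas, trait absent in Africa and concentrated in
Pacific/South America small families, biased large families at strength
0.9 (1.0 in Africa) — which makes bookkeeping and conservation properties
checkable at corpus scale.

What the generator deliberately does **not** emulate: language contact and
areal diffusion (the area stratification is the only contact control, as
in the analysis itself), realistic non-uniform branch lengths, correlated
evolution across subsystems of one language beyond the shared generating
direction, and resolved taxonomy substructure (benchmark families are star
trees). Passing tests therefore certify the estimators and their
calibration under the stated model, not the fidelity of that model to any
real corpus.

## Problem sizes and numerics

The suite's simulation batteries use 500 replicates at 50 tips (LRT size),
100 at 200 tips (rate-ordering recovery, gain/loss 0.05/0.30), 40
stepping-stone comparisons at 40 tips (logBF calibration) and 10,000
extrapolation replicates — sizes chosen so the full suite completes in well
under a minute on one core while keeping Monte-Carlo error far below the
tested margins. Likelihood tolerances: optimizer `ftol` 1e−12, LRT
negative-statistic tolerance 1e−6; pruning is validated against exhaustive
enumeration over internal states at ≤ 5 tips to 1e−10.

## Known limitations

* No hidden-rate/covarion models, no >2 states, no ancestral-state
  reconstruction.
* The LRT's χ²(1) reference is asymptotic; at very small families it is
  only approximate (empirically near-nominal at 50 tips).
* Stepping-stone logBF magnitudes depend on the rate prior; conclusions
  (threshold crossings) are what the calibration tests pin down.
* Strength-based deviation probabilities ignore the uncertainty of the
  strength estimates themselves.
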