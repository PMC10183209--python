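# Methods

This note records the models implemented in camokit, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that matter when reading results.

## Stimulus blending

Two equally sized sRGB images are blended per channel in the Fourier
domain. Writing `F_A = |F_A| e^{iφ_A}` for the 2-D DFT of a channel, the
blend at weight `w` (proportion of background A) is

    amplitude:  w·|F_A| + (1−w)·|F_B|
    phase:      arg( w·e^{iφ_A} + (1−w)·e^{iφ_B} )

followed by the inverse transform, discarding the imaginary residue and
clipping to [0, 1] (the clipped fraction is recorded per blend; it is
typically well below 0.1% for the synthetic banks). The amplitude/phase
split, rather than a complex-linear mixture, is deliberate: a linear
mixture of complex coefficients is identical to pixel-domain averaging,
which washes out contrast wherever the parents are out of phase. The
circular phase blend keeps each coefficient at full blended amplitude and
steers its phase toward the dominant parent, so spatial structure from
both parents survives. When the two phase vectors cancel exactly
(resultant magnitude < 1e−12) the phase of A is used for w ≥ 0.5, else B —
a measure-zero tie-break that makes the operation deterministic. The DC
coefficient is blended like any other.

Consequences used as test oracles: `w = 1` returns image A exactly;
blending an image with itself is the identity; `blend(A, B, w)` equals
`blend(B, A, 1−w)`; the blended amplitude spectrum is coefficient-wise the
stated convex combination; and for a single shared frequency the blend
reduces to ordinary amplitude interpolation.

Four-way (G4) blends apply the same operation to two disjoint 50%
pair-blends, giving effective weights (¼, ¼, ¼, ¼).

## Targets and experiment designs

Targets are 150 × 75 px isosceles triangles: base along the top edge of
the bounding box, apex at bottom-center, rasterized by pixel-center
inclusion. Anchors are uniform over all positions that keep the box inside
the source image; pixels outside the mask carry a sentinel 0 and export as
transparent alpha.

*Two-background design*: each of `n_pairs` image pairs (distinct
categories, no pair repeated) yields blends at 25/50/75% of background A
and one target per blend; a play shows 6 targets (2 per condition), each
on both parent backgrounds, at a shared center distance per target —
12 slides. *Four-background design*: a 4 × 30 bank yields 360 specialist
targets (3 per raw image), 360 G2 targets (60 per category pair, every
image used twice per pairing) and 360 G4 targets (every image in exactly
12 four-way blends); a play shows 9 targets (3 per type), each once per
category — 36 slides.

Target center distances are drawn with density ∝ r up to the largest
radius that keeps the target on-screen at some angle (the diagonal of the
valid-placement rectangle; screen default 1280 × 800). This up-weights
peripheral placements — equivalently, placements are area-uniform in
radius — and the angle is then drawn uniformly over the exactly computed
admissible arcs, so no rejection sampling is needed. The linear density is
one concrete choice of "more likely further away" and is isolated in
`sample_radius` for easy substitution.

## Background-difference metrics

All three metrics operate on CIELAB under D65/2° (scikit-image's sRGB
conversion). Pattern and luminance use the L\* channel; the channel choice
is a configurable convention, since grayscale-plugin behavior could also
be approximated by mean RGB.

* **Color**: Euclidean distance between the two image-mean (L\*, a\*, b\*)
  vectors.
* **Pattern**: granularity curves at 21 scales `2·√2^k`, k = 0…20
  (2 → 2048 px). Band k is an isotropic ideal bandpass over wavelengths
  `[s_k/2^{1/4}, s_k·2^{1/4})` — geometric half-steps to the neighboring
  scales, half-open so the bands tile the spectrum without overlap. The
  energy is the population SD of the band-filtered image; because every
  band excludes DC this equals the Parseval band amplitude, which is how
  it is computed (tests verify agreement with an explicit DFT-matrix
  oracle to 1%). Bands whose wavelengths exceed the image keep their ~0
  energy rather than being dropped, so curves always have 21 entries.
  The difference is the L1 distance between curves.
* **Luminance**: L1 distance between 32-bin histograms of L\*/100 over
  [0, 1] (last bin right-closed); proportions rather than counts so
  unequal image sizes compare fairly. Bounded by 2.
* **MDPS**: each metric standardized as a proportion of its maximum over
  the analysis collection (the standardization scope is an explicit
  pipeline parameter; an all-zero axis stays 0), then
  `√(s_color² + s_pattern² + s_luminance²)` ∈ [0, √3]. The underlying
  phrase "distance between two points" is geometrically ambiguous for a
  single pair; the distance-from-zero-difference reading is adopted.

## Synthetic backgrounds

A category is (mean Lab, per-image Lab jitter, spectral slope β, L\*
contrast, luminance skew). An image is phase-random 1/f^β noise on L\*,
standardized to the target contrast, optionally passed through the
monotone transform `(e^{s·z}−1)/s` (restandardized) to skew the luminance
histogram, with constant a\*, b\* at the jittered category mean, converted
to sRGB and clipped. The eight default categories span the realistic
ranges of the emulated substrates: mean L\* 35–75, chroma from strongly
green (grass) to red-brown (brick), β 1.2–1.9, contrast 6–14.

What this emulates: the axes the metrics and the detection model respond
to — mean color, luminance distribution, spatial-frequency content. What
it does not: oriented structure, edges, occlusion, depth, photometric
noise, or any object semantics. Passing tests therefore demonstrate that
the *pipeline machinery* behaves correctly on textures with controlled
statistics, not that any conclusion transfers to photographs.

Seeding is counter-based: every per-image seed derives from
(master seed, category index, replicate) via `SeedSequence` spawn keys, so
a single image can be regenerated without rebuilding the bank, and every
generator is a pure function of (spec, seed).

## Virtual observer

Detection is a piecewise-constant-hazard process. With phases delimited by
cuts (right-continuous: a time equal to a cut belongs to the later phase),
the hazard of a trial is

    h(t) = Z · exp( b_{p(t)} + c_{p(t)}[cond] + m_{p(t)}[cond]·bg_diff
                    + β_trial·trial + β_dist·dist_norm )

where Z is a play-level log-normal frailty (SD default 0.5), standing in
for participant and device heterogeneity that the analysis absorbs with
cluster-robust errors rather than a generative model. `m_p` maps each
condition to its background-difference slope, encoding the
condition × MDPS interaction with per-condition sign. Times are drawn by
exact inversion of the piecewise-exponential CDF and censored at 15 s.

Two calibrations are shipped for the two-background design and one for the
four-background design. `default_observer_exp1` encodes the *marginal*
pattern — specialists ~7% higher detection hazard before 1.5 s, ~20% lower
after 2.5 s, trial-number HR 1.015 — with no background-difference term;
`metric_effect_observer_exp1` drives the same crossover purely through the
background-difference covariate (±0.9 per unit standardized difference).
They are intentionally not combined: the two effect sets come from
different fitted models of the same data, and adding both would
double-count the condition contrast. `default_observer_exp2` makes
specialists easier to find through the first five phases and harder in the
final 10.5–15 s phase, trial HR 1.006.

## Survival analysis

Outcomes (final response per slide: detection time or 15-s timeout) are
split into counting-process episodes `(tstart, tstop]` at the cutpoints;
exposure and events are conserved exactly. The default cutpoints are
1.5/2.5 s (two-background) and 0.6/1.2/1.4/2/10.5 s (four-background);
they are run parameters, not estimated — the originals were chosen by
visual inspection of survival-curve crossings, so no automatic selection
is implemented.

`fit_cox` maximizes the Breslow partial likelihood over episodes (summed
across strata when stratifying by distance quartile) by Newton iteration.
Risk-set sums are computed with sorted suffix cumulative sums (a row is at
risk at t iff tstart < t ≤ tstop), giving O(n log n) per iteration.
Convergence is declared at gradient sup-norm < 1e−8 or when the partial
likelihood is stationary to 1e−10 relative — on ~40k-episode data float64
cancellation limits gradient resolution to ~1e−7, so the literal gradient
criterion alone is unattainable. Newton steps are capped at sup-norm 5
with step-halving to guarantee finite ascent; under complete separation
(possible in sparse phase × condition × metric cells of tiny runs) the fit
stops at a large finite coefficient, as standard implementations do.
Covariate columns with no variation are pinned at coefficient 0 with
infinite SE and excluded from the AIC parameter count. Ties are handled by
Breslow's approximation; simulated times are continuous, so ties are
measure-zero.

Variance is the clustered score-residual sandwich `A⁻¹ (Σ_g U_g U_gᵀ) A⁻¹`
with clusters at the play level — the cluster can sit *above* the episode
grouping, which is why the fitter is implemented here rather than
delegated (lifelines' time-varying fitter clusters only at its row-id
level; it serves as an independent cross-check in the tests, agreeing to
1e−6 on tie-free data). Confidence intervals are Wald at 95% (z = 1.96).
AIC = −2·logPL + 2·(estimated coefficients); strata add no parameters.
Concordance is Harrell's C over the counting-process risk sets (tied event
times incomparable), computed with a Fenwick tree and optional because it
is the only O(n log n)-with-large-constant descriptive in the fit.

Odds ratios summarize whole-trial survival: for hits/timeouts `(h_c, t_c)`
versus reference `(h_r, t_r)`, OR = `(t_c·h_r)/(h_c·t_r)`, Wald CI on the
log scale, Pearson chi-square without continuity correction; zero cells
get the Haldane +0.5 correction (flagged on the result). Distance strata
are sample quartiles (linear/type-7 interpolation) with boundary ties
assigned to the lower stratum.

## Simulation studies

*Parameter recovery*: plays are simulated under known phase-wise condition
log-HRs (`recovery_observer_exp1`: +log 1.07 early, 0 mid, log 0.80 late,
trial log 1.015) and refitted with the matching model family
(phase × condition + trial number, clustered by play). The generating
conditions for this study set frailty, distance and background-difference
effects to zero so the marginal model's estimand coincides with the
generative coefficients — under frailty, risk-set selection makes the
population-marginal HR drift from the conditional one, and "coverage of
the truth" stops being well-defined. The cluster-robust machinery is
exercised separately by a test that checks robust SE exceeds naive SE for
cluster-constant covariates under frailty. At the working size — 100
replicates × 1000 plays — every term's 95% CI covers its truth in ≥ 90% of
replicates and the early-positive/late-negative crossover sign pattern
appears in ≥ 90%.

*Metric identification*: with detection driven purely by the luminance
difference (via `metric_effect_observer_exp1`), the AIC suite — condition
only, condition × pattern, × color, × luminance, × MDPS — is refitted on
100 replicates of 250 plays; the luminance model ranks best in ≥ 90%.
Replicate sizes (1000 and 250 plays; 40- and 60-pair stimulus sets at
192 px) were fixed as the smallest designs at which the effects of
interest are comfortably identified.

## Known limitations

* The texture model is not photorealistic; see above for what it omits.
* Only the final response per slide is generated — intermediate wrong
  clicks ("shotgun" strategies) are out of scope, as are eye movements and
  per-device display variation beyond the play frailty.
* Efron/exact tie corrections, frailty (random-effect) Cox models,
  proportionality tests and automatic cutpoint discovery are not
  implemented; diagnostics are limited to what the fit object reports.
* Bank images default to 192 × 192 px — the smallest convenient size that
  can contain a 150 × 75 px target; real substrate photographs are much
  larger, so absolute pattern-energy magnitudes are not comparable to
  full-resolution analyses.
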