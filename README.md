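# camokit

Simulation and analysis toolkit for background-matching camouflage search
experiments, built for researchers studying how **specialist** (closely
matched to one background) versus **generalist** (compromise) camouflage
performs when prey can appear on two or more background types.

The toolkit reproduces, end to end and on purely synthetic data, the
computational chain of a screen-based "find the moth" study:

1. **Synthetic substrate banks** — categorized 1/f^β noise textures with
   category-mean CIELAB color, luminance contrast and histogram skew,
   standing in for photographs of leaves, bark, grass, sand, shrubs,
   pebbles, stone and brick.
2. **Stimulus blending** — pairs of backgrounds are combined per RGB
   channel in the Fourier domain: amplitudes mix linearly,
   `|F| = w·|F_A| + (1−w)·|F_B|`, and phases circularly,
   `φ = arg(w·e^{iφ_A} + (1−w)·e^{iφ_B})`, so a 25/50/75% blend inherits
   the spatial structure of both parents even when they are out of phase.
   Triangular 150 × 75 px "moth" targets are cut from the blends.  Both
   the two-background design (25/50/75% blends, 766 pairs → 2298 blends at
   full scale) and the four-background design (360 specialist, 360 G2, 360
   G4 targets from a 4 × 30 bank) are implemented.
3. **Background-difference metrics** — per pair: color (ΔE between mean
   L\*a\*b\* vectors), pattern (Σ|ΔE_k| over a 21-band granularity curve,
   wavelengths 2…2048 px in √2 steps, pattern energy = SD of the
   band-filtered L\* image), luminance (Σ|Δp| over 32 luminance bins), and
   their combination **MDPS** = ‖(s_color, s_pattern, s_luminance)‖₂ after
   each metric is standardized by its maximum.
4. **Virtual observer** — detection times are drawn from a piecewise
   exponential whose log hazard is phase-specific and log-linear in target
   condition, background difference, trial number and screen distance,
   with a play-level log-normal frailty; trials censor at the 15-s timeout.
5. **Survival analysis** — trials are expanded into counting-process
   episodes at chosen cutpoints (defaults 1.5/2.5 s and
   0.6/1.2/1.4/2/10.5 s) so condition effects can vary by time phase; a
   Cox model is fitted by Newton iteration on the Breslow partial
   likelihood with a **cluster-robust** (score-residual sandwich) variance
   at the play level, optional distance-quartile stratification, AIC model
   comparison, Kaplan–Meier curves and hits/timeouts odds ratios.

## Worked example

`examples/04_simulate_and_fit.py` simulates 600 plays (7200 trials) on the
calibrated two-background observer and fits the phase-wise condition model:

```
simulated 7200 trials in 600 plays; 5139 detections, rest timed out at 15 s

phase-wise hazard ratios vs the generalist (50%) reference:
  cond[25]:0-1.5     HR=1.138  95% CI [1.045, 1.239]
  cond[25]:1.5-2.5   HR=0.892  95% CI [0.748, 1.063]
  cond[25]:2.5+      HR=0.751  95% CI [0.662, 0.853]
  cond[75]:0-1.5     HR=1.084  95% CI [0.994, 1.184]
  cond[75]:1.5-2.5   HR=0.985  95% CI [0.833, 1.164]
  cond[75]:2.5+      HR=0.776  95% CI [0.677, 0.890]
  trial number       HR=1.0095

delta AIC (condition model vs trial-only): -20.5
overall survival OR, 50 vs 25: 0.886 (p=0.0587)
```

Reading the numbers: hazard ratios above 1 in the first 1.5 s mean the
specialist populations (25% and 75% blends) are detected *faster* than
generalists early — the poorly matched half of the specialists gives
themselves away — while HRs below 1 after 2.5 s mean the surviving,
well-matched specialists are *harder* to find late in the search.  The
negative ΔAIC says the time-varying condition model beats the trial-only
model; the survival odds ratio below 1 says generalists time out less
often than 25% specialists overall at this effect size.

The other scripts in `examples/` each demonstrate one capability
(bank generation, blending and target extraction, difference metrics, the
full pipeline, and the simulate-and-refit recovery study).

## Layout

```
src/camokit/
  images.py     RasterImage container
  synthetic.py  category specs, background generator, virtual observer
  stimuli.py    Fourier blending, triangle targets, play assembly
  metrics.py    color / pattern / luminance differences, MDPS
  survival.py   episode splitting, Cox fitting, KM, odds ratios
  pipeline.py   config-driven orchestration and simulation studies
  io.py         CSV/PNG/JSON artifact formats
docs/methods.md   model and design notes
examples/         one narrative script per capability
```
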