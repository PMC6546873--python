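# Methods

This note documents the generative model behind the synthetic recordings,
the measurement conventions of the analysis chain, the numerical choices
that were genuinely open, and what the simulations do and do not establish
about real recordings.

## Generative model

Each simulated epoch is `CM(t) + SP(t) + CAP(t) + noise`, sampled at 25 µs
on a −5 … +12 ms window around the click, with 500 trials per polarity by
default and white Gaussian noise of 10 µV SD per trial (so the 500-trial
average carries ≈ 0.45 µV of noise, ≈ 0.32 µV after the two-polarity
mean).  Real promontory recordings are band-limited (5–8000 Hz) and carry
line interference and movement artifacts; none of that is simulated, so
passing tests demonstrate correctness of the *measurement rules*, not
robustness to every recording pathology.

**Cochlear microphonic.**  A 2 kHz sine carrier — the center of the
1.5–3 kHz band where click-evoked CM energy concentrates — gated by
0.25 ms raised-cosine ramps around a 4 ms plateau.  CM onset is defined as
ramp start.  Its sign flips between condensation and rarefaction clicks
and its amplitude scales only with `ohc_gain`; no neural parameter touches
it.  The sine carrier (zero at onset) and the short ramp make the onset
steep enough that the 3×SD onset detector is noise-limited rather than
ramp-limited.

**Summating potential.**  A polarity-invariant negative Gamma-shaped bump
(shape 8, mode 0.5 ms at 120 dB), scaled by the synaptic survival fraction
`s`.  The narrow bump gives the SP a distinct leading deflection with a
local minimum before the CAP trough — the "SP shoulder" a clinician marks.

**Compound action potential.**  The convolution of a damped-sinusoid
single-fiber unit response (period 1 ms, decay 0.5 ms, first phase
negative) with a two-component Gamma latency density: a fast pool
(shape 8, mean 1.6 ms at 120 dB, weight 0.75) and a slow pool (mean
2.4 ms, weight 0.25).  `fast_fiber_loss` multiplies the fast weight by
`(1 − loss)` *without renormalizing*, so depleting the fast pool both
attenuates the CAP and moves/broadens it — the synaptopathy latency
signature.  The whole CAP scales with `s`.  At 120 dB the intact CAP
trough sits at ≈ 1.55 ms after CM onset with 11.4 µV amplitude.

**Level dependence.**  Component amplitudes follow logistic functions of
click level (midpoints 85–90 dB p.e. SPL, slopes 10–12 dB); latencies grow
linearly at 0.015 ms/dB below 120 dB.  These are monotone, smooth and
easily invertible conventions, not fits to any patient data — no
quantitative level functions exist for the population of interest, so the
generator's constants are free parameters chosen to land peak latencies
and amplitudes in the physiologically familiar range.

**Phenotypes.**  `normal` fixes `ohc_gain = 1, s = 1, fast_fiber_loss =
0`.  `synaptopathy(survival=s)` keeps `ohc_gain = 1` (CM and OAEs
preserved) and by default couples `fast_fiber_loss = 1 − s`, expressing
the assumption that synapse loss preferentially removes the rapid
low-spontaneous-rate fibers; both couplings can be overridden.
`cochlear_loss(ohc_gain)` attenuates the CM directly and shifts the
effective drive of SP/CAP by 40 dB per unit gain loss, raising thresholds
without neural delay — the contrast class to synaptopathy.

**Click trains.**  The train paradigm is an initial click, a 15 ms silent
gap, ten clicks at 2.9 ms intervals, repeated every 191 ms.  Per-position
CAP amplitudes follow `a_k = ρ + (1 − ρ)·exp(−(k−1)/τ)` with the
steady-state floor ρ (default 0.5) a phenotype parameter and τ = 2
positions a generator constant.  ρ is deliberately phenotype-independent
by default: synaptopathy scales the CAP but leaves train dynamics intact,
so normalized adaptation profiles of patients and controls coincide.  CM
and SP repeat unattenuated at every click (receptor potentials adapt far
less than the neural response over these rates).

**Acoustic reflexes.**  Immittance traces to 300 ms tones (18 ms ramps)
are built from two phasic zero-integral kernels: a fast pathway (rise
15 ms, relaxation 150 ms) weighted by `1.2·(1 − fast_fiber_loss)` and a
slow pathway (rise 60 ms, relaxation 400 ms) weighted 0.8.  Depleting the
fast component moves the response peak continuously from ≈ 65 ms to
≈ 140 ms after onset, reproducing the delayed, slowed reflex morphology of
synaptopathic ears without abolishing the response.  Units are arbitrary;
only timing claims are meaningful.

**Seeds.**  One top-level seed per session; per-level/polarity substreams
are drawn deterministically from it, so identical seeds give bit-identical
sessions.

## Measurement conventions

* **Baseline** = mean of the 1 ms preceding CM onset; detection bands are
  ±2 SD of that stretch, with a floor of 2% of the peak deflection so the
  rules stay defined on noiseless input.  "Sustained" means ≥ 0.2 ms.
* **CM onset** = first ≥ 3-sample run with |CM| above 3×SD of the
  pre-stimulus baseline (floor 0.5% of peak), traced back to the last
  sample within one baseline SD; this marks where the rise began rather
  than where it cleared the band.
* **SP** = first local minimum between the onset of the sustained negative
  deflection and the CAP trough; when the descent has no local minimum the
  leading shoulder (a local slope maximum followed by renewed descent) is
  used.  Amplitudes are reported as positive magnitudes of negative
  deflections.
* **CAP** = global negative extremum after SP onset, ties broken toward
  earlier time.  **Duration** runs from the deflection onset to the first
  sustained return inside the baseline band after the trough.
* **Residual-CM low-pass**: "12 dB/octave, 2 kHz" is read as the
  asymptotic slope of a second-order Butterworth magnitude.  The filter is
  applied in the frequency domain as the real magnitude response
  `1/sqrt(1 + (f/fc)^4)` — zero-phase by construction, so latencies are
  unbiased while the single-pass −12.3 dB-per-octave magnitude is
  preserved (a forward–backward time-domain pass would square the
  magnitude to 24 dB/octave).  A config switch applies it only when the
  1.5–3 kHz share of total power exceeds 5% ("where needed").
* **Train amplitudes**: because the 2.9 ms inter-click interval is shorter
  than the ≈ 4 ms response, consecutive responses overlap.  The initial
  click is isolated for 15 ms; its response serves as a per-ear template.
  Walking through the train, each measured click's scaled template is
  subtracted before the next position is read, and troughs are taken in a
  ±0.3 ms band around the template's CAP-peak lag so the non-adapting SP
  cannot masquerade as an adapted CAP.  Profiles are normalized to the
  initial click (position 1; the alternative normalization to the first
  in-train click is a one-line change in the caller).  Residual bias grows
  below ≈ 100 dB as responses broaden; noiseless recovery error is ≈ 0.02%
  at 120 dB and ≈ 3% at 90 dB.
* **Survival estimation** inverts the forward CAP amplitude model
  (logistic level term × s × fast-loss shape factor, with the default
  `fast_fiber_loss = 1 − s` coupling) by root finding; values slightly
  above 1 are possible under noise and are reported as-is.
* **Reflexes**: onset = first deviation beyond baseline ± 2 SD sustained
  5 ms (the trace is slow); peak latency = maximum negative deflection
  re onset; threshold = lowest responding level, absent if nothing
  responds at ≤ 110 dB HL.
* **Staircase**: initial gap 8 ms, 2 ms steps halved to 1 ms after 2
  reversals, floor 0.1 ms, stop after 8 reversals; threshold = mean of the
  last 6 reversal gaps (all post-shrink).  These schedule details are
  conventional transformed up-down practice; simulated thresholds are
  therefore comparable across listeners in distribution, not as absolute
  replicas of any particular laboratory's numbers.
* **ANOVA**: classical balanced mixed between–within decomposition; the
  sampling unit defaults to the ear (aggregate to subject means upstream
  if desired); no sphericity correction.  Unbalanced designs are rejected
  rather than approximated.  Group SS is referenced to the mean of group
  means so identical groups give F = 0 exactly.
* **PTA** is rounded half-up to integer dB.  Severity classes: normal
  < 20, mild 20–40, moderate 41–70, severe 71–95, profound > 95 dB HL;
  the mild band opens at 20 dB because clinical grouping treats a 20 dB
  PTA ear as mildly impaired.  The LF/HF summary averages (250/500/1000 Hz
  and 2/4/8 kHz) are reporting conventions of this package.

## Problem sizes

The test suite and the acceptance script run everything at the sizes the
analyses were designed for: 500 trials per polarity per level, 7-level
intensity series, 200 replicates per survival value for the recovery
check, 100-seed Monte-Carlo runs for onset robustness and staircase
convergence, 1000 simulated null tables for p-value calibration, and
20,000 post-convergence staircase trials for the percent-correct
criterion.

## Known limitations

* The generator's amplitude/latency constants are conventions; agreement
  with any particular patient series is qualitative (direction and shape
  of effects), not quantitative.
* White noise only; no line hum, myogenic artifact or trial rejection.
* The survival estimator assumes the generator's own forward model — on
  real data it would need calibration against a control population.
* Train-profile recovery degrades at low stimulus levels as responses
  broaden beyond the inter-click window.
* Immittance amplitudes are arbitrary units; only reflex timing is
  modeled.
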