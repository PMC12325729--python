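# Methods

This note documents the models, conventions and numerical choices behind
`habcalcium`, and what the synthetic-data generator does and does not
emulate.

## ΔF/F and trial averaging

Two baseline modes mirror the two recording regimes:

* **trial_prestim** — per stimulus event, F0 is the mean fluorescence over
  the 5 s (configurable) immediately before onset; ΔF/F = 100·(F−F0)/F0 is
  computed over a trial segment [−5 s, +30 s]. Neurons with F0 ≤ 0 are
  flagged invalid (NaN rows, counted in the report); trials that start too
  close to the recording edge are dropped with a warning.
* **moving_window** — F0(t) is a 6 min (configurable) sliding mean,
  *centered* on t and truncated at the recording edges. Centering is a
  choice made for phase neutrality (the alternative, a trailing window,
  shifts evoked transients); even-length windows take the extra frame on
  the left, matching the pandas rolling convention.

Frames are 0-based and assigned to windows by their start time. The
response window is half-open, (onset, onset + 10 s], and the baseline
window is [−5 s, 0). Response amplitude R and the baseline statistics
(μ_b, σ_b) are computed on the trial-averaged trace; per-trial amplitudes
are also returned for analyses that need them. Averaging before windowing
vs windowing per trial then averaging are identical unless trials are
dropped; the trial-mean route is the default.

Gaussian smoothing uses a unit-sum kernel with reflective edges,
implemented as normalised convolution so trial-mode matrices smooth within,
not across, their defined segments.

## Classification rules

Sensory: excited ⟺ R > μ_b + k_exc·σ_b (k_exc default 2, sweepable over
1–4); inhibited ⟺ R < μ_b − k_inh·σ_b (k_inh default 1). Excitation is
checked first; with positive thresholds both cannot hold at once. A flat
baseline (σ_b = 0) is flagged degenerate and the neuron classified by the
sign of R − μ_b.

Drug-affected: same construction on moving-window ΔF/F, comparing the drug
window mean against μ_b ± k·σ_b of a pre-wash-in baseline window (k_up = 2,
k_down = 1, windows fully configurable; the conventional windows are
minute 13–18 against the 5 min before wash-in for an antagonist and
minute 26–28 against 2 min for an agonist). Note that a *sustained* shift
is strongly attenuated by the centered 6 min baseline (the baseline tracks
the shift within ~3 min); detection therefore favours effects that are
large or transient relative to the window — a property of the ΔF/F
convention, not of the classifier.

The shuffle null circularly rotates every neuron's trace by an independent
uniform offset and recomputes the affected fraction; rotation preserves
each neuron's autocorrelation, which is the relevant null for window
means. The chance level is the null mean; the rotation scheme is one of
several defensible nulls and is documented as a choice.

Micro-stimulation: per event, median ΔF/F of the pre window and of the
first 2 s post; a two-sided Wilcoxon
signed-rank test across events at α = 0.05, direction from the sign of the
median difference. The stimulated neuron is excluded from the follower
table and must itself test excited for the recording to be admitted. The
exact null distribution is used for n ≤ 25 events without ties; zero
differences are dropped (Wilcoxon's convention).

## Interaction index

index = 100·(R_comb − max(R_L, R_V))/max(R_L, R_V). Categories:
super-additive (> 100), sub-additive ([0, 100]; index 0 belongs here since
depression is strictly below zero), depression (< 0). When
max(R_L, R_V) ≤ ε the record is flagged undefined rather than divided
through by near-zero; ε defaults to 0.5% ΔF/F and may be set to 0 to apply
the formula literally to every neuron. Stored values are never clipped;
±300 clipping is a display concern only. Per-fish category percentages are
taken over valid records, with undefined records counted separately; fish
are the replication unit in group comparisons.

## Spatial analyses

Several defensible definitions of a "significantly correlated" pair exist;
the default here is a t-transform of r with an effective sample size corrected for lag-1
autocorrelation (Bartlett: n_eff = n(1−ρ_i ρ_j)/(1+ρ_i ρ_j), floored at 4),
with a circular-shift permutation test as the alternative. Both are flagged
interpretations.

Correlation–distance profiles bin pairs by 3-D Euclidean distance
(contiguous bins, empty bins reported as missing, never zero); the
grouping unit for cross-animal summaries is the hemisphere. The two-factor
comparison ("ANOVA-n") is a fixed-effects two-way ANOVA on per-unit bin
means with main effects distance bin and treatment, no interaction by
default, restricted to bins occupied in every unit.

Dorsomedial selection: y is centred on the population mean and scaled by
the y-range; z is converted to depth from the dorsal-most neuron and scaled
by the z-range; the score is |y_norm| + z_norm and the smallest
⌈fraction·N⌉ neurons (fraction 0.40) are retained, ties broken by
neuron_id. Centring vs range-scaling conventions vary between published
analyses; range-scaling both axes makes them commensurate, and the
40%-retention count is invariant to the choice. The dorsal/ventral split takes z as depth-from-top as given and
thresholds at 40 µm (dorsal strictly below).

## Behavior

Positions are millimetres; in side view y is height above the floor.
Depth-change fraction is defined as post/pre (a documented convention —
post/pre makes diving < 1 — with the direction switchable). The post window defaults to 0–30 s after the stimulus;
sustained windows are assay- and figure-defined, hence parameters, never
constants. Speed is the summed x–y step length per 1 s bin, steps assigned
by their start sample; light→dark speed change divides post-transition bins
by the mean of the 5 s pre-transition baseline.

## The synthetic generator

The generator is the test bed: every downstream estimator is validated by
parameter recovery against its ground truth.

* **Kernel** — double exponential (rise 0.2 s, decay 1.8 s), a GCaMP6s
  stand-in sampled at 3 Hz (volumetric acquisition runs 2.3–3.4 Hz per
  plane); a GCaMP6s-like response has no single canonical kernel, so both
  constants are configurable.
* **Population** — neurons form spatially compact Gaussian ensembles
  (default 4 blobs, 15 µm length scale) in a 100 × 60 × 80 µm box; depth is
  shifted so the dorsal-most neuron sits at 0.
* **Spontaneous activity** — one slow latent per ensemble (2 s Gaussian
  smoothing), correlated across ensembles by a coupling matrix whose
  off-diagonal defaults to −0.3 to reproduce the anti-correlated Hb
  clusters; each neuron loads on its own ensemble's latent with a weight
  decaying exponentially with distance from the ensemble centre, which
  (with additive noise) yields correlations that fall off with pair
  distance. One global amplitude scale is used so those loadings survive
  (per-neuron normalisation would cancel them).
* **Evoked responses** — class assignment is by exact counts with seeded
  shuffles, so requested fractions are met exactly and recovery tests have
  no assignment noise. Defaults: 30% excited / 10% inhibited per modality,
  peak amplitudes 50% / −20% ΔF/F with lognormal spread (σ = 0.2), 10%
  per-trial jitter, per-frame noise SD 2% of baseline fluorescence. These
  amplitude/noise values are free parameters; they are chosen so
  the 2-SD classifier operates away from ceiling and floor (hit rate ≈ 1,
  false positives ≈ 0), which is what a parameter-recovery test requires.
  Inhibition is a negative deflection from a positive baseline, with a
  floor keeping fluorescence positive.
* **Multisensory modes** — on combined events the amplitude is
  factor × max(single amplitudes): additive ≥ 2 (default 2.5; exactly 2
  sits on the super/sub boundary, so the default is strictly above it),
  depressed < 1 (default 0.5), independent between 1 and 2 (default 1.5,
  partial summation). The additive and depressed behaviours follow their
  category definitions; "independent" has no forced definition and is
  deliberately placed in the interior of the sub-additive band so that no ground-truth mode sits on a
  category boundary where noise would split it. Default mode fractions are
  60% depressed / 20% additive / 20% independent, matching the reported
  prevalence of response depression.
* **Drug wash-in** — affected neurons receive a baseline shift ramping in
  over 60 s between the drug-on and drug-off markers.
* **Behavior** — depth follows a mean-reverting walk (relaxation 5 s⁻¹,
  i.e. the position tracks its set-point within ~0.2 s, as startle dives
  do) toward a preferred depth of 40 mm. A vibration drops the set-point by
  dive_frac (default 0.5) of the preferred depth, holds it for 30 s (the
  period over which evoked diving is sustained), then releases it with
  exponential recovery (τ default 30 s). The hold-then-recover shape is a
  modelling choice: it separates the dive magnitude (measured by the
  depth-change fraction over the hold) from the recovery time constant
  (measured in the sustained window after the hold). Dark phases multiply
  the target swim speed (default gain 2); the light/dark assay is simulated
  top-view with a heading random walk so the speed ratio is exact in
  expectation. The default light/dark protocol runs 3 dark/light cycles of
  5 min after 5 min habituation (the full assay runs 10 cycles; the length
  is a parameter).

What the generator does **not** emulate: optics (no PSF, no neuropil
contamination), spiking statistics (latents are smoothed Gaussian
processes, not spike trains), motion artefacts, z-drift, and real
swimming kinematics (no bout structure). A green recovery test therefore
establishes that an estimator inverts this stated world — not that it is
robust to every artefact of real recordings.

## Determinism and numerics

All generators are deterministic under (config, seed); generated seeds are
derived via `SeedSequence` with per-purpose salts. Exact rank-test p-values
are used whenever the data permit (paired n ≤ 25, unpaired min(n) ≤ 10 and
total ≤ 20, no ties), normal approximation with tie/continuity correction
otherwise; the exactness is recorded on every result. No multiple-testing
correction is applied by default (per-test p-values are reported); a
Benjamini–Hochberg helper is available. Window membership uses half-open
intervals throughout, and all public times are seconds.

## Known limitations

* The centered moving-window baseline attenuates sustained drug effects
  (see above); detection of a clean step through the full pipeline is
  marginal by construction and the drug-recovery tests use strong effects.
* The ε-guard on the interaction index excludes neurons without a usable
  single-stimulus response; near ε the index is noisy, which slightly
  inflates the depression category on real-valued data.
* The permutation alternative for pair significance recomputes the full
  correlation matrix per permutation and is quadratic in neurons — intended
  for small populations or spot checks.
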