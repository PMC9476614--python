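# Methods

This note documents the models, numerical choices and limitations behind
`duetibs`: an analysis chain for amplitude-envelope inter-brain synchrony
(IBS) in a dual-EEG piano-duet paradigm, together with the synthetic dyad
generator used to validate every stage.

## The paradigm being modelled

Each trial of the paradigm runs, cue-locked, from −1 to 16 s: a visual tempo
cue (0–1 s), four metronome beats at 120 bpm (1–3 s), a first phrase of seven
crotchets plus a crotchet rest at 120 bpm (3–7 s), a silent two-bar pause at
120 bpm (7–11 s), and a second phrase at the cued tempo (150 bpm → ends
14.2 s; 96 bpm → ends 16 s).  The 2 × 2 within-pair design crosses TEMPO
congruency (both players cued to speed up / slow down vs opposite cues) with
FAMILIARITY (partner's part practiced or not).  The full schedule is 48
trials per cell (192 per pair); piece-to-familiarity assignment is
counterbalanced so half of the pairs learn pieces A, B bimanually and half
C, D.

## Envelope PLV

The IBS measure is the phase-locking value between the two players'
band-limited amplitude envelopes, not between raw carrier phases.  Steps and
conventions:

1. **Preprocessing** — zero-phase Butterworth 0.5–95 Hz band-pass and
   45–55 Hz band-stop (3rd order per pass), linked-mastoid re-reference when
   mastoid channels are present (synthetic data are reference-free and skip
   it), epochs −1…16 s.  Interactive artifact correction (ICA, manual trial
   rejection) is intentionally out of scope; a per-trial boolean keep-mask
   stands in for it.
2. **Envelope** — band-pass into delta/theta/alpha/beta/gamma (two-pass
   Butterworth, 4th order per pass: "4th order, zero-phase" is read as order
   4 per pass, which is the common toolbox convention), then |analytic
   signal|.  All Hilbert transforms are computed over the whole −1…16 s
   epoch; the padding outside the 1–14.2 s analysis range absorbs filter and
   edge transients.
3. **Envelope phase** — the envelope is re-filtered to 1–3 Hz (the range
   spanned by the musical tempi: 96 bpm = 1.6 Hz, 120 bpm = 2 Hz,
   150 bpm = 2.5 Hz) and its analytic phase extracted.  The band-pass
   removes DC, so no separate demeaning is applied.
4. **Windowed PLV** — per trial and homologous channel pair, the modulus of
   the mean unit phasor of the phase difference over half-open 2-s windows
   stepped by 100 ms, starting at 1 s (metronome onset) and ending at 14.2 s
   (the earliest time at which fast trials end), i.e. 113 windows at 500 Hz
   with T = 1000 samples.  **Window timestamps are window centers**
   (2.0, 2.1, …, 13.2 s): a run of significant centers 7.7–8.3 s reflects
   data from 6.7 to 9.3 s.  The implementation windows a cumulative phasor
   sum (O(N) per trial); tests pin it to the naive per-window resultant at
   1e−12.
5. **Averaging order** — channel pairs within the ROI first, then trials per
   condition.  ROIs: GLOBAL (all 29 pairs), right-posterior RP
   {C4, CP2, CP6, P4, P8}, and its left homolog LP.
6. **Power convention** — band power is the mean squared envelope over the
   window/ROI/trials, consistent with the envelope-based pipeline (used only
   by the power-confound control).

## Cluster-based permutation statistics

Per window, a fully within-pairs 2 × 2 rmANOVA.  With two-level factors each
effect's F(1, n−1) is exactly the square of the paired *t* on the
corresponding within-pair contrast, which is how it is computed (vectorized
over windows and permutations); Greenhouse–Geisser correction is moot at two
levels.  Clusters are maximal runs of ≥ 2 consecutive windows with p < 0.01
(the stringent cluster-forming threshold compensates for testing five
bands); cluster mass is the summed F.  The null re-shuffles the assignment
of trials to all four cells within each pair — one shuffle per permutation
serves all three effects, but each effect keeps its own max-mass null
distribution, and permutations without clusters contribute mass 0.  Cluster
p-values use the add-one convention (b + 1)/(m + 1), so p ∈ [1/(m+1), 1] and
the test is exactly valid.  Default 1000 permutations, cluster significance
at p ≤ 0.05.

## Controls

* **Baseline PLV**: player 2's trials are re-paired within the dyad by a
  random derangement and the PLV pipeline re-run; averaging over 20
  derangements (count not externally constrained; 20 stabilizes the curve at
  modest cost) gives the locking attributable to the temporal structure
  shared by all trials.  Conditions are compared to baseline by pointwise
  paired *t* (uncorrected, by design — these are descriptive "circles").
* **Surrogate pairs**: player 1 of pair k is paired with player 2 of pair
  π(k) (cyclic shift by default, seeded derangement optionally) — no real
  pair survives.  Within each design cell, player 2's trial list is
  truncated, or extended by duplicating its first trials in order, until it
  matches player 1's count, so the surrogate analysis has exactly the
  statistical power of the real one.  The surrogate data then run through
  the identical cluster permutation test.
* **Power confound**: paired *t* across pairs on band power in the
  cluster's ROI/window, per effect.

## The synthetic dyad generator

The generator's role is to emulate the paradigm's data-generating structure
closely enough that every downstream stage is exercised with known ground
truth.

**Keystrokes.**  A first-order linear phase-correction model: each player's
next onset is the previous one plus their internal beat period, plus
α × (partner's last onset − own last onset) while auditory feedback exists
(phrase 1 only; the pause is silent, phrase 2 is muted), plus Gaussian motor
noise (default σ = 10 ms).  Anticipation of the cued tempo makes the
internal period drift from 500 ms toward the target period (400 or 625 ms)
by β ms per beat (default 0.5) through phrase 1, the pause and the phrase-2
entry beat; phrase-2 IKIs run at the target.  This minimal model reproduces
the qualitative signatures the analysis must detect: up-down cues lead
(negative signed asynchrony at every phrase-1 position), down-up lag,
congruent cues are symmetric (zero-mean), incongruent planning inflates the
entry asynchrony (≈150 ms at default β) and phrase-2 IKI differences
(225 ms noise-free), and larger α makes lag-0 IKI correlations more
negative.  The magnitudes are free parameters — the paradigm's published
record constrains the signs and orderings, not the millisecond scale.

**Dual EEG.**  Per band, latent sources (a broad topography and a
right-posterior one, so ROI averaging is meaningful) carry band-limited
Gaussian noise whose amplitude is multiplied by
m(t) = 1 + d·cos(2π·2·t − φ_p(t)), d = 0.8 by default, with segment gains
(no modulation before the metronome, 0.7 in the pause).  Player 2's
modulation phase φ₂ wanders slowly *around the beat* (mean-reverting AR(1)
at beat resolution), so trial-averaged envelopes keep their 2-Hz beat-locked
periodicity; player 1 tracks it with a per-beat offset drawn von
Mises(0, κ), interpolated between beats.  κ is resolved per
(band, segment, condition): κ = 0 gives independent envelope phases, κ → ∞
perfect tracking.  Channels are topography-weighted source mixtures plus
1/f^a background noise.  Note a structural ceiling: even at κ = ∞ and zero
background noise the measured envelope PLV saturates near ~0.88, because
the players' *carriers* are independent noises whose intrinsic envelope
fluctuations leak into the 1–3 Hz phase — the same mechanism that bounds
PLV in real recordings.  Blinks, muscle artifacts, volume conduction and
audio are not simulated; only the timing consequences of the paradigm are.

**ROI-level phase sessions.**  Calibration and power studies of the cluster
statistics need hundreds of sessions, so a light generator emits ROI-level
envelope-phase series directly.  In its dyadic mode each player's phase
diffuses around the beat with per-beat volatility 1.0 rad, decomposed into a
shared and a private diffusion component mixed with weight
λ = I₁(κ)/I₀(κ).  Two properties make this the right null machine:
mean PLV is monotone in κ (λ = 0 → independent diffusion, λ = 1 → PLV = 1),
and each player's *marginal* phase law is identical in every condition, so
any condition effect lives purely in the dyadic relationship — cross-paired
(surrogate) players see exactly the same phase-difference law in every
condition, making the surrogate null exact rather than approximate.  A
separate "common" mode locks every player independently to the shared beat
grid with von Mises(0, κ) jitter; because that locking is common to all
players, surrogate pairs inherit its condition dependence — the positive
control demonstrating that the surrogate analysis *can* fire when locking
is stimulus-driven.

## Brain–behavior models

Trial-level `behavior ~ PLV + (1|pair)`, with the PLV predictor averaged
over a stated window × ROI × band.  Linear models use ML-fitted
random-intercept regression (statsmodels MixedLM); significance is the
likelihood-ratio χ²(1) against the intercept-only null with the same random
structure.  Outcomes with |skewness| > 1 are log-transformed when strictly
positive, square-root-transformed when nonnegative (recorded in the report).
Bimodal outcomes — phrase-2 IKI differences split by congruency — are
median-split (ties to the lower bin, for determinism) and fitted with a
random-intercept logistic model estimated in-package by adaptive
Gauss–Hermite quadrature (21 nodes, Newton-recentred per group), which a
unit test pins against R's `lme4::glmer` (nAGQ = 21) on the same data.
Complete separation is reported via a flag (slope at the optimizer bound),
not silently dropped; singular random-intercept fits are flagged likewise.

## Problem sizes and numerical choices

* Calibration experiments run at the retained-data scale of the paradigm
  (14 pairs, 36 trials per cell) on a coarsened 0.3-s window grid
  (38 windows) with 200 permutations and 200 null sessions — large enough
  for a binomial check of the 0.05 family-wise rate while keeping the
  experiment an in-suite computation.  The acceptance script re-runs exactly
  this experiment.
* Effect-recovery experiments use κ(pause) = 6 (congruent) vs 0.5
  (incongruent) over 50 replicate sessions, requiring a significant TEMPO
  cluster overlapping the pause in ≥ 80% and surrogate clusters at the
  nominal rate.
* Fisher-z clamps |r| at 1 − 1e−10 so downstream averages stay finite.
* The rmANOVA guards zero-variance contrasts (F = 0 rather than NaN).
* All generators are seeded through `numpy` SeedSequence spawning
  (per pair/trial), so outputs are bit-identical given a seed and
  independent of iteration order; the pipeline derives per-stage seeds from
  the global seed and stage name.

## What passing tests do and do not show

The synthetic generators share the paradigm's timing skeleton and the
statistical structure of the measures, but not the full physiology of EEG:
no artifacts, no volume conduction, no inter-individual topographic
variability, and envelope coupling is injected at a single mechanism
(modulation phase).  Green tests therefore certify the correctness and
calibration of the *analysis* — filters, window arithmetic, statistics,
controls, models — under a faithful null and a controllable alternative;
they do not certify that real duet EEG contains such effects, nor can the
published real-data cluster masses or behavioral F values be reproduced
without the original recordings, which are not publicly deposited.
Trial-exclusion criteria of the original behavioral cleaning are likewise
approximated by an explicit rule (correct pitches, 7 keystrokes per phrase,
mean phrase-2 IKI at least 50% of the way to the cued target), since the
original criteria are specified only in prior work.
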