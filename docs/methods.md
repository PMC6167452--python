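# Methods

## Signal chain

Raw multichannel sEMG (2 kHz for NinaPro-style recordings) is processed
per channel:

1. **High-pass**, 7th-order Butterworth at 50 Hz, applied forward and
   backward (`sosfiltfilt`), so the effective magnitude response is
   |H(f)|² with zero phase. This removes motion artifacts without
   shifting movement onsets.
2. **Rectification**, then the magnitude of the **analytic signal** of
   the rectified trace. The Hilbert step is read as the common envelope
   construction — rectifying first is what gives the analytic magnitude
   a demodulating effect.
3. **Low-pass**, 7th-order Butterworth at 10 Hz, single forward pass
   (causal), matching the mono-directional smoothing convention; the tiny
   negative ripple a causal IIR can produce is clipped to zero because
   NMF requires nonnegative input.
4. **Decimation** of the envelope to 100 Hz by subsampling (the signal is
   10 Hz-limited by construction, so no further anti-alias filtering is
   needed). This makes the factorization ~20× cheaper and is configurable
   (`envelope_out_fs = fs` disables it).

Movement segments are maximal runs of a constant nonzero label in the
per-sample movement stream. Each segment is linearly resampled onto a
common 0–100 % phase axis so repetitions of different durations can be
pooled; the default is 1000 phase points for real recordings, and the
synthetic studies in the tests and acceptance script use 100 (envelopes
this smooth are fully described by far fewer points, and the smaller
pooled matrices keep the many-restart factorizations fast).

Noisy-channel screening is advisory only: a channel whose rest-period RMS
exceeds 3× the across-channel median is flagged, never dropped
automatically, because removing a channel changes the decomposition of
the remaining ones.

## Factorization and model order

NMF uses Lee–Seung multiplicative updates for the squared Frobenius loss.
Updates stop when the relative decrease of the reconstruction error falls
below `nmf_tol` (default 1e-6 of the signal energy) or at
`nmf_max_iter` = 500. Each order is factorized from `nmf_reps`
independent random initializations (uniform in (0, 1] scaled by
√(mean(V)/r)); per-restart seeds are spawned from a master seed with a
counter-based scheme so any restart is reproducible alone. The restart
with the highest VAF wins; restarts that leave a synergy column at zero
are discarded in favor of the next best. W columns are rescaled to unit
norm with the scale absorbed into C, leaving W·C unchanged.

**VAF is uncentered** (signal energy in the denominator, not
mean-centered variance). Envelopes are nonnegative with large means, so
the uncentered convention is the one under which the 90 % threshold is
meaningful; a centered definition would select different orders.

The order rule: r₀ is the smallest order with VAF ≥ `vaf_threshold`
(0.90); N extends past r₀ while each additional synergy adds
≥ `vaf_increment` (0.05) of VAF. The factorization loop stops one order
past the decision point; `full_curve=True` computes the whole curve up to
`r_max` when the diagnostic is wanted. `r_max` defaults to the channel
count, beyond which VAF cannot improve.

Pooling is per subject per grasp (repetitions concatenated). Pooling all
grasps of a subject into one matrix is a different analysis (it mixes
grasp-specific recruitment into shared modules) and is deliberately not
implemented rather than shipped untested.

## Clustering and the NED rule

All extracted spatial synergies (unit-norm vectors) form one population,
clustered by Lloyd's algorithm with plain Euclidean distance at each
order k. Initialization is k-means++ D² seeding; with the reduced restart
budget of the test profile, plain random-row seeding visibly failed to
reach the restart-budget optimum (the MED curve lost monotonicity).
Each order runs `kmeans_repeats` restarts (seeds derived from
(master, k, repeat)), and the solution with the lowest MED — the stated
quality index, mean distance of members to their assigned centroid — is
kept. Empty clusters are repaired by reseeding with the point farthest
from its assigned centroid, which preserves the every-cluster-nonempty
invariant without inflating MED. Nearest-centroid ties break toward the
lowest centroid index.

NED(k) = MED(k)/MED(1) is exactly 1 at k = 1 by construction; its slope
NED′ is the backward difference on the integer k axis (reported, not used
for selection). The clustering order is the smallest k with
NED(k) < `ned_threshold` (0.05); if the threshold is never reached the
largest tested k is returned with a warning. A population of identical
vectors (MED(1) = 0) is rejected as meaningless to cluster.

## Characterization

Centroid similarity is the dot product of unit-normalized centroid
directions (centroids are means of unit vectors, hence slightly short of
unit length). Each member synergy contributes one temporal curve — its
per-repetition phase-normalized activations averaged across repetitions —
routed to its centroid via the population's provenance records; the
centroid's mean temporal component is the pointwise mean over members.
Temporal similarity is the Pearson correlation of mean temporal
components (scale-invariant, so no amplitude normalization); a constant
curve yields NaN with a warning instead of an error.

Per-grasp cross-subject matching designates the first subject's synergy
ordering as the reference slots and assigns every other subject's
synergies to slots by maximizing total temporal-component Pearson
correlation over all injective assignments (exhaustive — module counts
are ≤ 3, so at most 3! permutations). Exhaustive matching is optimal and
deterministic where greedy matching is not.

## Synthetic ground truth

The generator runs the synergy model forwards so that every pipeline
stage has a known answer:

- **Prototypes** (default 10 over 12 channels): sparse nonnegative unit
  vectors with 3–6 active channels, rejection-sampled to pairwise cosine
  ≤ 0.9. They play the role of the true mean spatial synergies.
- **Grasp structure**: each grasp recruits 1–3 prototypes, drawn once per
  grasp with weights (0.35, 0.55, 0.10) so the expected modules-per-group
  (~1.75) reproduces the ~1.7 modules/group regime of a 28-subject ×
  20-grasp hand-grasp study. Subjects share the grasp structure.
- **Subject variability**: each subject perturbs the recruited prototypes
  by adding |N(0, sv)| per channel and renormalizing; sv defaults to
  0.01. This value is calibrated against the clustering rule rather than
  literature-typical cross-subject spread: selecting the true order via
  NED < 0.05 requires the mean within-cluster distance (perturbation
  spread ≈ 1.9·sv plus the NMF estimation floor ≈ 0.03 at the default
  noise) to stay below 0.05·MED(1) ≈ 0.037. Larger sv produces
  populations whose true clustering order is no longer recoverable at the
  5 % tolerance — a scenario the generator is explicitly not trying to
  emulate.
- **Activations**: the first recruited module is monophasic (Gaussian
  bump at 50 % phase, sd 15 %) — the grasp/hold pattern; accessory
  modules are biphasic (bumps near 15 % and 85 % phase, sd 8 %) at 80 %
  amplitude, the second pre-shaping-dominant (bump heights 1.0/0.2) and
  the third release-dominant (0.2/1.0). The skewed balances keep
  three-module groups identifiable: two biphasic modules with
  proportional activations would be a single module in every sense the
  factorization can see. Bump centers jitter across repetitions
  (sd 2 % of phase).
- **Noise**: additive Gaussian (sd 0.02 by default) on the envelope,
  clipped at zero. The clipping induces a small positive bias in silent
  regions that is the main driver of the ≈ 0.03 NMF estimation floor.
- **Raw signals**: envelopes are laid into a labeled 2 kHz timeline (5 s
  movements, 3 s rests) and multiply a zero-mean Gaussian carrier
  band-passed to 60–450 Hz. Running the preprocessing chain on this
  recovers the envelopes up to an irreducible low-frequency ripple of
  ≈ 9 % (the 10 Hz low-pass bounds how much carrier variance can be
  averaged out), which puts the mean per-channel round-trip correlation
  near 0.94 and the worst single channel near 0.89.

What the generator does not emulate: motor-unit action potentials,
electrode cross-talk, fatigue drift, inter-channel noise correlation, or
realistic cross-subject synergy variability (see the sv calibration
above). Passing tests therefore demonstrate that the pipeline recovers
the synergy model's structure under its own assumptions, not that those
assumptions hold for any particular real recording.

## Problem sizes and determinism

The library defaults mirror full-fidelity analysis (1000 NMF restarts,
200 k-means repeats, clustering orders 1–50). The test suite and
`scripts/acceptance.py` use the reduced profile — 20 restarts, 20
repeats, orders 1–15, 100 phase points — which reproduces the same
selections on the synthetic studies in a few minutes. All randomness
(generator, NMF restarts, k-means restarts) descends from a single master
seed through `numpy.random.SeedSequence` spawning, so identical configs
and seeds reproduce every output file byte-for-byte.

## Known limitations

- The 5 %-increment reading of the order rule extends past the 90 %
  threshold only; an alternative reading (apply the increment rule below
  the threshold too) is not implemented.
- k-means order selection uses NED only; NED′ is reported for inspection
  but no elbow heuristic is applied.
- Decimation assumes the envelope is band-limited by the low-pass; if
  `lp_cutoff_hz` is raised near the output Nyquist the subsampling
  becomes lossy (a parameter error guards the hard limit).
- MAT reading covers the common NinaPro layout (2-D `emg`, 1-D
  `restimulus`/`stimulus`); exotic container layouts are not handled.
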