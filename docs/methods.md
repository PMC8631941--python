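# Methods

## The model and its assumptions

The package treats multi-region neural activity as a binary pattern
process. After band-limiting to gamma (30–80 Hz), envelope extraction
and spatial Hjorth derivation, each of the N = 7 regions is either
"active" (+1, envelope above its temporal mean) or "inactive" (−1) at
every sample. The pairwise maximum-entropy model assigns pattern
`V` the energy `E(V) = −h·σ − ½ σᵀJσ` and probability
`P(V) ∝ e^(−E(V))`; it is the least-structured distribution consistent
with the observed region means and pairwise co-activations. Nothing in
the fit uses temporal order — the model describes the stationary
pattern distribution, and temporal structure is reintroduced only
through the Metropolis walk, which has this distribution as its
stationary law.

All modules share one pattern-indexing convention: bit
`bᵢ = (σᵢ+1)/2` with region 0 as the least-significant bit.

Fitting is plain gradient ascent on the log-likelihood with
exact-enumeration model moments (`h_i += η(⟨σᵢ⟩−⟨σᵢ⟩_m)`, likewise for
`J`). At N = 7 one iteration enumerates 128 patterns, so no
approximate inference is needed; the ascent step is η = 0.1 with a
geometric decay when the gradient direction starts oscillating, the
convergence tolerance is 1e-4 on the largest moment gap, and the
iteration cap is 1e5. Degenerate empirical means in the first-order
reference model are handled by clipping `atanh` at ±(1−1e-9). In the
KL divergences, empirical zero-probability patterns contribute zero
(`0·log 0 = 0`).

## Landscape construction

* **Minima** are patterns strictly below all N single-flip neighbours.
* **Basins** follow deterministic steepest descent; when two downhill
  neighbours tie exactly, the lower pattern index wins. Exact ties are
  a measure-zero event for fitted parameters; the rule exists so that
  every input has one answer.
* **Saddles** `E*(l,m)` are computed by re-inserting nodes in ascending
  energy order with a union–find: the level at which two minima first
  join is the lowest threshold at which they stay connected when all
  nodes at or above the threshold are removed. Equal-energy nodes are
  inserted together, which is equivalent to stepping the threshold over
  the sorted distinct energy values. The resulting matrix is a
  single-linkage ultrametric; the recorded merge events are the
  disconnectivity tree.
* **Directional barriers** are `E*(l,m) − E(min l)`, so
  `barrier(l→m) − barrier(m→l) = E(min m) − E(min l)` exactly.
* **Coarse-graining** absorbs minimum `l` into `m` when
  `barrier(l→m) < 1` and `E(l) > E(m)`; the lowest qualifying barrier
  merges first and group saddles are single-linkage, re-evaluated after
  each merge. The threshold of 1 energy unit is the standard choice for
  this analysis family and is exposed as a parameter. Surviving minima
  are named from their activity profiles — F must have the frontal trio
  active and the visual pair silent, V the reverse — and the
  intermediate state is the remaining survivor whose tree position lies
  between them. Patterns of surviving minor basins are labelled Other.
  Steepest descent classifies every pattern, so no samples are dropped
  at saddles; "Other" is purely basin membership.

## The synthetic three-basin template

The packaged ground truth is a fixed (h, J) pair for N = 7, shipped as
documented constants. It was calibrated once by a penalised
Nelder–Mead refinement of the 28 free parameters, started from a
pairwise fit to a three-cluster target distribution, against purely
structural criteria:

* exactly three major states after coarse-graining at threshold 1 —
  frontal-dominant `(+,+,+,−,+,−,−)`, intermediate `(−,−,−,−,+,−,−)`
  and visual-dominant `(−,−,−,−,+,+,+)` — with every major barrier
  above 1 (range ≈ 1.4–2.7 in the shipped template);
* the intermediate state between F and V in the disconnectivity tree,
  and no direct F|V basin adjacency, so that transitions pass through
  Int;
* basin pattern counts matching Boltzmann basin occupancies (so that
  appearance frequencies track basin sizes, as in recordings);
* wide energy margins at every minimum and basin boundary, so that the
  landscape of a model refitted from 1e5 samples reproduces the same
  structure (the fourth, co-active local minimum is kept robustly
  shallow and is always absorbed into the intermediate state);
* bounded parameter magnitudes and energy range, keeping the fit
  well-conditioned.

The template gives the parietal pSPL a tonically active role and
leaves aSPL weakly coupled (a free "noise" dimension), which breaks
block degeneracies. The profile differs from the simplest sketch
(F and V exactly complementary): that sketch cannot satisfy the
rare-direct-transition and basin-occupancy criteria simultaneously,
because complementary deep wells always develop direct basin contact
on the 7-cube.

Sampling uses exact categorical draws from the enumerated Boltzmann
distribution; a persistence parameter repeats the previous pattern with
probability p and redraws otherwise, which adds temporal
autocorrelation while leaving the marginal distribution untouched.

### Synthetic EEG

Each region's centre electrode carries a 30–80 Hz carrier whose
envelope is high while the region's latent activity is +1 and low
otherwise (levels 1.0 / 0.1); its three surrounding electrodes carry
the shared low-frequency background and their own broadband noise, so
the Hjorth derivation (3 × centre − neighbours) recovers the
modulation. The carrier is band-limited noise reduced to its
instantaneous phase — a constant-envelope, noise-like gamma signal —
so that the envelope equals the state modulation; the multiplicative
Rayleigh fluctuation of a Gaussian carrier is not part of the modelled
signal and would otherwise dominate per-sample binarisation errors.
`snr` scales the modulated carrier against unit-variance additive
noise; `snr = 0` yields pure noise and chance-level recovery. The
generator does not model volume conduction, realistic spectra beyond
the gamma band, or eye-movement artifacts — passing tests show that
the analysis chain inverts its own generative model at the stated
noise levels, not that it would perform identically on recordings.

Percept durations are generated as `slope · travel + noise`, truncated
at 0.1 s; with the default travel-length spread the noise is chosen so
the population travel/duration correlation is ≈ 0.67.

## Temporal conventions

One Metropolis step is treated as one sample of the offline recording
(300 Hz), so the 10 ms smoothing window equals 3 steps on simulated
trajectories. Rejected proposals occupy one step. Travel length
counts the steps from an entry into F to the first return to F after V
has been visited (back-moves included); with no completed cycle the
result is flagged undefined rather than zero.

Smoothing computes per-state appearance frequencies in a centred
sliding window (Other counts in the denominator only), applies a
Gaussian of FWHM 10 ms (σ = FWHM/2.3548), and takes the per-sample
argmax over (F, Int, V) with ties resolved to the earlier state in that
fixed order. The output therefore never contains Other.

## Online tracking

The tracker reproduces the real-time chain deterministically: Hjorth
reduction of the 28 channels, a 1000 ms window (2000 points at 2 kHz),
frequency-domain gamma masking with the analytic signal built directly
in the frequency domain, 100 ms edge trims, and a Yule–Walker AR(30)
forecast of 280 ms beyond the trimmed edge (T = −100…+180 ms around
the true recording end; coefficients from sample autocovariances via a
Toeplitz solve, recursion via an IIR filter). After binarisation
against control-run thresholds, classification and smoothing, states
cover T = −95…+175 ms. A trigger requires the target state in > 90 %
of T = 25…175 ms (history conditions additionally require the prior
state in > 90 % of T = −95…25 ms), fires at window end + 21 ms, and is
suppressed for 9 s after an honoured trigger. The window stride
defaults to 5 ms and is configurable (the hardware cadence of the
original system is not part of the simulation); the packaged tests use
10 ms to keep runtimes modest. Each window contributes its predicted
labels at T = +25 ms…+25 ms+stride to the online state stream, i.e.
the earliest part of the actionable span, which is what the trigger
logic acts on. Simulated trigger latency is exact by construction and
reported as zero error.

Control-run thresholds are per-region means of the windowed gamma
envelope over a separate recording; the generator's control runs use
i.i.d. latent states so every region visits both levels.

## Virtual stimulation

Inhibition of region *i* removes every pattern with `σᵢ = +1`; the
remaining 2^(N−1) patterns keep their energies (same h, J) and the
whole landscape machinery runs on the restricted adjacency. A removed
major minimum is re-anchored at its surviving neighbour (the pattern
differing only at the target region), and the label attaches to the
restricted basin containing that neighbour. When two major labels land
in one restricted basin the collapse is raised as an explicit error —
on the packaged template this happens for frontal and visual targets,
whose states are sustained by strong within-block couplings, while
parietal targets preserve all three states. Preserving all three
states under silencing of *every* frontal site is not achievable
jointly with the template's other structural criteria: summing the
stability margins of the restricted frontal state over the three
possible silenced sites equals `E(Int) − E(F)` identically, so full
survival would require an intermediate minimum several units shallower
than F, with a basin too broad to realise on 128 patterns while basin
counts track occupancies. The restriction machinery itself is
independent of the template and is verified against brute-force
enumeration at small N. Removal matches the simulated intervention this analysis family
uses; a graded alternative (a basal-activity shift on the target
region, `graded_inhibition`) is provided as a clearly labelled
extension and feeds the same landscape pipeline.

## Behavioural statistics

Median percept duration uses clear (non-mixed) percepts only.
Mediation is ordinary least squares with the product of coefficients:
α from `M ~ X`, β and γ′ from `Y ~ X + M`, γ from `Y ~ X`, indirect
effect α·β with a percentile bootstrap (default 5000 resamples) over
participants; for linear models γ = γ′ + α·β holds to numerical
precision, which the tests assert. No covariates are used. Effect
decay is profiled as the absolute Fisher-z-transformed
across-participant correlation per analysis window.

## Problem sizes and numerical choices

The packaged analyses use 1e5-sample series, 1e5-step walks (burn-in
100) and 1e6-step walks for stationarity checks; these sizes put the
sampling error of every reported quantity well inside its acceptance
band while keeping the default test run short. Zero-phase filtering
(forward–backward Butterworth) is used everywhere offline so envelope
timing is undelayed. Binarisation uses a strict ">" with a 1e-9
relative guard so values exactly at threshold (e.g. a constant series
against its own float-accumulated mean) map to −1 deterministically.
The optional first-difference pre-whitening step before the Hjorth
derivation is exposed as a config flag and defaults to off; whether
such a step should apply to raw signals or envelopes is ambiguous in
this analysis family, and the flag documents rather than hides that
choice.

## Known limitations

* Exact enumeration bounds the model at N ≤ 20 regions (the analyses
  here use 7); no pseudo-likelihood fallback is provided.
* The synthetic EEG generator is an inverse model of the preprocessing
  chain, not a biophysical forward model.
* The online simulator models timing bookkeeping, not hardware
  latencies; real closed-loop accuracy additionally depends on
  acquisition and stimulation delays.
* Landscape-restriction results depend on the fitted parameters;
  preservation of all major states under silencing of a strongly
  coupled region is data-dependent and not guaranteed (and is
  explicitly reported when it fails).
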