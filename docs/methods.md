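# Methods

## The coupled double-column model

Each cortical column follows the three-population neural mass architecture:
pyramidal cells receive an excitatory feedback loop (interneurons), an
inhibitory feedback loop, and external input.  Average PSPs obey
second-order kinetics — gains `A = 3.25 mV` (EPSP) and `B = 22 mV` (IPSP),
rate constants `a = 100 s⁻¹` and `b = 50 s⁻¹` — and population potential
converts to firing rate through
`S(v) = 2 e₀ / (1 + exp(r (v₀ − v)))` with `e₀ = 2.5 s⁻¹`, `v₀ = 6 mV`,
`r = 0.56 mV⁻¹`.  These constants are the standard literature values for
this model family and are treated as fixed physiology; they are exposed in
`ColumnConstants` but not estimated.

The four intra-column synapse counts derive from one global connectivity
constant per column: `(C, 0.8 C, 0.25 C, 0.25 C)`.  We interpret the free
parameters `C1`, `C2` as these global constants, one per column, searched
in `[60, 120]`.  This is a genuine modelling choice — the alternative
reading (a single sub-constant) is inconsistent with a search range that
sits below the canonical value `C = 135` yet still produces the classical
band-limited oscillation, which we verify for `C = 135` in the tests.

Inter-column coupling: the pyramidal firing `S(u_j)` of column j passes
through a critically damped delay kernel with rate constant
`a_d = 33 s⁻¹` (the slower kinetics of long-range transmission; literature
value for the coupled-column model, as no printed value exists for this
study) and enters the other column's excitatory input block scaled by the
directed gain — `K1` for occipital → frontal, `K2` for the reverse.
Setting `K1 = K2 = 0` decouples the system exactly into two isolated
columns, which the test suite checks bit-for-bit.

State vector: 8 states per column (three PSP blocks plus the delay block,
each position + velocity), 16 total.  Output per column is the pyramidal
membrane potential, the difference of the excitatory and inhibitory PSP
states.

### Numerics

* Fixed-step classical RK4 at `dt = 1 ms`, matching the 1000 Hz recording
  rate; the drive is held constant across each step (the drive noise is
  white at the sample rate, so sub-stepping it would change nothing).  An
  optional finer step with decimation exists but is not the default:
  reproducibility and speed matter more here than adaptive error control,
  and halving `dt` changes the output by less than the fit tolerances.
* Initial state all zeros, with a 1 s burn-in integrated and discarded
  before the 3 s analysis window — at least 30 time constants of the
  slowest kernel, ample for transient decay.
* The integrator is compiled (numba); the swarm objective simulates all
  particles of a generation in one batched kernel call (~60 ms per
  generation of 60 particles on one core).
* Trajectories that leave `|y| < 1e12` are reported as diverged: the
  scalar API raises naming the parameter set, while the PSO objective
  substitutes a large finite penalty (1e6) so the swarm continues.  Inside
  the search box the sigmoid saturates all feedback and divergence does not
  occur at the default constants; it can occur for user-supplied rate
  constants beyond the RK4 stability limit.

## Stimulus model

The occipital drive `p(t)` is uniform white noise on `[120, 320]` pulses/s;
flicker conditions add a square pulse train (amplitude 7.0, 50% duty) at
the stimulus frequency; the frontal drive `p′(t)` is always pure noise.
The pulse shape and duty cycle are configuration, not physiology: a
flickering LED is closest to a square drive, and the drive increment is
treated as dimensionless (the "7 V" of the original LED supply has no
pulse-density unit).  With these defaults the 8 Hz output shows a clear
stimulus-frequency spectral line, while the 44/84 Hz responses are
attenuated by roughly two orders of magnitude through the PSP low-pass
chain — the selectivity that makes 8 Hz an SSVEP-effective frequency in
this model.

## Inversion

Fitness of a candidate `(C1, C2, K1, K2)` is
`RE(u₁, U₁) + RE(u₂, U₂)` with `RE(X, Y) = ‖X − Y‖ / ‖X‖`.  The relative
error is the only error measure defined for this problem; summed squared
error and a spectral-magnitude RE are available through configuration.

**Shared-noise protocol.**  Candidate simulations reuse one fixed drive
realisation: the stored generating drives for synthetic fixtures, a seeded
surrogate for real recordings.  This is load-bearing — the output
fluctuations are noise-driven, so with per-candidate fresh noise the
waveform-level RE would plateau at the noise floor (~0.03 here) and the
sub-0.01 fit regime would be unreachable.

**PSO.**  Standard inertia-weight swarm: Q = 60 particles, G_max = 100
generations, accelerations t₁ = t₂ = 2, inertia decaying linearly
0.9 → 0.4 across the budget (the canonical schedule for this PSO variant),
velocities initialised uniformly over ± the box span, positions clamped to
the box with the violating velocity component zeroed, incumbent best kept
on ties.  Termination: G_max generations, or global-best improvement below
δ = 1e-6 for D = 20 consecutive generations.  The stagnation rule stops
mid-plateau runs early by design; the convergence property test therefore
uses a longer window (D = 60) to measure the optimizer's asymptote.

**Identifiability.**  Shared-noise inversion reaches per-channel RE of
order 1e-4, but the map from parameters to waveforms is nearly degenerate
along a (C1, K1) compensation ridge: pilot recovery runs show per-segment
K1 errors with a standard deviation near 300 that does not shrink with more
PSO budget.  Per-segment estimates are therefore noisy even when fits are
essentially perfect; averaging the five segments of each subject (the
pipeline default, mirroring the study design) is what makes
condition-level K1 contrasts detectable.  This is a property of the model
and data length, not of the optimizer.

## The emulated study

`StudyFixture` defaults define the synthetic study: 10 subjects × 4
conditions (control, 8, 44, 84 Hz) × 5 segments of 3 s at 1000 Hz.
Generating parameters: `C1 = C2 = 90`, `K2 = 350`, `K1 = 2000`, with the
8 Hz condition's `K1` at 2500 — a 25% elevation chosen once to mirror the
strong, clearly significant frequency effect the analysis is meant to
detect — plus between-subject jitter (sd 150 on K1, 50 on K2, 5 on C's)
and small condition-level jitter (sd 50/20/2).

PDC needs more channels than the two-column model produces, so each
segment also carries a six-electrode VAR(2) recording over
`V1_L, V1_R, V2_L, V2_R, FrA_L, FrA_R` with known directed structure:
stable diagonal dynamics, bidirectional within-area links, a weak constant
FA→VC feedback (0.08), and VC→FA lag-1 coefficients of 0.12 elevated to
0.30 for 8 Hz (subject jitter sd 0.03).  The two planted effects — model
K1 and VAR VC→FA — emulate the same underlying physiology from the two
analysis perspectives.

What the generator does **not** emulate: volume conduction and reference
effects, line noise and movement artifacts (the emulated segments are
"artifact-free" by construction), 1/f background spectra in the VAR
recordings, and any coupling between the model channels and the VAR
channels within a segment.  Passing tests therefore demonstrate that the
estimators recover known structure under the study's design and noise
model, not that real tissue satisfies these models.

## PDC

MVAR coefficients come from multichannel OLS on the stacked lag regression,
per segment, no intercept, channels mean-centred (the model has no constant
term; recorded EEG is band-passed and near zero-mean anyway).  Order is
chosen by `AIC(p) = ln det Σ̂_p + 2 p N² / n` over 5–20, ties to the
smaller order.  PDC uses the column normalisation
`π_ij(f) = |A_ij(f)| / ‖a_j(f)‖₂` (a_j the j-th column of A(f)), so each
source's outflows are normalised: `Σ_i |π_ij(f)|² = 1` at every frequency,
enforced to 1e-10 in tests.  Flow matrices are stored target-by-source and
labelled, because silently transposing this matrix flips the direction of
every headline conclusion; `aggregate_flows` works on labels, never on
positions.  Band averaging takes the **magnitude** of PDC (not its square)
over the 1 Hz grid points in 6–92 Hz, reading "average of PDC strength"
literally; the squared variant is a config switch.

## Group statistics

One-way repeated-measures ANOVA per measure:
`F = MS_cond / MS_error` with df `(k−1, (k−1)(n−1))` — `(3, 27)` for the
10 × 4 design.  Greenhouse–Geisser ε comes from the double-centred
condition covariance, `ε = (tr M)² / ((k−1) tr M²)`, clipped to
`[1/(k−1), 1]`; both df are scaled by ε for the corrected p value.
Post-hocs are two-sided paired t tests of the reference condition (8 Hz by
default) against each of the other three, Bonferroni-corrected with m = 3;
sidedness is two-sided throughout as the conservative default.  Degenerate
inputs are explicit: zero effect SS → F = 0; zero residual variance →
error; zero-variance nonzero-mean post-hoc differences are flagged
undefined rather than silently infinite.  Implementation is from the
textbook formulas (the degenerate cases above need explicit control);
`pingouin` and `scipy.stats.ttest_rel` serve as independent oracles in the
test suite, and the null calibration test checks a 5% ± 2% rejection rate
over 1000 null tables.

## Validation scales

Problem sizes used by the packaged validation experiments (chosen as the
package's own benchmark protocol):

* Fit quality: full study protocol — 4 conditions × (Q = 60,
  G_max = 100) on 3 s segments; reported bound max RE < 0.01.
* Planted-effect ordering: the full default study (10 × 4 × 5) with a
  reduced swarm budget (Q = 30, G_max = 25), which preserves fit quality
  well below the working bound while cutting wall time; recovery noise at
  this budget is indistinguishable from the full budget (see
  Identifiability above).
* Detection power: 20 regenerated study replicates at one segment per
  condition (Q = 24, G_max = 25), inversion + statistics stages only.
  Single-segment replicates forgo the 5-segment averaging, so this is a
  conservative lower bound on the default design's power.

## Known limitations

* Only two coupled columns; no extended networks, no volume conduction or
  reference modelling.
* The (C1, K1) ridge limits per-segment parameter identifiability (see
  above); confidence in single-segment estimates should not be based on RE
  alone.
* PDC here quantifies direct linear Granger-type influence on the fitted
  montage; flows routed through unmodelled nodes are not attributed.
* The physiological constants are fixed at literature values; misfit from
  wrong constants is absorbed into the coupling estimates.
* EDF import is read-only and maps labels verbatim; no montage re-referencing
  is performed.
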