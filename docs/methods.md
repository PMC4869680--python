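# Methods

## Signal model

Heart period (the interbeat interval, IBI) is used rather than heart
rate because heart period is linearly related to autonomic input in
vagal stimulation studies. The stimulus-evoked heart period response
(HPR) is modelled as the output of a linear time-invariant (LTI)
system: a brief autonomic input at (or near) CS onset convolved with a
fixed response function. Linearity implies pure summation of
overlapping responses, which is only approximately true of the cardiac
oscillator; the assumption is serviceable because trial schedules keep
at least 11 s between CS onsets.

The canonical heart period response function (HPRF) is a gamma density
with shape `k`, scale `theta` (s), onset `x0` (s) and amplitude `A`
(free in the GLM). Four parameter sets are shipped, named for the data
they were derived from (`dataset1`, `dataset1_optimized`, `dataset12`,
`dataset12_optimized`); the combined-sample optimized row
(k=48.5, theta=0.182, x0=−3.86, peak 4.79 s after CS onset) is the
default because the larger derivation sample generalises better. The
gamma parameterisation is strongly degenerate: the `dataset1` row
(k=2.56e5, theta=2.26e-3, x0=−574) and its optimized counterpart
produce nearly identical curves from wildly different parameters, so
curves — peak latency, width, amplitude — are the meaningful
quantities, never raw parameters. All basis functions are
peak-normalized; GLM amplitudes rescale inversely, and all
reconstruction-based scores are invariant to the normalisation and,
more generally, to any invertible recombination of the basis.

Basis sets: G1 = canonical; G2 = canonical + analytic time derivative
(first-order absorption of latency shifts); G3 = G2 + an early
stimulus-processing response; S1 = CS− baseline response + canonical.
The early and CS− components have no analytic definition in this
package: they ship as clearly-labelled synthetic stand-in fixtures
(`src/hpr/data/*_synthetic.tsv`, generated by
`hpr.synthetic.fixture_curve`) with plausible shapes. They only enter
the secondary models G3 and S1; G2 is the recommended model.

## Preprocessing conventions

* QRS detection: offline Pan–Tompkins — zero-phase 5–15 Hz band-pass,
  derivative, squaring, 150 ms centred moving-window integration,
  adaptive dual thresholds with search-back, 200 ms refractory — then
  R-peak refinement on the raw signal within ±100 ms.
* Pulse (PPS) detection: template matching. Template-eligible peaks
  need prominence above one third of the signal amplitude (robustly
  taken as the 1st–99th percentile span, so single artifact spikes do
  not disqualify ordinary pulses) and more than 0.3 s distance from
  neighbouring candidate peaks. The template is the mean one-IBI
  window around eligible peaks; beats sit at normalized
  cross-correlation maxima (threshold 0.5, spacing ≥ 0.3 s). A pulse
  whose full template window extends past the recording edge cannot
  be matched. The pulse-transit lag shifts all beats equally and
  cancels in IBIs.
* IBIs deviating more than 2 SD from the subject mean can be flagged;
  automatic repair is opt-in (`interpolate` re-derives beat times from
  interpolated IBI values; `merge_split` redistributes beats between
  clean anchor beats, preserving event alignment) and always emits a
  human-readable log. It replaces case-by-case expert review, which
  remains possible via the log.
* Each IBI (ms) is assigned to its following beat, interpolated
  linearly at 10 Hz (edge values held), and band-pass filtered with a
  zero-phase Butterworth filter, order 2 per pass (effective order 4),
  default cutoffs 0.015–0.5 Hz. Filter padding is scipy's default
  odd-reflection. Epochs run [0, 11) s from CS onset at 10 Hz (110
  samples); the baseline is the literal mean over [−5, 0) s, with no
  exclusion of overlap from previous trials.

## GLM and scoring

Design columns are per-condition impulse trains convolved with each
basis function and filtered identically to the data, so filtering
commutes with the model. Reinforced CS+ trials are excluded from
condition scores; by default they are modelled as two nuisance columns
(canonical at their CS onsets and at the US times) so their variance
does not bleed into retained-trial estimates — toggleable, since
omitting them entirely is also defensible. Estimation uses the
pseudoinverse (minimum-norm least squares under rank deficiency).
Regressors are condition-wise, one amplitude vector per condition per
subject; trial-wise estimation is possible through the same design
machinery but is not the default because single-trial HPR is dominated
by respiratory sinus arrhythmia.

Scores: model-based = signed value at the maximum absolute deviation
of the reconstructed response in [2, 11) s (ties break to the earliest
sample, for determinism); P1 = the same statistic on the condition-mean
epoch; P2 = maximum positive value in [2, 11) s; P3 = mean over
[2, 8) s (shorter window because the mean is more noise-sensitive
after the response ends). The first 2 s are excluded because early HP
changes are stimulus-nonspecific. Model-free scores are computed on
the condition-mean epoch; per-trial scoring then averaging is exposed
via the epoch list.

Predictive validity regresses condition (1/0) on score plus subject
dummy intercepts; NLL = n·log(RSS/n) with an RSS floor of 1e-300; no
parameter-count penalty because the regression has the same dimension
for every method. The score coefficient's t is algebraically the
paired t (both reduce to t² = (N−1)(Σd)²/(NΣd²−(Σd)²)). |ΔNLL| > 3 is
decisive, strict inequality. The US-locked variant shifts the basis by
(SOA − 3.5 s) with unchanged shape and requires a constant SOA per
session. The filter search spans high-pass {0.01…0.1} Hz × low-pass
{0.25, 0.5, 1} Hz, refits the response function on the grand-mean
difference wave at each grid point, and flags settings within +3 of
the optimum as indistinguishable.

## Gamma fitting

The 4-parameter gamma fit to a difference waveform is degenerate, so
optimisation starts from the best point of a deterministic coarse grid
(peak latency 3–7 s × width 0.5–3 s × shape {5, 20, 60, 200}, with the
amplitude solved linearly) and refines with bounded least squares in
(log k, log theta, x0, A); if refinement ever worsens the residual the
grid optimum is kept, so the final RSS never exceeds the grid's.
All-zero input returns a degenerate fit with A = 0. Gaussian
autonomic-input reconstruction (input ∗ prior response function ≈
observed response) is bounded least squares with the centre
constrained non-negative, so the estimated input cannot precede CS
onset.

## Synthetic sessions

The generator emulates what the model assumes: an instantaneous
heart-period function p(t) = mean (900 ms) + RSA sinusoid (0.25 Hz,
40 ms, random phase per subject) + slow drift (0.005 Hz, 30 ms) +
gamma-shaped conditioned responses (CS+ 40 ms, CS− 10 ms, US-evoked
50 ms on reinforced trials) with a per-subject latency shift
(SD 0.5 s). Beats follow a renewal rule — the IBI ending at each beat
equals p evaluated at that beat, solved by fixed-point iteration —
which is exactly the construction the downstream interpolation
inverts, plus white per-beat noise (10 ms SD). Schedules mirror delay-
and trace-conditioning designs: ITIs drawn from {7, 9, 11} s, 4 s CS,
SOA 3.5 or 4 s, 50% reinforcement, 80 CS+ / 40 CS− per subject by
default. ECG rendering places a Gaussian-sum PQRST complex at each
beat; PPS rendering places a smooth pulse at each beat plus a constant
transit lag.

What it does not emulate — and therefore what passing tests do not
show about real data: RSA is narrowband rather than broadband and has
no amplitude modulation; there is no Mayer-wave (~0.1 Hz) variability,
no movement or electrode artifact, no ectopic beats; response shape is
exactly the canonical gamma (the self-consistency regime in which the
derivative term of G2 demonstrably helps); and response amplitudes are
homogeneous across subjects, so simulated effect sizes are much larger
than typical empirical ones. The simulation-based tests validate that
the estimation machinery recovers the model's own generative
structure, not that the model fits real cardiac data.

## Problem sizes and numerical choices in the shipped tests

Study-scale checks use 50 replicates of 30 subjects (80 CS+ / 40 CS−
trials each) for the method-ranking property; 200 replicates of 12
subjects (20 CS+ / 10 CS−) with equal true amplitudes for
false-positive calibration against the binomial 95% interval; 15
replicates of 15 subjects for the US-locking comparison — sizes chosen
to give stable majorities at desk scale. Oracle equivalences are
asserted at 1e-8 (least squares vs normal equations; regression t vs
paired t) and 1e-10 (design columns vs direct impulse summation). All
simulation seeds are fixed.

## Known limitations

Single-trial amplitude estimation is exposed but unvalidated (RSA
dominates single trials). RSA is only mitigated by band-pass filtering
and trial averaging, not modelled from a respiratory signal. The
early-response and CS− fixtures are synthetic stand-ins, so absolute
conclusions about G3 and S1 should not be drawn from this package.
Multi-lead ECG fusion, arrhythmia handling beyond IBI flagging, and
real-time detection are out of scope.
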