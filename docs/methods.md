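# Methods

This note documents the models implemented in `cardiofuse`, the
parameters that matter, the numerical conventions, and the places where
the design was genuinely open and a choice had to be made.

## Conventions

All timestamps are seconds from recording start; all sample indices are
0-based on the common 100 Hz grid; all intervals are milliseconds. A
cardiac cycle runs from one R-peak to the next, left-closed
right-open — R-peaks are the only fiducials available to every
modality. The physiologic beat-to-beat interval range is fixed at
333–2000 ms (30–180 bpm) and bounds every lag search and interval
stream.

## Shape-based SNR

Cycles are segmented by the reference R-peaks; only cycles fully inside
the analysis window count, partial edge cycles are dropped. Each cycle
is linearly interpolated onto a P-point unit phase grid (P = 200 by
default, ≥ 2× the samples per cycle at 100 Hz and 60 bpm; linear
interpolation both directions — cheap, monotone, adequate at this
sampling rate) and the template is the pointwise mean. The noise-free
reconstruction interpolates the template at
φ = (n − beat_k)/(beat_{k+1} − beat_k), wrapping between the last grid
point and the first. Samples not covered by a complete cycle are
excluded from **both** sums of the SNRS ratio rather than zero-filled,
which would bias the residual with unmodeled segments. A zero residual
or zero reconstruction power is reported as an explicit ±∞ sentinel,
never silently.

Per-episode analysis extracts a separate template per maneuver episode
from the artifact-free period of the same 30-s slot — window
[maneuver end + guard, slot end] with a 2-s guard for artifact tails —
because a change of posture after a maneuver can change the waveform
morphology. SNRS is reported over the maneuver window and the rest
window separately. An episode whose rest window is predominantly
rail-saturated (more than half the samples at the channel's extreme
values, which only clipping produces) or has fewer than two beats is
skipped with a warning; in the standard synthetic protocol this removes
the two stand-up/sit-down slots.

"10 log" is read as 10·log₁₀ — decibels throughout.

## RMS motion

Movement is defined as the AC component of each marker coordinate: for
a window of N samples, RMS = √(mean((x − x̄)²)) with the mean taken over
the same N samples, recomputed per analysis window. Thorax motion
averages the per-axis RMS over markers 2, 3, 4 and 6 (head marker 1 and
arm markers 5 and 7 excluded). RMS of an exactly constant coordinate is
returned as exactly zero. Note that window RMS is not additive across
sub-windows unless their means agree; per-episode values must be
computed on the episode window directly.

## Pan–Tompkins QRS detection

The classic stage chain re-derived for fs = 100 Hz: 5–15 Hz
second-order Butterworth band-pass (applied zero-phase; the detector is
offline, and removing the group delay simplifies fiducial refinement),
differentiation, squaring, 150-ms moving-window integration, adaptive
signal/noise threshold tracking with a 200-ms refractory period, and
search-back with a halved threshold when the gap since the last beat
exceeds 1.66× the running RR average. Detections are refined to the
local extremum of the band-passed signal within ±100 ms. The first 2 s
initialize the thresholds; shorter inputs yield no detections, with a
warning.

## Local interval estimator (LIE)

The estimator exploits the self-similarity of consecutive heartbeats:
in a 3-s window, a normalized autocorrelation profile over the
333–2000 ms lag range scores how well the signal repeats at each
candidate interval; the profile peak gives the interval and a
peak-to-mean concentration ratio gates emission. The full chain per
window and channel:

1. **Baseline removal.** A 1-s moving-average baseline is subtracted.
   Motion artifacts ride on slow baseline bumps that correlate at
   arbitrary lags; removing them also collapses saturated plateaus to
   zero variance, so a clipped window gates itself out.
2. **Two correlation curves.** Per-lag Pearson correlation of (a) the
   waveform after a 50-ms Hann smoothing — narrow QRS spikes misalign
   completely under physiologic beat-to-beat jitter, and widening them
   restores the one-beat-lag peak — and (b) the amplitude envelope
   (rectified, 150-ms smoothing). Each curve is floored:
   score = clip((r − 0.25)/(1 − 0.25), 0, ·). The 0.25 floor is ≈ 3σ of
   the finite-sample correlation null at these window lengths, so white
   noise produces a near-empty profile. The profile is the geometric
   mean of the two curves: the waveform curve is precise but shows side
   peaks at the intra-beat oscillation period of multi-lobe waveforms
   (BCG), the envelope curve is blind to intra-beat structure, and only
   lags supported by both survive.
3. **Per-channel gate.** A channel enters the fusion sum only if its
   window is not clipped (≤ 5 % of samples at the channel's rails), its
   profile peak is significant (≥ 0.5 — tiny sparse peaks would
   otherwise score arbitrarily high concentration ratios), and its
   peak-to-mean ratio reaches the threshold (default 3.5, chosen as the
   strictest value that keeps every clean single cardiac channel at
   ≥ 95 % coverage in a calibration run; the smooth PPG profile is the
   binding case). Gating before summation prevents catastrophic
   fusion — a corrupted channel would otherwise pour noise into the
   joint profile.
4. **Greedy fusion.** Admitted profiles are summed in descending
   peak-height order, keeping each addition only if the joint profile
   still passes the gate. One confident channel is therefore never
   vetoed by a disagreeing weaker one, and the fused stream emits
   whenever at least one channel passes.
5. **Lag selection.** Candidate peaks are ranked by
   score(τ) + max(score near 2τ) (±100 ms tolerance, matching the
   beat-jitter displacement of the two-beat peak): the true interval is
   reinforced by its own harmonic while the harmonic finds no support
   at 4τ. A 3-point parabolic fit refines the winning lag below the
   10-ms sample resolution.
6. **Trend consistency.** An interval outside ±(25–35) % of the median
   of the last five accepted intervals is almost always a harmonic or
   half-lag slip — the heart does not halve its rate between beats —
   and is rejected rather than reported. Five consecutive rejections
   clear the history so the tracker can re-lock after a genuine rate
   change.
7. **Pacing.** After an accepted interval the window advances by that
   interval (one estimate per heartbeat, so coverage can reach 100 % of
   the reference intervals); after a rejection it advances 0.5 s.

The optional adaptive prior multiplies the profile by
0.15 + 0.85·exp(−(τ − m)²/2σ²), centered on the median m of the recent
accepted intervals (robust to a single gross error), with
σ = 120 ms · (1 + Δt/5 s) growing with the time since the last
acceptance so a stale prior fades. The prior shapes **lag selection
only**; the gate always sees the unweighted profile, which the prior
would otherwise concentrate into passing.

An emitted interval is timestamped at the window center: the estimator
measures intervals, not fiducials — the mechanical modalities have no
QRS-locked landmark.

## Mixed-level fusion

QRS detections on the cECG are converted to intervals (midpoint
timestamps; values outside 333–2000 ms dropped). For each LIE emission
the nearest-in-time QRS interval within 1 s is its candidate; if
|Δr_QRS − Δr_LIE| < Δth (default 40 ms) the QRS value is emitted,
otherwise the LIE value. The rule swaps values but never adds or
removes emissions: coverage semantics stay with the gated LIE stream,
and QRS-only intervals are never emitted. Pairing is nearest-in-time
because both streams are quasi-periodic at ~1 Hz, making a 1-s window
unambiguous at rest; the sweep utility evaluates the full pipeline over
a Δth grid (Δth = 0 is the LIE-only limit, Δth → ∞ the QRS-only value
choice).

## Evaluation

Coverage is the emission count over the reference interval count, in
percent, computed as exact ratio arithmetic; values above 100 % are
possible with spurious emissions and are flagged, not clipped. Error is
the mean absolute difference over matched pairs; matching is one-to-one
nearest-in-time within 1 s, implemented by ranking all candidate pairs
globally by time distance (symmetric under time reversal). Correlations
are Pearson's r throughout. Moving-window curves use 12-s windows at a
1-s step; windows without a reference interval are skipped, windows
without a matched emission contribute coverage but no error.

## Synthetic sessions

The generator is the controlled counterfactual of the armchair
measurement: every quantity the analysis estimates has a known ground
truth.

**Beats.** RR[k] = mean_rr + sd_rr·ε_k + rsa_depth·sin(2π·f_resp·t_k),
ε_k i.i.d. standard normal. Defaults: mean_rr 900 ms, sd_rr 40 ms,
rsa_depth 30 ms, f_resp 0.25 Hz — a resting adult with ordinary
short-term variability and respiratory sinus arrhythmia.

**Waveforms.** Fixed analytic unit-phase templates per modality —
Gaussian Q/R/S/T complex for the ECG channels (R at phase 0.03), a
gamma-like single-lobe pulse for PPG (peak near phase 0.16), a damped
6-cycle sine for the BCG variants, one sinusoid period for the
impedance channels — stretched to each cycle's RR, delayed by the
modality's mechanical delay (0.15–0.25 s after the R-peak), amplitude
modulated by 1 + depth·sin(2π·f_resp·t), plus white Gaussian noise.
Analytic shapes keep the generator fully reproducible with no data
download; the SNRS and LIE machinery is deliberately shape-agnostic.

**Protocol.** 60 s rest, eight maneuvers at low amplitude in 30-s slots
(torso shifts left/right 50 mm, stand-up/sit-down, torso torsions,
head torsion, arm lifts), the same eight at high amplitude (100 mm
shifts), 60 s rest — 18 episodes, 600 s. Within a slot the displacement
follows a raised-cosine out-and-back profile over the first 8 s; the
rest of the slot is motionless and serves as the template window.
Marker displacement is idealized: exactly the instructed amplitude,
deterministic profile. Shifts move all markers in x; torsions move
trunk and arm markers in x and y with a small (0.15×) vertical shoulder
component; the head torsion moves only the head marker and arm lifts
only the respective arm marker, so those maneuvers leave the thorax
exactly still; stand-up/sit-down lifts all markers 400 mm in z.

**Artifacts.** Each chair sensor receives a disturbance with
instantaneous standard deviation gain · d(t) plus a deterministic
baseline shift 0.3 · gain · d(t), clipped to the sensor rails (±5 a.u.
against unit-amplitude signals), where d(t) is the axis-weighted thorax
displacement magnitude in mm. The coupling is directional per sensor
geometry: the backrest PPG suffers most from left-right shifts
(weights 1.5/0.4/0.3 in x/y/z), the seat-mat EMFi BCG responds to
vertical loading and is nearly immune to horizontal slides
(0.15/0.15/1.5), cECG and the optical BCG couple to any motion
(1/1/1 at the highest gains, 0.25 a.u./mm — triboelectric charge and
loss of optical contact), the impedance pair is split between y- and
x-dominant coupling. Gains were calibrated once so that the per-episode
SNRS–motion correlations land in a plausibly strong negative range and
no single modality survives every maneuver — the situation that makes
fusion worthwhile. Stand-up/sit-down forces rail saturation of all
chair sensors for the whole slot: the subject leaves the chair, and no
analysis window inside it is usable. The adhesive reference sensors are
left clean; they define the ground truth.

**Determinism.** One root seed is split into per-component child
streams (beat times, one render and one artifact stream per channel)
via `numpy.random.SeedSequence.spawn`, so any sub-computation is
reproducible in isolation and a full report bundle regenerates
byte-identically from (config, seed).

**What the generator does not emulate** — and hence what passing tests
do not establish about real recordings: real waveform morphology and
its inter-subject variability, ectopic beats and arrhythmia, gradual
posture drift and electrode-coupling changes between maneuvers,
nonlinearity of real artifact coupling beyond saturation, respiratory
influence on the impedance baseline, subject deviation from the
instructed amplitudes, and marker occlusion. Numbers obtained on
synthetic sessions (errors of ~20 ms, coverage near 99 % at rest)
characterize the implementation under these idealized conditions, not
expected field performance.

## Known limitations

* SNRS requires a reference segmentation; it cannot assess signal
  quality from unobtrusive channels alone, and irregular beats lower it
  even in clean signals.
* The LIE estimates a window-average interval. Against a beat-to-beat
  fluctuating reference, its error floor is set by the short-term HRV
  inside the 3-s window (tens of ms at the default HRV), which is why
  the QRS-anchored mixed fusion improves accuracy whenever the cECG is
  usable.
* The per-window error of the gated estimator on a single 10-min
  protocol session is a noisy statistic; motion-correlation analyses
  of it should be read with that sampling variance in mind.
* Session I/O covers the package's own directory format and a generic
  CSV bridge; native motion-capture or DAQ exports need external
  conversion.
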