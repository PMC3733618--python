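# Methods

`wavestate` re-implements, as a tested pipeline, the analysis chain used to
study how cortical traveling waves depend on global brain state under
urethane anesthesia: classification of synchronized vs desynchronized
states from field-potential RMS, laminar current source density (CSD) with
two state-specific event-triggering schemes, a temporospatial correlation
algorithm that extracts wave speed, direction and pattern class from an
optical detector array, and the circular/nonparametric statistics used to
compare the two states.  No raw recordings from the original study are
available, so a synthetic generator emulates the study conditions with
known ground truth; every downstream stage is validated as parameter
recovery against that ground truth.

Conventions: times in seconds, positions in mm, speeds in mm/s, angles in
radians in [0, 2π), frame and channel indices 0-based.

## State classification

The RMS of consecutive, non-overlapping 2 s segments of ECoG (or LFP) is
bimodal when the cortex alternates between a large-amplitude slow-wave
(synchronized) and a low-amplitude fast (desynchronized) regime.  The
criterion dividing the two regimes is the saddle point of a Gaussian-kernel
density estimate (Silverman bandwidth) of the RMS sample: the density
minimum between the two most prominent modes, with plateaus resolved at
their midpoint.  Modes must rise by at least 5% of the density maximum
above their surroundings; otherwise the distribution is declared unimodal
and an error is raised rather than an arbitrary split returned.  Segments
strictly above the criterion are labelled synchronized; ties go to
desynchronized.  Episodes are the run-length encoding of the labels.

Power spectra are averaged modified periodograms of Hamming-windowed 2 s
segments (zero overlap, 0.5 Hz resolution), normalized by the trapezoidal
integral of power over frequency so that densities integrate to one and are
comparable across recordings.

## Laminar CSD

The CSD is the negative second spatial difference of the depth LFP profile
(32 contacts, 50 µm pitch): `csd[z] = −(V[z−1] − 2V[z] + V[z+1]) / h²`,
with the end channels duplicated (Vaknin padding) so the output spans all
depths, an optional 3-point Hamming smoothing along depth, and output in
arbitrary units unless a conductivity is supplied.  Layer bands default to
contacts 1–10 (supragranular), 11–16 (granular) and 17–32 (infragranular)
in 1-based counting; the original layer boundaries were histological, so
the bands are configuration inputs.

Two triggering schemes define the events to average:

* **MUA persistence rule (synchronized state).**  Spikes pooled over all
  contacts are binned at 5 ms and integrated over a trailing 50 ms moving
  sum.  A trigger fires at the first bin whose integrated count exceeds the
  trailing-500 ms baseline mean by 3 SD and stays above that threshold for
  at least 500 ms; the threshold is frozen at the crossing bin for the
  persistence check (a rolling threshold would be contaminated by the up
  state itself), and the next trigger is allowed only after the count falls
  back below threshold.  The 50 ms integration window is a design choice:
  raw 5 ms Poisson counts fluctuate below any realistic threshold many
  times per second, so a persistence criterion on unintegrated bins never
  holds.
* **Hilbert zero-phase rule (desynchronized state).**  One LFP channel is
  band-passed 3–6 Hz (4th-order Butterworth, forward–backward so the phase
  is not delayed), the analytic-signal phase computed, and a trigger placed
  at every upward crossing of phase zero — the oscillation peaks, under the
  cosine convention.  Triggers within 1.5 s of either recording edge are
  dropped; the finite-length analytic signal is unreliable within a few
  cycles of the 3 Hz band edge.

Triggered averages use 1000 ms windows centered on each trigger (edge
triggers dropped and not counted).  AVREC traces are the mean absolute CSD
over depth; the supragranular fraction is the ratio of depth-summed,
time-integrated rectified CSD in the SG band to the same quantity over all
depths, within a 200 ms window centered on the trigger.  Summing (rather
than averaging) over depth makes the fraction a true share in [0, 1]:
with equal rectified mass in the three bands it equals 1/3 regardless of
band widths, and it reproduces the printed AVREC_SG/AVREC_total values.
It is invariant to sign flips and global gain.

## Temporospatial flow detection

The wave detector works on a hexagonal analysis patch — one detector plus
its six nearest neighbors (12 nearest-neighbor pairs) — of a photodiode
array sampled at 1600 Hz.  The signal is band-passed 0.5–35 Hz (zero
phase), and a 200 ms (320-frame) correlation window slides in 4-frame
steps.  Within each window, for every pair the lag maximizing the
normalized cross-correlation over ±25 ms (±40 frames) is found and refined
to sub-frame precision with a 3-point parabola through the correlation
peak; at 1600 Hz the raw lag quantization (0.625 ms) would otherwise be
~12% of the 5 ms neighbor lag of a 100 mm/s wave at 0.5 mm spacing.

A pair's lag is used only if it carries actual timing information:

* peak correlation ≥ 0.5 (`corr_min`) — uncorrelated noise peaks near 0.14
  for 320-frame windows, and without this cut random lag patterns clear the
  reliability threshold often enough to produce ~1 false event/s;
* peak-to-trough drop of the correlation function ≥ 0.15 (`sharp_min`) —
  smooth, slowly varying stretches (e.g. repolarization ramps) correlate
  near 1 at *every* shift, so their argmax is noise;
* |lag| not clipped at the ±25 ms search boundary;
* at least 10 of the 12 pairs surviving (`min_pairs`) — with only 4–6
  pairs, a 2-parameter template fit matches random lag vectors too easily
  (the cosine of a random k-vector onto a 2-D subspace is large with
  non-negligible probability);
* pooled window RMS ≥ 10% of the recording's maximum window RMS
  (`amp_min`) — normalized correlation is scale-free, so a faint image of
  a wave (zero-phase filter tails extend acausally ~1 s on either side of
  an event) would otherwise match templates perfectly.

The lag gradient g (s/mm) is fit by least squares over pair offsets.
Templates: translation = the uniform gradient itself (direction
`atan2(g_y, g_x)`, speed `1/‖g‖`); source = radial lag pattern about the
patch center; spiral = rotational pattern (azimuthal angle differences,
zero for pairs through the center).  By hexagonal symmetry the three
templates are mutually orthogonal on an ideal plane wave.  Reliability is
the cosine similarity (clipped to [0, 1]) between the observed pair-lag
vector and the best template's ideal lags — a reimplementation choice, as
the original reliability statistic is defined in software cited but not
reproduced in print; the 0.85 retention cut is applied to this quantity.
Least-squares aggregation was preferred over averaging pairwise velocities
because it is exact for plane waves and robust to a single bad pair.

Runs of above-threshold windows whose spans overlap (gaps < 200 ms) are
merged into one event at the reliability-maximal window (earliest on
ties).  Run segmentation always uses the 0.85 cut (or lower if the caller
asks for less), while `reliability_min` filters run peaks, so tightening
the threshold can only remove events, never split one into two.  Finally,
an event whose window amplitude is ≥2.5× weaker than another event within
0.6 s is discarded as a residual image of the same wave (temporal
non-maximum suppression); genuine neighboring waves have comparable
amplitudes.

`pairwise_lags` (the public single-window entry point) receives exactly one
320-frame window and computes shifted correlations on the overlapping parts
of the traces; the sliding path inside `detect_flow_events` has the full
traces available and shifts complete windows instead.  Both share the peak
search and parabolic refinement.

## Circular and nonparametric statistics

Rose histograms bin angles wrapped to [0, 2π) into 18 bins of 20° (the
original bin width is not stated) and are normalized to the maximum bin.

The two-sample Kuiper statistic is `V = sup(F̂₁−F̂₂) + sup(F̂₂−F̂₁)`
evaluated over the pooled sample points with ties grouped; this form is
invariant under a common rotation of both samples, which is the property
that makes it the circular analog of the Kolmogorov–Smirnov test.  The
p-value uses the asymptotic Kuiper tail series with Stephens' correction at
the effective sample size n₁n₂/(n₁+n₂) (p capped at 1 below λ = 0.4, where
the series is unstable); a label-permutation p-value (vectorized, add-one
estimator) is available as an oracle and agrees with the asymptotic one to
within ±0.01 at n₁ = n₂ = 100.  The statistic is discrete (steps of 1/n),
so the realized size of a nominal 5% test at n = 100 per group is ≈0.035 —
a property of the statistic, not of the approximation.

Per-recording median speeds are compared across states with the two-sided
Wilcoxon matched-pairs signed-rank test (scipy), exact for ≤25 non-zero
differences.

## Synthetic data generator

The generator is the package's stand-in for the in-vivo recordings and
defines the study conditions; its defaults are the values printed for the
original preparation wherever such values exist.

**Optical (VSD-like) sessions.**  Waves are plane waves crossing the
hexagonal array: every channel receives the same waveform rigidly delayed
by `(p − p_center)·û / v`.  Per-wave speeds follow a right-skewed
Gamma(shape 4) law — a qualitative match to the reported skewed speed
distributions — whose *median* is the state preset: 98 mm/s
(synchronized) and 118 mm/s (desynchronized).  The medians are pinned
because the printed speeds are means over animals of per-recording
medians; parameterizing the Gamma by its mean would place every recovered
median ~8% below the printed value by construction.  Directions are von
Mises (κ = 2 by default) with the desynchronized mean opposed 180° to the
synchronized one.  The synchronized waveform is an up-state front — a
half-sine rise whose duration is the 2 mm wavefront width divided by the
wave speed, followed by a 0.45 s decaying tail carrying a 25% ripple at
7 Hz (up states are not silent plateaus; a featureless ramp would carry no
timing information for the correlation stage) — recurring sparsely
(0.9–1.4 s gaps) at amplitude 1.  The desynchronized waveform is a 0.5 s,
two-cycle 4 Hz packet under a sin² envelope, recurring every 0.7–0.9 s at
amplitude 0.25, with multiplicative per-channel gain jitter (SD 0.3)
emulating the spatial fragmentation of the activated state; the packet
train gives the ~4 Hz spectral peak.  White detector noise (SD 0.02 a.u.)
is added.  Segment RMS of the two presets separates completely, and the
synchronized state carries most of its power below 3 Hz.  The detector
spacing is 0.5 mm — the inter-detector pitch is not printed anywhere and
is flagged as an assumption (it cancels out of speed recovery tests that
use the same geometry end to end).

**Laminar sessions.**  The ground-truth CSD is a fixed depth profile times
a temporal envelope.  The profile is built from three sink/source dipoles
with compact (cosine²) supports strictly inside the SG, G and IG bands;
each dipole sums to zero over depth exactly (current conservation) and the
SG dipole carries exactly `sg_fraction` of the total rectified current
(defaults 0.684 sync / 0.699 desync), the remainder split equally between
G and IG.  The temporal envelope is a train of 50 ms Gaussian transients
at up-state onsets (~0.8 Hz, jittered) in sync mode, or a continuous
4.25 Hz sinusoid in desync mode.  The LFP is produced by the declared
forward model — the exact discrete inverse of the second-difference CSD
estimator (`V[z+1] = 2V[z] − V[z−1] − h²C[z]`, depth mean removed) — so
the estimator recovers the interior ground truth to machine precision in
the noiseless limit, enabling closed-loop testing.  The CSD amplitude is
scaled so the LFP comes out ~0.5 mV RMS, with 5 µV white noise (~1%):
rectified-CSD integrals are biased upward by noise, and at this
signal-to-noise the bias after averaging tens of triggers is below 0.01 in
the recovered fraction.  MUA is Poisson: 0.5 Hz per contact between up
states and 20 Hz for 650 ms at each up state (sync), or sinusoidally
modulated at 4.25 Hz around 5 Hz (desync).

**ECoG.**  Alternating episodes of band-limited noise — 0.5–3 Hz at
200 µV RMS (synchronized) vs 3–6 Hz at 50 µV (desynchronized) over a 5 µV
broadband floor — with episode durations uniform in 10–60 s, a 12×
desk-scale stand-in for the minutes-long episodes seen in vivo.  Episode
durations are rounded to whole 2 s segments so every segment has a
well-defined true state and the trailing remainder is absorbed without
leaving the requested range.

**What the generator does not emulate.**  Optics and hemodynamic/heartbeat
artifacts; spike waveforms (only timestamps); non-planar wave geometry
(source/spiral events are classified but never generated, so their
recovery is tested only on constructed lag patterns); slow drifts of
anesthesia depth; inter-animal variability beyond seed-to-seed sampling.
Passing recovery tests therefore shows the analysis chain is correct and
well-conditioned at realistic signal-to-noise, not that it is robust to
every artifact of real optical recordings.

## Problem sizes

Recovery runs use 60 s optical sessions (nine per state, ~50 synchronized
or ~75 desynchronized waves each) and 60 s laminar sessions (ten per mode,
~38 up-state triggers or ~240 phase triggers each); unit tests use shorter
versions of the same conditions.  These sizes put the Monte Carlo error of
each recovered quantity well inside the tolerances asserted for it.

## Known limitations

* The reliability statistic is a reimplementation; absolute reliability
  values are not comparable to the original software, only the 0.85
  cut's behavior (retaining coherent plane waves, rejecting noise) is.
* The MUA baseline window ("the preceding bin window") and the exact layer
  boundaries are ambiguous in print; both are configuration inputs.
* Speed estimates inherit a small (<2%) low bias from lag noise entering
  the gradient norm nonlinearly.
* The Kuiper asymptotic p-value is accurate to ~±0.01 for effective sample
  sizes ≥ 50; use the permutation method below that.
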