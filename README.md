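# wavestate

State-dependent analysis of propagating cortical waves.

Under urethane anesthesia the cortex alternates between a synchronized
state (large-amplitude slow waves, < 3 Hz) and a desynchronized state
(low-amplitude activity with a ~4 Hz peak).  Spontaneous depolarization
waves travel laterally across the cortical surface in both states, but
their propagation is state-dependent: desynchronized waves run ~20% faster
and prefer the opposite direction along the dominant axis.  `wavestate`
implements the complete analysis chain behind such a comparison, for
anyone working with multichannel optical (voltage-sensitive dye) imaging,
laminar probe or ECoG recordings of cortical population activity:

* **State classification** — RMS of 2 s segments, saddle-point criterion
  on the bimodal RMS distribution, episode durations, and normalized
  Hamming-window power spectra.
* **Laminar CSD** — second-spatial-difference current source density
  `csd[z] = −(V[z−1] − 2V[z] + V[z+1])/h²` (Vaknin-padded), event triggers
  from a multi-unit persistence rule (3 SD above baseline, ≥ 500 ms) or
  from the zero crossing of the 3–6 Hz Hilbert phase, 1 s triggered
  averages, and AVREC (average rectified CSD) with the supragranular
  fraction AVREC_SG/AVREC_total.
* **Flow detection** — a temporospatial correlation algorithm: pairwise
  best-correlation lags (200 ms windows, ±25 ms shifts, sub-frame
  refinement) over a hexagonal detector ring, least-squares lag-gradient
  fit, template matching (translation / source / spiral), flow reliability
  with a 0.85 retention cut; translation events yield speed `1/‖g‖` and
  direction `atan2(g_y, g_x)`.
* **Circular statistics** — max-normalized rose histograms, a two-sample
  Kuiper test (rotation-invariant circular analog of the two-sample KS
  test), and the Wilcoxon matched-pairs signed-rank test for per-recording
  median speeds.
* **Synthetic two-state generator** — plane waves with Gamma-distributed
  speeds (median 98 mm/s synchronized, 118 mm/s desynchronized) and von
  Mises directions 180° apart; laminar sessions built from a ground-truth
  dipolar CSD through an exactly invertible forward model; bimodal ECoG.
  Every analysis stage is testable as parameter recovery with no external
  data.

## Worked example

```python
import numpy as np
from wavestate import gen_vsd_recording, detect_flow_events

for preset in ("sync", "desync"):
    rec, truth = gen_vsd_recording(preset, duration=60.0, seed=1)
    events = [e for e in detect_flow_events(rec) if e.pattern == "translation"]
    speeds = np.array([e.speed for e in events])
    print(preset, len(events), "events, median speed %.1f mm/s" % np.median(speeds))
```

prints

```
sync 51 events, median speed 97.4 mm/s
desync 72 events, median speed 110.3 mm/s
```

— the detector found essentially every injected wave (51 of 51 and 72 of
74) and recovered each session's median propagation speed to within a few
percent of the generator's ground truth (97.8 and 109.9 mm/s for these
seeds).  The scripts in `examples/` walk through each capability the same
way: `classify_brain_states.py` (saddle-point classification, 99% segment
accuracy), `laminar_avrec.py` (supragranular fraction 0.681/0.698 recovered
against presets 0.684/0.699), `detect_waves.py` (speeds and directions),
and `state_comparison_stats.py` (nine-session comparison: speed ratio 1.20,
Wilcoxon p = 0.0039, Kuiper p ≪ 0.001).

A thin CLI mirrors the library:

```sh
wavestate simulate --preset sync --duration 60 --seed 1 --out rec.h5
wavestate flow --in rec.h5 --out events.csv
wavestate stats --events events.csv --group-by state --out report.json
wavestate pipeline --out results/       # simulate -> classify -> flow -> stats
```

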