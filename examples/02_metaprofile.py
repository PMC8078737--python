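"""Oriented metaprofile with bootstrap band around simulated origins.

Simulates study-scale conditions (727 origin-bearing gene bodies, Poisson
background of 2 reads per 100-nt bin, 2-fold head-on enrichment in the case
sample), aggregates normalized signal over transcription-oriented 24 kb
windows, and prints the mean profile with a 95% bootstrap band at a few
offsets.  The case profile steps up on the HO (negative-offset) side of the
origin and returns to background on the CD side.
"""

import numpy as np

from dripmeta import (SimConfig, WindowSpec, aggregate, make_truth,
                      normalize_track, simulate_track, summarize_profile)

config = SimConfig(seed=11)          # defaults are the study-scale conditions
truth = make_truth(config)
origin = [r for r in truth.regions if r.region_class == "origin_in_gene_body"]

spec = WindowSpec()                  # 24 kb window, 100-nt bins
case = normalize_track(simulate_track(truth, "case", seed=1))
ctrl = normalize_track(simulate_track(truth, "control", seed=2))

for name, track in (("control", ctrl), ("case", case)):
    profile = aggregate(track, origin, spec)
    summary = summarize_profile(profile, "mean", n_boot=2_000, seed=5)
    print(f"\n{name} mean profile over {len(profile.region_ids)} regions "
          f"(value [95% band]):")
    for offset in (-9_000, -3_000, 3_000, 9_000):
        j = int(np.nonzero(profile.offsets == offset)[0][0])
        print(f"  offset {offset:+6d} bp: {summary.point[j]:6.2f} "
              f"[{summary.ci_low[j]:5.2f}, {summary.ci_high[j]:5.2f}]")

# Control sits near its normalized background everywhere; the case sample is
# elevated ~2-fold only at negative (head-on) offsets from the origin.
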