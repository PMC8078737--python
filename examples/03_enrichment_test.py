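"""Fisher-exact enrichment of a case sample over HO/CD sub-windows.

Builds study-scale synthetic data with a 2-fold head-on enrichment, forms
one contingency table per sub-window (rounded normalized in-window counts
against the remainder of each 10M-scaled library), and prints the
Bonferroni-adjusted Fisher p-values.  The head-on window is overwhelmingly
significant; the unenriched co-directional window is not — the asymmetry
expected when replication forks meet transcription head-on.
"""

from dripmeta import (SimConfig, WindowSpec, compare_samples, make_truth,
                      normalize_track, results_to_frame, simulate_track,
                      split_sub_windows)

config = SimConfig(seed=23)
truth = make_truth(config)
origin = [r for r in truth.regions if r.region_class == "origin_in_gene_body"]

case = normalize_track(simulate_track(truth, "case", seed=31))
ctrl = normalize_track(simulate_track(truth, "control", seed=32))
print(f"library sizes: case={case.library_size:,} control={ctrl.library_size:,}")

spec = WindowSpec()
subs = split_sub_windows(spec)
results = compare_samples({"case": case}, ctrl, origin,
                          [subs["full_quant"], subs["HO"], subs["CD"]], spec)
print(results_to_frame(results).to_string(index=False))

# window 'HO' carries the injected fold: odds ratio ~2, p_adj ~ 0.
# window 'CD' is unenriched: odds ratio ~1, p_adj large.
# m = 3 tests (one sample x three windows) enter the Bonferroni family.
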