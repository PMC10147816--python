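"""Simulate a resting-state cohort with planted network structure.

Builds the default 97-ROI atlas (45 bilateral pairs + 7 midline regions,
eight bilateral modules and two lateralized 15-ROI twin modules), simulates
33 subjects x 264 time points of latent-factor signals with AR(1) noise,
and prints what was planted.
"""

import numpy as np

import dogconn as dc

meta = dc.default_metadata(seed=1)
spec = dc.default_generator_spec(meta, seed=1)
cohort = dc.generate_timeseries(meta, spec)

print(f"ROIs: {len(meta)} ({len(meta.pairs())} bilateral pairs, "
      f"{len(meta.midline_names())} midline)")
print(f"subjects: {len(cohort)}, time points each: {cohort[0].n_timepoints}")

layer1 = dc.planted_layer1_labels(spec)
final = dc.planted_final_labels(spec)
print(f"planted first-layer modules: {len(set(layer1.values()))}")
print(f"planted final modules (after lateralized twins split): {len(set(final.values()))}")
print(f"planted hub pairs: {sorted(dc.planted_hub_pairs(spec, meta))}")

# the generator standardizes each ROI signal; bilateral homologs are coupled
left, right = meta.pairs()[0]
cols = {n: i for i, n in enumerate(cohort[0].roi_names)}
r = np.corrcoef(cohort[0].data[:, cols[left]], cohort[0].data[:, cols[right]])[0, 1]
print(f"sample correlation of homolog pair {left}/{right}: {r:.3f}")
print("(positive because pair members share a coupled latent factor)")
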