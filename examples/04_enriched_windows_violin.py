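"""Replication timing of enriched windows versus matched random controls.

Selects 50-kb windows with log2(ChIP/input) > 0 for a late-biased factor,
draws an equal number of random control windows, and compares the two RT
distributions with the two-sided Mann-Whitney rank-sum test — the
statistic behind violin-plot panels.
"""

import replimap as rm

grid, table, truth = rm.simulate_genome(rm.SimGenomeConfig(seed=1))
rt = table["rt"].to_numpy()

chip = rm.simulate_chip_counts(rt, rm.SimChipConfig(bias_beta=-1.0, seed=1))
inp = rm.simulate_chip_counts(rt, rm.SimChipConfig(bias_beta=0.0, seed=2))
enrichment = rm.compute_enrichment(rm.tpm_normalize(chip),
                                   rm.tpm_normalize(inp))
selected = rm.select_enriched_windows(enrichment)
controls = rm.sample_matched_controls(len(grid), len(selected), seed=1)

out = rm.violin_rt_summary(selected, controls, rt)
print(f"enriched windows:   n = {out['selected']['n']}, "
      f"median RT = {out['selected']['median']:+.3f} "
      f"(Q1 {out['selected']['q1']:+.3f}, Q3 {out['selected']['q3']:+.3f})")
print(f"random controls:    n = {out['controls']['n']}, "
      f"median RT = {out['controls']['median']:+.3f}")
print(f"Mann-Whitney U = {out['U']:.0f}, two-sided p = {out['p_value']:.3g}")
# A late-biased factor pulls the enriched-window RT median well below the
# control median (negative RT = late replication); p << 0.001.
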