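"""Simulate the default genome: blocky A/B compartments, an RT track that
follows the compartment sign, and histone-mark tag counts.

Prints the compartment fraction, the RT/compartment correlation and the
mark contrast — the structural features the downstream analyses rely on.
"""

import numpy as np

import replimap as rm
from replimap._util import pearson

cfg = rm.SimGenomeConfig(seed=1)
grid, table, truth = rm.simulate_genome(cfg)

a = truth.compartment == "A"
sign = np.where(a, 1.0, -1.0)
print(f"windows:                 {len(grid)} x {grid.width // 1000} kb")
print(f"A-compartment fraction:  {a.mean():.3f}")
print(f"corr(RT, compartment):   {pearson(table['rt'].to_numpy(), sign):.3f}")
print(f"H3K4me3 mean tags A/B:   {table['h3k4me3'][a].mean():.0f} / "
      f"{table['h3k4me3'][~a].mean():.0f}")
print(f"H3K9me3 mean tags A/B:   {table['h3k9me3'][a].mean():.0f} / "
      f"{table['h3k9me3'][~a].mean():.0f}")
# The RT/compartment correlation ~0.95 means early replication coincides
# with the A compartment, as it does genome-wide in real cells; the marks
# favour their compartment by the configured ~4-fold contrast.
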