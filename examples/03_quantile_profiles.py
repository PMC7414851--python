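"""Coverage of biased ChIP factors across 25 replication-timing quantiles.

Simulates an early-biased (DONSON-like) and a late-biased (FANCM-like)
factor, profiles their TPM coverage across RT quantiles (1 = latest,
25 = earliest) and prints the Spearman trend of quantile mean coverage.
"""

import replimap as rm

grid, table, truth = rm.simulate_genome(rm.SimGenomeConfig(seed=1))
rt = table["rt"].to_numpy()
labels = rm.assign_quantiles(rt, n=25)

for name, beta in [("early-biased factor", +1.0),
                   ("late-biased factor", -1.0),
                   ("unbiased input", 0.0)]:
    counts = rm.simulate_chip_counts(rt, rm.SimChipConfig(bias_beta=beta,
                                                          seed=1))
    tpm = rm.tpm_normalize(counts)
    profile = rm.quantile_coverage_profile(tpm, labels, scheme="rt",
                                           sample=name)
    rho, _ = rm.trend_statistic(profile)
    q1 = profile.summary["mean"].iloc[0]
    q25 = profile.summary["mean"].iloc[-1]
    print(f"{name:20s} trend rho = {rho:+.3f}   "
          f"mean TPM latest/earliest quantile = {q1:7.0f} / {q25:7.0f}")
# rho = +1 means coverage rises monotonically from late- toward
# early-replicating quantiles; the unbiased input shows no trend.
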