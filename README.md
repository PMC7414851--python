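# replimap

Replication-timing and chromatin-compartment profiling of replisome ChIP
enrichment, plus proximity-ligation-assay (PLA) foci-per-nucleus
quantification.

## The problem

Replisomes are not a homogeneous population: accessory factors can mark
subsets that run in different chromatin at different times in S phase — an
early-replicating, euchromatic subset (DONSON-like) and a late-replicating,
heterochromatic subset (FANCM-like). Two desk-side analyses expose such a
split:

1. **Genomic profiling.** The genome is divided into 50-kb windows. ChIP
   tag counts per window are scaled to tags per million
   (TPM<sub>i</sub> = c<sub>i</sub> / Σc × 10⁶), enrichment is
   e<sub>i</sub> = log₂((ChIP<sub>i</sub>+c)/(Input<sub>i</sub>+c)),
   and windows with e<sub>i</sub> > 0 are compared with size-matched random
   control windows through their replication-timing (RT = log₂(Early/Late))
   distributions (two-sided Mann–Whitney rank-sum test). Coverage is also
   profiled across *n* = 25 equal-count quantiles of RT or of the Hi-C A/B
   compartment eigenvector, ordered late→early (B→A); a Spearman ρ between
   quantile index and quantile mean coverage summarises the trend.
2. **Compartment eigenvector.** From a binned intra-chromosomal contact
   matrix: Knight–Ruiz balancing (equal row sums), observed/expected
   normalisation per genomic-distance diagonal, Pearson correlation of bin
   profiles, and the first principal component, whose sign — oriented so
   that positive correlates with early RT — assigns A (>0) and B (<0)
   compartments.
3. **PLA quantification.** Nuclei are segmented from the DAPI channel,
   diffraction-limited PLA foci detected with a size ceiling, assigned to
   the nucleus containing their centroid, and per-nucleus counts compared
   between conditions (Mann–Whitney; "significant" below p = 0.001, "NS"
   above p = 0.05). For sequential two-round PLA the rigid inter-round
   drift (dy, dx, angle) is estimated from the DAPI channel and focus
   overlap is scored against a within-nucleus permutation null.

A seeded synthetic-data module (`replimap.synthetic`) generates genomes
with blocky A/B compartments, RT tracks tied to compartment sign,
multinomially biased ChIP tag counts, distance-decaying checkered contact
matrices, and two-channel nucleus/foci images with Poisson focus counts —
all with persisted ground truth, so every stage is testable end to end
without external data.

## Worked example

```python
import replimap as rm

grid, table, truth = rm.simulate_genome(rm.SimGenomeConfig(seed=1))
rt = table["rt"].to_numpy()

counts = rm.simulate_chip_counts(rt, rm.SimChipConfig(bias_beta=1.0, seed=1))
tpm = rm.tpm_normalize(counts)
profile = rm.quantile_coverage_profile(tpm, rm.assign_quantiles(rt, 25))
rho, _ = rm.trend_statistic(profile)
print(rho)
```

prints `1.0`: an early-biased factor's coverage rises strictly
monotonically from the latest to the earliest RT quantile. The
`examples/` scripts walk through each capability; for instance
`python examples/05_pla_counting.py` prints

```
early : 60 nuclei, 228 foci counted (228 simulated), mean 3.80 per nucleus
late  : 60 nuclei, 58 foci counted (58 simulated), mean 0.97 per nucleus
fold ratio early/late = 3.93, U = 3240, p = 1.78e-14 -> significant
```

— every simulated focus is recovered and assigned to the right nucleus,
and the recovered ~4-fold early/late contrast matches the simulated
Poisson rates (λ = 4 vs 1), with the rank-sum comparison labelled
significant.

The same pipelines are reachable from the shell:

```bash
replimap demo --seed 1 --out demo_out        # simulate + both pipelines + report
replimap simulate --seed 1 --out sim/
replimap compartments --matrix sim/contacts.txt --rt sim/rt.bedgraph \
    --chrom-sizes sim/genome.chrom.sizes --out sim/ev.bedgraph
replimap pla-count --image early sim/pla_early.tiff --image late sim/pla_late.tiff \
    --out pla_out
```

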