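"""Escape frequency across mutation-burden buckets vs the simulated background.

Samples are split into 20 log10(TMB) buckets between the 1st and 99th
percentile; per bucket the escape frequency is bootstrapped, and 100
simulated-GIE iterations (same burden, random placement) give the background.
"""
from giescan import (
    CohortConfig, annotate_cohort, bucket_gie_frequency, generate_cohort,
    hg19_genome, load_gene_registry, overlay_simulated, run_simulations,
)

genome = hg19_genome()
registry = load_gene_registry()
bundle = generate_cohort(CohortConfig(
    n_samples=400, seed=2, gie_base_rate={1: 0.15}, gie_tmb_slope=1.5,
    focal_loh_rate=5.0,
))
events = annotate_cohort(bundle.samples, bundle.segments, bundle.mutations,
                         bundle.hla, registry, genome)
series = bucket_gie_frequency(bundle.samples, events, n_buckets=10,
                              n_boot=1000, seed=2)
simulated = run_simulations(bundle.samples, bundle.segments, bundle.mutations,
                            registry, genome, n_iter=50, seed=2)
series = overlay_simulated(series, simulated)

cols = ["bucket", "n", "freq", "boot_sd", "sim_mean", "sim_sd"]
print(series.table[cols].to_string(index=False))
# freq rising with the bucket index reflects the burden-linked injection; the
# gap between freq and sim_mean is escape beyond what random placement of the
# same alteration burden explains.
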