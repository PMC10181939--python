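"""Generate a small synthetic tumor cohort and look at its tables.

The generator draws purity, ploidy and mutation burden per sample, tiles every
autosome with allele-specific copy-number segments, and reports HLA-I allele
states with per-allele predicted-neoepitope counts. Everything is seeded.
"""
from giescan import CohortConfig, generate_cohort

config = CohortConfig(
    n_samples=20,
    seed=7,
    gie_base_rate={1: 0.3},    # inject HLA-I LOH in ~30% of samples
    allele_loss_beta=2.0,      # bias loss toward the higher-neoepitope allele
)
bundle = generate_cohort(config)

print(bundle.samples.head().to_string(index=False))
print(f"\n{len(bundle.segments)} copy-number segments, "
      f"{len(bundle.hla)} HLA gene states, "
      f"{len(bundle.truth)} ground-truth injections")
# Each samples row is one tumor: purity/ploidy condition CN calls, tmb is the
# genome-wide SNV+indel count, n_neoepitopes sums the per-allele repertoires.
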