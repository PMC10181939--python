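"""Call genetic immune escape (GIE) events and summarize pathway prevalence.

Six pathways are annotated over the 21-gene registry: HLA-I loss, antigen
presentation, IFN-gamma, PD-L1 amplification, CD58 and SETDB1.
"""
from giescan import (
    CohortConfig, annotate_cohort, generate_cohort, hg19_genome,
    load_gene_registry, prevalence, qc_filter,
)

genome = hg19_genome()
registry = load_gene_registry()
bundle = generate_cohort(CohortConfig(
    n_samples=120, seed=3, gie_base_rate={1: 0.2, 2: 0.05, 3: 0.05},
    focal_loh_rate=8.0,
))

kept, excluded = qc_filter(bundle.samples)  # purity >= 0.2, TMB >= 50
samples = bundle.samples[bundle.samples["sample_id"].isin(kept)]
events = annotate_cohort(samples, bundle.segments, bundle.mutations,
                         bundle.hla, registry, genome)
prev = prevalence(events, samples)

print(events["event_class"].value_counts().to_string())
print()
print(prev[["pathway", "numerator", "denominator", "proportion"]]
      .to_string(index=False))
# proportion = samples with >= 1 event in the pathway / cohort size; the "any"
# row is the overall escaped fraction (a sample counts once per pathway).
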