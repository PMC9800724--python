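"""Strand-resolved spectra and region densities: control vs coding region.

Annotates a simulated catalog and contrasts the mutation spectrum and
density of the control region (mtCTR) with the coding region (mtCDR) -
the comparison that motivates treating the control region as a
relaxed-selection compartment.
"""

from mtselect import (
    MitoGenomeModel,
    SyntheticConfig,
    annotate_catalog,
    classify_somatic,
    generate_cohort,
    mutation_density,
    spectrum_proportions,
)

model = MitoGenomeModel.bundled()
config = SyntheticConfig(n_samples=432, mean_mutations_per_sample=5.0, seed=7)
calls, _ = generate_cohort(config, model)
catalog, _ = classify_somatic(calls, config.n_samples, model)
annotate_catalog(catalog, model)

for region in ("mtCTR", "mtCDR"):
    d = mutation_density(catalog, region, model)
    print(f"{region}: {d.n_mutations} mutations over {d.length_bp} bp "
          f"-> {d.density:.4f} per sample per kb")
    table = spectrum_proportions(catalog, region, model)
    for cls, row in table.iterrows():
        print(f"    {cls:8s} {row['proportion']:.3f}")
print()
print("Heavy-strand C>T (forward G>A) dominates the coding region, the"
      "\nsignature of replication-coupled deamination of the displaced strand.")
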