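"""Relaxed and negative selection tests: HVS/non-HVS and tRNA stem/loop.

Simulates a cohort with tRNA loop mutations thinned to 0.4x and runs
the two goodness-of-fit style selection tests: the control-region
HVS/non-HVS split against its 27.54% length expectation (relaxed
selection leaves it at the expectation) and the tRNA stem-vs-loop
density comparison (negative selection depletes the loops).
"""

from mtselect import (
    MitoGenomeModel,
    SyntheticConfig,
    annotate_catalog,
    build_selection_report,
    classify_somatic,
    generate_cohort,
    hvs_nonhvs_analysis,
    replay_analysis,
    trna_stem_loop_analysis,
)

model = MitoGenomeModel.bundled()
config = SyntheticConfig(
    n_samples=432,
    mean_mutations_per_sample=6.0,
    seed=23,
    selection_multipliers={"tRNA-loop": 0.4},
)
calls, _ = generate_cohort(config, model)
catalog, _ = classify_somatic(calls, config.n_samples, model)
annotate_catalog(catalog, model)

hvs = hvs_nonhvs_analysis(catalog, model)
print(f"control region: {hvs['n_ctr_mutations']} mutations")
print(f"  observed non-HVS share {hvs['observed_nonhvs_pct']:.1f}% vs "
      f"expected {hvs['expected_nonhvs_pct']:.2f}% (chi2 p = {hvs['p']:.3f})")
print("  -> consistent with the length split: relaxed selection, no depletion")

trna = trna_stem_loop_analysis(catalog, model)
print(f"\ntRNA genes: {trna['n_trna_mutations']} mutations")
print(f"  stem density   {trna['stem_density']:.4f} /sample/kb")
print(f"  loop density   {trna['nonstem_density']:.4f} /sample/kb "
      f"(chi2 p = {trna['p']:.3g})")
dp = trna["deleterious_proportion"]
print(f"  deleterious proportion: stem {dp['stem']:.2f}, loop {dp['nonstem']:.2f}")

rec = replay_analysis(config, build_selection_report(catalog, model), model)
est = rec["trna_loop_multiplier"]
print(f"  composition-corrected loop multiplier estimate: {est['estimate']:.2f} "
      f"(95% CI {est['ci95'][0]:.2f}-{est['ci95'][1]:.2f}, truth 0.40)")
print("  -> the raw density ratio overstates the depletion (stems are G/C-rich"
      "\n     mutational targets); the corrected estimate recovers the 0.4x thinning")
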