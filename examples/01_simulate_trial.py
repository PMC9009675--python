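"""Draw a synthetic wheat drought trial and look at its structure.

The preset emulates an 18-genotype x 2-environment (irrigated control vs
drought) x 3-block trial with 12 agronomic/physiological/biochemical traits,
calibrated so per-trait heritabilities span the ~0.03-0.85 range reported
for this kind of experiment.
"""

from mgidi import preset_wheat_drought, simulate_met, summarize_design, trait_summary

config = preset_wheat_drought(seed=7)
data, truth = simulate_met(config)

design = summarize_design(data)
print(f"design: g={design.g} genotypes, e={design.e} environments, "
      f"b={design.b} blocks, n={design.n} plots, balanced={design.balanced}")

print("\nGrain yield (kg/ha) by environment — E1=control, E2=drought:")
print(trait_summary(data, "GY", by="environment").round(1).to_string(index=False))

print("\nProline (ug/g) by environment — the osmoprotectant surges under drought:")
print(trait_summary(data, "pc", by="environment").round(1).to_string(index=False))

print("\nTrue (drawn) genotype effects for the first 5 genotypes:")
print(truth.genotype_effects[["GY", "pc", "Na"]].head().round(2))
# Positive GY effects mark genetically higher-yielding lines; these are the
# quantities the REML/BLUP stage tries to recover from noisy plot data.
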