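"""Estimate heritability and litter effects with the pedigree animal model.

Simulates phenotypes with known genetic parameters (taxon h2 = 0.3, litter
fraction c2 = 0.05) on the four-generation study design under random mating,
then re-estimates them with AI-REML, including the enterotype label treated
as a 0/1 trait.
"""

from holosel import generate_study_phenotypes, heritability_binary, reml_fit

ped, data = generate_study_phenotypes(seed=42)
print(f"{len(data)} phenotyped animals, pedigree of {len(ped)} (incl. founders)\n")

for trait, truth in (("prevotella", 0.3), ("adg", 0.2)):
    fit = reml_fit(data, ped, trait)
    print(f"{trait:12s} h2 = {fit.h2:.3f} +/- {fit.se['h2']:.3f}  "
          f"c2 = {fit.c2:.3f}  (true h2 = {truth}, c2 = 0.05)")

binary = heritability_binary(data, ped, "enterotype01")
print(f"\nenterotype as a 0/1 trait: observed-scale h2 = {binary.h2:.3f}")
print(f"liability-scale conversion: {binary.extra['h2_liability']:.3f} "
      f"(prevalence {binary.extra['prevalence']:.2f})")
print("\nEstimates should bracket the generating values within ~2 SEs; the")
print("liability conversion rescales the observed-scale estimate to the")
print("underlying continuous-risk scale.")
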