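"""Extrapolating biases to small families via area-level resampling.

Large families give an area's Pr(bias) (Laplace rule of succession) and
Pr(deviation) (one minus the mean bias strength).  Small families are then
treated as survivors of larger unknown families: each replicate draws
whether they are biased, in which direction, and whether the survivors
deviate from it.  Means over 10,000 replicates estimate per-area counts.
"""

import famdrift as fd

# six large families, all biased against the trait, mean strength 0.9
large = [fd.BiasEstimate(f"L{i}", "set_binomial", fd.AGAINST, s, 0.01, 20,
                         area="Eurasia")
         for i, s in enumerate([0.85, 0.88, 0.90, 0.90, 0.92, 0.95])]
model = fd.estimate_area_model(large, "Eurasia")
print(f"Pr(bias) = ({model.n_large_biased}+1)/({model.n_large}+2) "
      f"= {model.pr_bias:.3f}")
print(f"mean strength = {model.mean_strength:.2f} "
      f"-> Pr(deviation) = {model.pr_deviation:.2f}")

# 30 isolates without the trait, 5 with it
smalls = []
for i in range(35):
    val = 1 if i < 5 else 0
    smalls.append(fd.FamilyDataset(
        family_id=f"iso{i}", taxonomy="autotyp", area="Eurasia",
        languages=[f"iso{i}-l0"], trials=[val],
        trials_by_language={f"iso{i}-l0": [val]}))

summary = fd.extrapolate(smalls, {"Eurasia": model}, n_reps=10_000, seed=42)
print(summary.mean.round(2).to_string())
print("standard errors:", summary.se.round(3).loc["Eurasia"].to_dict())
# counts of small families estimated biased against (A), towards (E), or
# showing no bias; rows always sum to the number of small families.
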