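"""Set-based bias detection within single families.

An exact binomial test asks whether a family's trial values (one per
grammatical subsystem per language) depart from a 50/50 split; a
significant majority is read as a directed bias in the family's history.
"""

import famdrift as fd

cases = {
    "9 trials, all without the marker": [0] * 9,
    "8 absent vs 2 present": [0] * 8 + [1] * 2,
    "perfectly balanced": [1] * 5 + [0] * 5,
    "12 present vs 1 absent": [1] * 12 + [0],
}
for label, trials in cases.items():
    est = fd.family_bias_binomial(trials)
    print(f"{label:35s} direction={est.direction:4s} "
          f"strength={est.strength:.2f} p={est.evidence:.4f}")
# direction A = biased against the marker, E = towards it, none = no signal;
# strength is the majority proportion, later reused as 1 - Pr(deviation).
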