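"""Predict population-replacement thresholds from measured components.

Uses the bundled fecundity means (adult offspring per vial at 25 C) and
4-fly mate-choice counts for the two engineered-incompatibility lines to
predict each line's replacement threshold: the engineered-genotype
frequency above which the drive spreads to fixation.  A fecundity ratio
F and an assortative-mating weight w1 put the threshold at 1/(1 + F*w1);
here it is located numerically as the zero crossing of the
per-generation frequency change.
"""

from egidrive import datasets, estimate_preferences, predict_threshold_from_components

for line in ("A3.7", "N17.1"):
    F = datasets.fecundity_ratio(line)
    w1 = estimate_preferences(datasets.MATE_CHOICE_TABLES[(line, "OregonR")])[0]
    fec_only = predict_threshold_from_components(F)
    both = predict_threshold_from_components(F, w1)
    mate_only = predict_threshold_from_components(1.0, w1)
    print(f"{line}: F = {F:.4f}, w1 = {w1:.4f}")
    print(f"  fecundity only        -> threshold {fec_only:.4f} ({100 * fec_only:.1f}%)")
    print(f"  fecundity + mate choice -> threshold {both:.4f} ({100 * both:.1f}%)")
    print(f"  mate choice only      -> threshold {mate_only:.4f} ({100 * mate_only:.1f}%)")

print()
print("A release above the threshold drives the engineered genotype to")
print("fixation; below it, the genotype is eliminated from the population.")
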