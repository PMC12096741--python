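"""Classify sample sources with molecular diagnostic ratios (MDR).

Isomer-pair ratios such as Flua/(Flua+Pyr) separate petrogenic from
combustion signatures sample by sample.
"""

from collections import Counter

from pahkit import SyntheticSpec, annual_fraction, classify, compute_ratios, \
    generate_samples

records, _, _ = generate_samples(SyntheticSpec(seed=1))
results = [classify(compute_ratios(r)) for r in records]

counts = Counter(r.classes["FluaPyr"] for r in results
                 if r.classes["FluaPyr"] is not None)
print("Flua/(Flua+Pyr) source classes across the campaign:")
for label, n in counts.most_common():
    print(f"  {label:35s} {n:4d} samples")

tab = annual_fraction(results, "AntPhe", "> 0.1")
print("\nShare of samples with Ant/(Ant+Phe) > 0.1 (combustion) per year:")
print(tab.to_string(index=False))
# Values near 100% indicate combustion-dominated emissions, consistent
# with the coal/biomass-heavy source mix the generator encodes.
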