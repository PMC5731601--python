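"""Compare predicted and true abundance profiles.

Evaluates how well read-count abundance profiles (fractions of classified
reads per taxon) recover the community composition, before and after
boosting, using the Pearson correlation over the union of taxa.
"""

from clior import (
    ClassifierSpec,
    CommunitySpec,
    abundance,
    boost,
    pearson_abundance,
    simulate_classifier,
    simulate_community,
)
from clior.synthetic import GenomeSpec

spec = CommunitySpec(
    genomes=[
        GenomeSpec(f"species_{chr(65 + i)}", f"genus_{chr(65 + i)}", 60_000)
        for i in range(4)
    ],
    abundances=[0.5, 0.25, 0.15, 0.1],
    n_reads=12_000,
    seed=5,
)
reads, truth, _ = simulate_community(spec)
base = simulate_classifier(truth, ClassifierSpec(dropout=0.6, mislabel=0.05, seed=6))
boosted = boost(reads, {"species": base}, seed=5).boosted["species"]

true_profile = abundance(truth)
for name, table in (("truth", truth), ("base", base), ("boosted", boosted)):
    profile = abundance(table)
    line = "  ".join(f"{t}={profile.proportions.get(t, 0):.3f}" for t in sorted(true_profile.proportions))
    r = pearson_abundance(profile, true_profile)
    print(f"{name:8s} r={r:.5f}  {line}")
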