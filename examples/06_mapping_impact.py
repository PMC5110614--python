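"""Quantify how the mapping genome changes differential-expression calls.

Compares adjusted p-values from reads mapped to the reference vs a
strain-specific genome: genes significant (p_adj <= 0.1) under only one
mapping are 'lost' or 'gained', and flagged 'borderline' when the
non-significant p-value sits within a factor of 2 of the cutoff.
"""

import numpy as np
import pandas as pd

from strainmosaic import compare_de_sets

rng = np.random.default_rng(4)
n = 1000
genes = [f"gene{i:04d}" for i in range(n)]
p_ref = rng.beta(0.4, 2.0, size=n)
is_pseudo = rng.random(n) < 0.05
# strain-genome mapping shifts a quarter of the p-values slightly;
# pseudogenes, which attract misplaced reads under the reference, shift
# strongly toward non-significance once reads map to the right genome
shift = (rng.random(n) < 0.25) | is_pseudo
factor = np.where(is_pseudo, rng.lognormal(1.5, 0.5, n),
                  rng.lognormal(0, 0.6, n))
p_strain = np.where(shift, np.clip(p_ref * factor, 0, 1), p_ref)
biotypes = pd.DataFrame({
    "gene": genes,
    "biotype": np.where(is_pseudo, "processed_pseudogene", "protein_coding"),
})

comparison, venn = compare_de_sets(
    pd.DataFrame({"gene": genes, "p_adj": p_ref}),
    pd.DataFrame({"gene": genes, "p_adj": p_strain}),
    alpha=0.1, borderline_factor=2.0, biotypes=biotypes)

print("DE Venn across mapping genomes "
      "(common + lost + gained + neither = tested):")
for k in ("common", "lost", "gained", "neither", "tested_both"):
    print(f"  {k:>12}: {venn[k]}")

flipped = comparison[comparison["de_status"].isin(["lost", "gained"])]
print(f"\n{len(flipped)} genes flip significance with the mapping genome; "
      f"{flipped['borderline'].mean():.0%} of those are borderline "
      f"(barely crossing the 0.1 cutoff).")
lost = comparison[comparison["de_status"] == "lost"]
print(f"pseudogenes among 'lost' genes: {lost['pseudogene'].sum()}/{len(lost)}"
      f" — significance driven by reference-mapping artifacts disappears"
      f"\nonce reads are aligned to the strain's own genome.")
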