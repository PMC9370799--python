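"""Cross-species GO-term abundance comparison with dual FDR control.

Simulates 11 species with 2,000 shared GO terms, 150 of which carry a
3-fold gene-count effect in 4 species, then runs the chi-square test of
proportions with Benjamini-Hochberg and Storey corrections and selects
terms passing q < 0.005 AND adjusted p < 0.01.
"""

import numpy as np

import annotkit as ak
from annotkit.synthetic_data import GoSimSpec, simulate_go_counts

matrix, effect_terms = simulate_go_counts(
    GoSimSpec(n_terms=2000, n_effect_terms=150, fold_change=3.0, seed=2)
)
tests = ak.test_terms(matrix)
sig = ak.select_significant(matrix, ak.SignificanceConfig(0.005, 0.01))

hits = {t.term for t in sig}
effects = set(effect_terms)
print(f"shared terms tested:   {len(tests)}")
print(f"significant terms:     {len(sig)} ({100*len(sig)/len(tests):.1f}%)")
print(f"planted effects found: {len(hits & effects)}/{len(effects)}")
print(f"false positives:       {len(hits - effects)}")

grouping = {
    sp: ("deciduous" if i < 5 else "evergreen")
    for i, sp in enumerate(matrix.species)
}
contrast = ak.group_contrast(sig[:3], matrix.species, grouping)
print("\nGroup medians (fraction of annotated genes) for 3 significant terms:")
print(contrast[["term", "deciduous_median", "evergreen_median"]].to_string(index=False))
print(
    "\nA term is called only when both FDR controls agree, so the "
    "false-positive count stays near zero even with 1,850 true nulls."
)
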