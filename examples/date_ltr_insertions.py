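"""Date LTR-retrotransposon insertions from 5'/3' LTR divergence.

Simulates a library of elements that inserted 3 million years ago, then
recovers their ages with the Jukes-Cantor chain: alignment identity ->
difference fraction p -> JC distance d -> age T = d/(2 mu).
"""

import numpy as np

import annotkit as ak
from annotkit.synthetic_data import LtrSimSpec, simulate_ltr_library

elements, truth = simulate_ltr_library(
    LtrSimSpec(n_elements=100, true_age_years=3e6, ltr_len_bp=1000, seed=1)
)
estimates = ak.date_library(elements, ak.JCParams(mu=1.57e-8))

strata = {el.element_id: el.superfamily for el in elements}
for summary in ak.summarize_ages(estimates, strata, bin_width_mya=0.5):
    print(
        f"{summary.stratum:>6}: n={summary.n:3d}  "
        f"mean={summary.mean_mya:.2f} MYA  median={summary.median_mya:.2f} MYA"
    )

ages = [e.t_mya for e in estimates if not e.saturated]
print(
    f"\nTrue age 3.00 MYA; recovered median {np.median(ages):.2f} MYA. "
    "Each element's two LTRs were identical at insertion, so their "
    "divergence, corrected for multiple hits, reads out the insertion time."
)
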