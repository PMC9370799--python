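# annotkit

Reusable analysis stages behind a draft-genome annotation, of the kind
produced for large, repeat-rich conifer genomes: dating LTR-retrotransposon
insertions, summarizing repeat landscapes without double-counting,
exhaustively scanning microsatellites, reporting gene-model structure and
repeat-overlap classes, and comparing GO-term gene abundance across
species with dual false-discovery-rate control. A synthetic-data module
generates inputs with recorded ground truth for every stage, so the whole
pipeline is testable without any downloads.

## Who it is for

Scientists annotating a plant (or other large) genome who have a FASTA
assembly, MAKER-style GFF3 gene models, RepeatMasker `.out` repeat
annotations, an LTR element library, and per-species GO count tables — and
want the bespoke downstream statistics as tested, importable functions
rather than one-off scripts.

## The core methods

**LTR insertion-time dating.** An LTR retrotransposon's two flanking long
terminal repeats are identical at insertion and diverge afterwards. From
the alignment identity of the 5′ and 3′ LTRs, with p = 1 − identity, the
Jukes–Cantor correction and molecular clock give

  d = −(3/4)·ln(1 − 4p/3),  T = d / (2μ),

with μ the substitution rate per site per year (default 1.57 × 10⁻⁸, a
conifer synonymous rate); the factor 2 reflects both copies diverging
simultaneously. Pairs at p ≥ 3/4 are saturated: they are excluded, not
clamped. Elements are stratified by superfamily (Copia = PR-INT-RT domain
order, Gypsy = PR-RT-INT) and by TG…CA flanking motif.

**Repeat landscape.** The naive repeat fraction sums feature lengths over
the genome length and double-counts overlapping/nested hits (it can exceed
100%); the union fraction merges intervals per sequence first and is the
true fraction of covered bases. Both are reported, with per-family tables
and length histograms.

**Microsatellites.** All maximal perfect tandem repeats of primitive 2–8
bp motifs with ≥ 5 complete copies (GMATo-style exhaustive scan), reported
once per locus at the primitive period, with per-motif tables and density
in loci per megabase.

**Gene statistics.** Counts and lengths of genes/exons/introns,
completeness classes from start/stop-codon flags, the AED < 0.5 quality
fraction, the intron share of the gene space, top-decile intron lengths,
and the "repeat-associated" call: ≥ 20% (inclusive) of a gene's CDS bases
covered by the union of repeats.

**GO comparison.** For terms shared by all species, a chi-square test of
equal proportions (genes with the term vs annotated genes, df = S − 1),
with Benjamini–Hochberg adjusted p-values and Storey q-values (smoother
π₀ estimate); a term is significant when q < 0.005 **and** adjusted
p < 0.01.

## Worked example

```python
import numpy as np
import annotkit as ak
from annotkit.synthetic_data import LtrSimSpec, simulate_ltr_library

elements, truth = simulate_ltr_library(
    LtrSimSpec(n_elements=100, true_age_years=3e6, ltr_len_bp=1000, seed=1)
)
estimates = ak.date_library(elements, ak.JCParams(mu=1.57e-8))
strata = {el.element_id: el.superfamily for el in elements}
for s in ak.summarize_ages(estimates, strata, bin_width_mya=0.5):
    print(f"{s.stratum:>6}: n={s.n:3d}  mean={s.mean_mya:.2f} MYA  "
          f"median={s.median_mya:.2f} MYA")
```

prints

```
 Copia: n= 55  mean=2.97 MYA  median=2.98 MYA
 Gypsy: n= 45  mean=3.01 MYA  median=3.02 MYA
   all: n=100  mean=2.99 MYA  median=2.98 MYA
```

One hundred elements were simulated as if inserted 3 million years ago
(each ancestral LTR copied twice, both copies mutated under the
Jukes–Cantor process); the dating chain recovers a median age of 2.98 MYA
— within sampling noise of the truth — and the two superfamily strata
agree, as they should when ages are drawn from the same distribution.

The `examples/` directory has one short script per capability
(`date_ltr_insertions.py`, `repeat_landscape.py`,
`scan_microsatellites.py`, `gene_model_report.py`,
`compare_go_terms.py`); each builds a small input, runs the method, and
explains the numbers it prints. A thin CLI mirrors the library:
`annotkit ltr-date`, `annotkit repeats`, `annotkit ssr`,
`annotkit gene-stats`, `annotkit go-compare`, `annotkit simulate`,
`annotkit validate`, `annotkit convert`.

## Scope

The package consumes standard annotation formats; it does not run the
upstream tools (RepeatMasker, MAKER, LTR detection, GO mapping) and does
not recompute AED or perform GO-graph propagation — counts and scores are
taken as provided.
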