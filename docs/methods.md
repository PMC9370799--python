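# Methods

This note records the models, conventions and numerical choices behind
annotkit, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; GFF3 and
RepeatMasker `.out` files (1-based inclusive) are converted at the parse
boundary only. When a gene carries several mRNAs, the representative
model is the mRNA with the longest summed CDS (ties broken by summed exon
length, then file order); per-gene statistics are therefore one-row-per-
gene regardless of isoform count. The `.out` parser accepts any header
lines that do not begin with a number, requires ≥ 11 columns on data
lines, and maps the complement flag `C` to the `-` strand. Sequences are
uppercased on read; non-ACGT letters are retained but never match in
alignments and break microsatellite runs. AED is read from `_AED`, `AED`
or `aed` attributes; completeness from explicit `has_start`/`has_stop`
flags — a model counts as full-length only when flagged, never by guess.

## LTR insertion-time dating

Model: both LTR copies of an element accumulate substitutions
independently after insertion, so the expected Jukes–Cantor distance
between them is 2μT. Given alignment identity, p = 1 − identity,
d = −(3/4)·ln(1 − 4p/3) and T = d/(2μ). The default
μ = 1.57 × 10⁻⁸ substitutions/site/year is a conifer synonymous rate;
halving μ doubles every age, so comparisons across strata are
rate-independent.

Identity is computed by global Needleman–Wunsch alignment with match +1,
mismatch −1, gap open −4, gap extend −1 and free terminal gaps, with
identity = matched columns / **all** alignment columns, terminal-gap
columns included. This choice is deliberate: for homologous pairs the
alignment spans both sequences and terminal gaps are negligible, while
pairs too diverged for the scoring scheme to support a full-length
alignment (expected per-column score turns negative near p ≈ 0.5)
collapse to a short overlap flanked by long free end gaps, driving
identity toward 0 and p into the saturation domain. Saturated estimates
(p ≥ 3/4, where the JC correction is undefined) are flagged and excluded
from all summaries rather than clamped — a deeply diverged pair is
reported as undatable, never as spuriously young. A local-alignment
(blastn-like) identity would give slightly different values for real
libraries; stratified medians are robust to this within roughly ±0.15
MYA.

Summaries report n, mean, median (mean of central pair for even n) and a
contiguous histogram from 0 MYA with 0.5-MYA bins per stratum, plus an
`all` stratum. Library ingestion pairs `*_5LTR`/`*_3LTR` FASTA records,
optionally annotated by a metadata TSV; unpaired records are an error
listing the offending ids. Merging a second library drops elements whose
5′ LTR matches an existing one at ≥ 90% identity over ≥ 90% of the
shorter sequence — a conventional redundancy threshold, recorded here
because no standard exists.

## Repeat landscape

Naive fraction = Σ feature lengths / total bp (can exceed 1; that is the
point — it quantifies double-counting). Union fraction merges intervals
per sequence by sort-and-sweep; adjacent intervals merge for coverage but
remain separate features in tables. Denominators are always explicit
(assembly vs read-set totals differ greatly in fragmented genomes), and
features on sequences without a stated length are an error rather than a
silent omission. Class/family split at the first `/`; a bare class is its
own family.

## Microsatellite scan

For each period k in 2..8 the scanner marks positions j with
s[j] = s[j+k] (both ACGT); a maximal stretch of marks is a periodic
region whose length determines the number of complete copies. A locus is
reported when the k-mer motif is primitive (not a repetition of a shorter
motif — longer-period aliases are skipped, so (AT)₈ is one dinucleotide
locus) and ≥ 5 complete copies fit; the interval is truncated to complete
copies and the start is leftmost (the periodicity extends neither side by
even one base). Motifs are canonicalized to the lexicographically
smallest rotation, optionally folding reverse complements. Mononucleotide
runs are excluded by default; compound or interrupted repeats are
separate loci. The 5-copy floor mirrors common GMATo usage and is
configurable; it is recorded in the CLI's output metadata because
reported locus counts are meaningless without it.

## Gene statistics

Per gene: introns are the gaps between sorted exons (count = exons − 1;
zero-length gaps produce no intron), and exon bp + intron bp equals the
exon-to-exon span. Completeness partitions genes into full-length /
5′-truncated / 3′-truncated / both. Mean CDS length is reported both
per gene (summed CDS) and per CDS segment, since both conventions appear
in annotation reports. The repeat-overlap call computes, per gene, the
CDS bases covered by the union of repeat intervals divided by total CDS
bp; ≥ 20% (boundary inclusive) marks the gene repeat-associated, and the
dominant family is the one covering the most CDS bp with lexicographic
tie-breaks. Genes with zero CDS bp get fraction 0 and an explicit flag.
An exon-footprint variant exists behind a flag but the CDS footprint is
the default.

## GO-term comparison

The k-sample test of proportions is the chi-square homogeneity test on
the S × 2 table (count, total − count) without continuity correction,
df = S − 1; identical proportions give statistic exactly 0. Terms with
any expected cell < 1 are flagged low-support but still returned.
Denominators are the per-species counts of gene models with at least one
GO term. BH adjustment is the standard step-up; Storey q-values use
π₀ estimated as #{p > λ}/((1 − λ)m) over λ = 0.05…0.95, smoothed with a
cubic smoothing spline and read off at the largest grid point, clipped to
(0, 1]; with fewer than 10 p-values π₀ falls back to 1 (making q
identical to BH), and a degenerate smoother falls back to the single
λ = 0.5 estimate. q-values are π₀-scaled BH with the step-up cumulative
minimum, so π₀ = 1 reduces exactly to BH. Significance requires both
q < 0.005 and BH-adjusted p < 0.01 (strict). The endpoint evaluation of
the smoother has non-trivial variance at m ≈ 5000 (sd ≈ 0.05 around a
true π₀ of 0.9); this is inherent to smoother-based π₀ estimation at
this scale and is why the q < 0.005 rule is paired with the BH rule. A
per-species-vs-rest z-test mode exists for sensitivity analysis
(smallest Bonferroni-adjusted p per term); the joint test is the
default. GO-graph propagation is not performed; counts are used as
provided.

## Synthetic data

The generators define the study conditions for every statistical claim
the tests make.

*LTR libraries*: one ancestral LTR per element (i.i.d. bases at GC
0.3541, TG…CA forced on a configurable fraction), two descendant copies
each evolved for T years at rate μ with a per-site Poisson number of
substitution events and uniform choice among the three alternatives —
back-substitutions included, so divergence saturates at 3/4 exactly as
the JC correction assumes. Defaults: 500 elements, 1-kb LTRs,
μ = 1.57 × 10⁻⁸. Parameter-recovery tests run at true ages 0.5/3/10 MYA
(recovered medians within 10%) and at 50 MYA, where divergence is beyond
what the alignment scoring supports and every element must be excluded
as saturated rather than mis-dated.

*Annotated genomes*: 5 × 100-kb sequences; ~40 genes with planted
exon/intron structure (1–5 exons, 90–300 bp exons, 60–600 bp introns)
written as GFF3 with AED and completeness attributes; repeat families
planted with controlled pairwise overlap and nesting so naive and union
coverage differ by a known amount (true union bp measured on an
independent per-base bitmask at generation time); SSR tracts planted at
~250 loci/Mbp into a background scrubbed of incidental perfect repeats by
rescanning, with one-period guard bases of a letter absent from the motif
so each tract is recovered at exactly its planted coordinates. Two
single-exon calibration genes receive repeat overlaps of exactly 60/300
and 59/300 CDS bp to pin the 20% boundary from both sides.

*GO matrices*: counts are binomial draws at per-term baseline proportions
log-uniform in [5 × 10⁻⁴, 5 × 10⁻³] with totals of 30,000 annotated genes
per species (11 species); effect terms multiply the proportion by a fold
change (default 3) in 4 affected species. Null simulations use 2,000
terms; planted-effect runs use 200 effect terms over 20 replicates.

What the generators do **not** emulate: real TE sequence composition,
indels in LTR divergence (substitution-only), overlapping genes or
alternative isoforms, GC heterogeneity, interrupted/compound SSRs, and
overdispersion of GO counts beyond binomial. Passing tests therefore
demonstrate correctness of the algorithms and calibration under these
models, not robustness to every property of real data; the alignment-
convention caveat above is the main known source of divergence from
values computed with local-alignment identities.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen to exercise
every code path with tight statistical bounds: 500 elements per age for
dating recovery, 1,000 random intervals on 100 kb for the coverage
oracle, 5,000 random 200-bp strings (a third of them low-entropy) for
scanner/oracle equality, 2,000-term GO matrices with 20 replicates for
FDR/power. All generators fan one seed out to fixed per-component child
streams (CRC-tagged), so every result is bit-reproducible under a given
seed. The empirical FDR of the dual-threshold GO selection sits at its
nominal bound by construction (the q-threshold is the quantity being
controlled), so measured values hover around 0.005 across seeds rather
than far below it.
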