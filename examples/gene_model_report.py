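"""Structural report card for a gene-model set, with repeat-overlap calls.

Simulates an annotated genome, writes GFF3 + RepeatMasker-style files,
reads them back, and summarizes: counts, exon/intron structure,
completeness classes, AED quality, and which genes are repeat-associated
(>= 20% of CDS bases covered by repeats).
"""

import tempfile
from pathlib import Path

import annotkit as ak
from annotkit.synthetic_data import GenomeSimSpec, simulate_annotated_genome

out = Path(tempfile.mkdtemp())
sim = simulate_annotated_genome(GenomeSimSpec(seed=5), out_dir=out)

models = ak.read_gff3(out / "genome.gff3")
repeats = ak.read_repeatmasker_out(out / "repeats.out")

s = ak.summarize_genes(models)
print(f"gene models:        {s.n_genes}")
print(f"exons / introns:    {s.n_exons} / {s.n_introns}")
print(f"mean exons/gene:    {s.mean_exons_per_gene:.2f} (mode {s.modal_exon_count})")
print(f"mean intron:        {s.mean_intron_len_bp:.1f} bp (max {s.max_intron_len_bp})")
print(f"full-length:        {s.n_full_length} of {s.n_genes}")
print(f"intron share of gene space: {100*s.intron_fraction_of_gene_space:.1f}%")
print(f"AED < 0.5:          {100*s.aed_below_cutoff_fraction:.1f}%")

calls = ak.repeat_overlap_classify(models, repeats, threshold=0.20)
assoc = [c for c in calls if c.is_repeat_associated]
print(f"repeat-associated genes (>=20% CDS overlap): {len(assoc)}")
for c in assoc:
    print(f"  {c.gene_id}: {100*c.overlap_fraction:.1f}% (dominant: {c.dominant_family})")

top = ak.top_fraction_introns(models, 0.10)
print(f"top-decile intron lengths: {top}")
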