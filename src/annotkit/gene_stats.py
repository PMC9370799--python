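"""Structural statistics of a gene-model set and repeat-overlap classification.

Covers the usual annotation report card — gene/exon/intron counts and
lengths, completeness classes, AED quality fraction, the intron share of
the gene space — plus the "repeat-associated" call: a gene whose CDS bases
are covered >= 20% (boundary inclusive) by the union of annotated repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenomicInterval, RepeatFeature
from .repeat_summary import merge_intervals

__all__ = [
    "GeneStatsSummary",
    "RepeatOverlapCall",
    "intron_intervals",
    "summarize_genes",
    "top_fraction_introns",
    "repeat_overlap_classify",
    "gene_space_fractions",
]


@dataclass(frozen=True)
class GeneStatsSummary:
    n_genes: int
    n_exons: int
    n_introns: int
    mean_gene_len_bp: float
    mean_exons_per_gene: float
    modal_exon_count: int
    mean_cds_len_bp: float  # summed CDS per gene
    mean_cds_segment_len_bp: float  # per CDS segment (the other convention)
    max_cds_len_bp: int
    mean_intron_len_bp: float
    max_intron_len_bp: int
    n_full_length: int
    n_trunc_5: int
    n_trunc_3: int
    n_trunc_both: int
    intron_total_bp: int
    intron_fraction_of_gene_space: float
    aed_below_cutoff_fraction: float


@dataclass(frozen=True)
class RepeatOverlapCall:
    gene_id: str
    overlap_fraction: float
    is_repeat_associated: bool
    dominant_family: str
    flagged_no_cds: bool = False


def intron_intervals(model: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; a single-exon gene has none.

    Exon bp + intron bp always reconstructs the exon-to-exon span.
    """
    exons = model.exons
    introns = []
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError(f"gene {model.gene_id}: overlapping exons")
        if b.start > a.end:
            introns.append(
                GenomicInterval(a.seq_id, a.end, b.start, a.strand)
            )
    return introns


def summarize_genes(
    models: Sequence[GeneModel], aed_cutoff: float = 0.5
) -> GeneStatsSummary:
    """Aggregate structural statistics over a gene-model set.

    Completeness: both codons -> full-length; missing start -> 5'
    truncated; missing stop -> 3' truncated; neither -> truncated both
    sides.  The AED fraction is taken over models that carry an AED.
    Adjacent (zero-gap) exons contribute no intron, so per gene
    n_introns <= n_exons - 1.
    """
    if not models:
        warnings.warn("no gene models; returning an all-zero summary")
        return GeneStatsSummary(*([0] * 3 + [0.0] * 3 + [0.0, 0.0, 0] + [0.0, 0]
                                  + [0] * 4 + [0, 0.0, 0.0]))
    gene_lens = []
    exon_counts = []
    intron_lens: list[int] = []
    cds_gene_lens = []
    cds_segment_lens: list[int] = []
    intron_bp = 0
    span_bp = 0
    n_full = n_t5 = n_t3 = n_both = 0
    aed_vals = []
    for m in models:
        gene_lens.append(m.span)
        exon_counts.append(len(m.exons))
        for iv in intron_intervals(m):
            intron_lens.append(iv.length)
        cds_gene_lens.append(m.cds_bp)
        cds_segment_lens.extend(iv.length for iv in m.cds)
        span_bp += m.span
        if m.has_start and m.has_stop:
            n_full += 1
        elif not m.has_start and m.has_stop:
            n_t5 += 1
        elif m.has_start and not m.has_stop:
            n_t3 += 1
        else:
            n_both += 1
        if m.aed is not None:
            aed_vals.append(m.aed)
    intron_bp = int(sum(intron_lens))
    counts = np.bincount(exon_counts)
    modal = int(np.argmax(counts))
    return GeneStatsSummary(
        n_genes=len(models),
        n_exons=int(sum(exon_counts)),
        n_introns=len(intron_lens),
        mean_gene_len_bp=float(np.mean(gene_lens)),
        mean_exons_per_gene=float(np.mean(exon_counts)),
        modal_exon_count=modal,
        mean_cds_len_bp=float(np.mean(cds_gene_lens)),
        mean_cds_segment_len_bp=float(np.mean(cds_segment_lens))
        if cds_segment_lens
        else 0.0,
        max_cds_len_bp=int(max(cds_gene_lens)),
        mean_intron_len_bp=float(np.mean(intron_lens)) if intron_lens else 0.0,
        max_intron_len_bp=int(max(intron_lens)) if intron_lens else 0,
        n_full_length=n_full,
        n_trunc_5=n_t5,
        n_trunc_3=n_t3,
        n_trunc_both=n_both,
        intron_total_bp=intron_bp,
        intron_fraction_of_gene_space=intron_bp / span_bp if span_bp else 0.0,
        aed_below_cutoff_fraction=(
            float(np.mean([a < aed_cutoff for a in aed_vals])) if aed_vals else 0.0
        ),
    )


def top_fraction_introns(
    models: Sequence[GeneModel], fraction: float = 0.10
) -> list[int]:
    """The ceil(fraction * n_introns) largest intron lengths, descending."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    lengths = []
    for m in models:
        lengths.extend(iv.length for iv in intron_intervals(m))
    if not lengths:
        return []
    k = int(np.ceil(fraction * len(lengths)))
    return sorted(lengths, reverse=True)[:k]


def repeat_overlap_classify(
    models: Sequence[GeneModel],
    repeats: Sequence[RepeatFeature],
    threshold: float = 0.20,
    on_exons: bool = False,
) -> list[RepeatOverlapCall]:
    """Classify genes as repeat-associated by CDS/repeat base overlap.

    overlap_fraction = (CDS bp covered by the union of repeat intervals) /
    total CDS bp, computed per gene; overlapping repeat hits count each
    base once.  A gene is repeat-associated when the fraction is >=
    ``threshold`` (boundary inclusive).  ``dominant_family`` is the repeat
    family covering the most CDS bp (ties broken lexicographically);
    ``on_exons`` switches the footprint from CDS to exons.
    """
    by_seq: dict[str, list[RepeatFeature]] = {}
    for r in repeats:
        by_seq.setdefault(r.interval.seq_id, []).append(r)
    calls = []
    for m in models:
        footprint = m.exons if on_exons else m.cds
        total = sum(iv.length for iv in footprint)
        seq_repeats = by_seq.get(m.interval.seq_id, [])
        if total == 0:
            calls.append(
                RepeatOverlapCall(m.gene_id, 0.0, False, "", flagged_no_cds=True)
            )
            continue
        # union of all repeats, restricted to the footprint
        merged_all = merge_intervals(
            (r.interval.start, r.interval.end) for r in seq_repeats
        )
        covered = _intersect_bp(footprint, merged_all)
        fraction = covered / total
        dominant = ""
        if covered > 0:
            per_family_bp: dict[str, int] = {}
            fams: dict[str, list[tuple[int, int]]] = {}
            for r in seq_repeats:
                fams.setdefault(r.family, []).append(
                    (r.interval.start, r.interval.end)
                )
            for fam, ivs in fams.items():
                bp = _intersect_bp(footprint, merge_intervals(ivs))
                if bp > 0:
                    per_family_bp[fam] = bp
            dominant = min(
                per_family_bp, key=lambda f: (-per_family_bp[f], f)
            )
        calls.append(
            RepeatOverlapCall(
                gene_id=m.gene_id,
                overlap_fraction=fraction,
                is_repeat_associated=fraction >= threshold,
                dominant_family=dominant,
            )
        )
    return calls


def _intersect_bp(
    footprint: Sequence[GenomicInterval], merged: Sequence[tuple[int, int]]
) -> int:
    """Base overlap between a set of disjoint footprint intervals and a
    merged (disjoint, sorted) interval list."""
    bp = 0
    for iv in footprint:
        for s, e in merged:
            if s >= iv.end:
                break
            lo = max(iv.start, s)
            hi = min(iv.end, e)
            if hi > lo:
                bp += hi - lo
    return bp


def gene_space_fractions(
    models: Sequence[GeneModel],
) -> tuple[int, int, float]:
    """(intron_bp, exon_bp, intron fraction of the gene space).

    Gene space = summed exon-to-exon spans of the representative models;
    exon and intron bp partition it, so the two fractions sum to 1.
    """
    intron_bp = 0
    exon_bp = 0
    for m in models:
        exon_bp += m.exon_bp
        intron_bp += sum(iv.length for iv in intron_intervals(m))
    space = intron_bp + exon_bp
    return intron_bp, exon_bp, (intron_bp / space if space else 0.0)
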