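"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_ltr_library` — LTR pairs diverged under the Jukes-Cantor
  substitution process for a known time at a known rate, so the dating
  chain can be checked by parameter recovery.
* :func:`simulate_annotated_genome` — a genome FASTA plus GFF3 gene
  models, a RepeatMasker-style ``.out`` with controlled overlap/nesting,
  and planted SSR tracts in an otherwise SSR-free background; every
  planted quantity is recorded as truth.
* :func:`simulate_go_counts` — binomial per-species GO count matrices
  with planted fold-change effects on chosen terms/species.

All generators are bit-reproducible under a fixed seed: one global seed
fans out to fixed per-component child streams.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    GenomicInterval,
    GeneModel,
    RepeatFeature,
    SequenceRecord,
    write_fasta,
    write_table,
)
from .go_compare import GoCountMatrix
from .ltr_dating import LtrElement
from .ssr_scan import SsrParams, find_ssrs

__all__ = [
    "LtrSimSpec",
    "GenomeSimSpec",
    "RepeatFamilySpec",
    "GoSimSpec",
    "simulate_ltr_library",
    "simulate_annotated_genome",
    "simulate_go_counts",
    "SimulatedGenome",
    "child_rng",
]

_BASES = np.array(list("ACGT"))
DEFAULT_GC = 0.3541  # larch-like genomic GC fraction


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-component stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


def _random_dna(rng: np.random.Generator, n: int, gc: float = DEFAULT_GC) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=probs))


# ---------------------------------------------------------------------------
# LTR library


@dataclass(frozen=True)
class LtrSimSpec:
    """Generative model for an LTR library of known insertion age.

    ``true_age_years`` may be a scalar (all elements that age) or a
    sequence of per-element ages.  ``superfamily_mix`` gives the (Copia,
    Gypsy) fractions; ``tgca_fraction`` the share of elements whose
    ancestral LTR is forced to start TG and end CA.
    """

    n_elements: int = 500
    true_age_years: float | Sequence[float] = 3.0e6
    mu: float = 1.57e-8
    ltr_len_bp: int = 1000
    internal_len_bp: int = 5000
    superfamily_mix: tuple = (0.5, 0.5)
    tgca_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_elements < 1 or self.ltr_len_bp < 4 or self.mu <= 0:
            raise ValueError("invalid LtrSimSpec")
        if abs(sum(self.superfamily_mix) - 1.0) > 1e-9:
            raise ValueError("superfamily_mix must sum to 1")
        if not (0 <= self.tgca_fraction <= 1):
            raise ValueError("tgca_fraction must be in [0, 1]")


def _jc_mutate(seq: str, rate_time: float, rng: np.random.Generator) -> str:
    """Evolve a sequence under JC69 for ``rate_time`` expected
    substitutions per site.

    Each site receives a Poisson number of substitution events, each
    replacing the base with one of the other three uniformly; back
    substitutions are therefore possible and divergence saturates at 3/4,
    matching the model the JC correction inverts.  After k events the base
    equals the original with probability 1/4 + (3/4)(-1/3)^k, which is
    sampled directly.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    k = rng.poisson(rate_time, size=len(seq))
    hit = np.nonzero(k > 0)[0]
    if hit.size == 0:
        return seq
    p_same = 0.25 + 0.75 * (-1.0 / 3.0) ** k[hit]
    stay = rng.random(hit.size) < p_same
    change = hit[~stay]
    if change.size:
        originals = arr[change]
        # uniform among the three alternatives
        base_idx = np.searchsorted(np.sort(_BASES.astype("S1")), originals)
        offsets = rng.integers(1, 4, size=change.size)
        sorted_bases = np.sort(_BASES.astype("S1"))
        arr[change] = sorted_bases[(base_idx + offsets) % 4]
    return arr.tobytes().decode()


def simulate_ltr_library(
    spec: LtrSimSpec,
) -> tuple[list[LtrElement], pd.DataFrame]:
    """Generate LTR elements plus a truth table of their true ages.

    Each element gets one ancestral LTR; its 5' and 3' copies evolve
    independently for ``true_age_years`` at rate ``mu``, so the expected
    pairwise JC distance is 2 * mu * T.
    """
    rng = child_rng(spec.seed, "ltr")
    ages = np.broadcast_to(
        np.asarray(spec.true_age_years, dtype=float), (spec.n_elements,)
    )
    elements = []
    truth_rows = []
    for i in range(spec.n_elements):
        ancestral = _random_dna(rng, spec.ltr_len_bp)
        is_tgca = rng.random() < spec.tgca_fraction
        if is_tgca:
            ancestral = "TG" + ancestral[2:-2] + "CA"
        rate_time = spec.mu * ages[i]
        ltr5 = _jc_mutate(ancestral, rate_time, rng)
        ltr3 = _jc_mutate(ancestral, rate_time, rng)
        superfamily = (
            "Copia" if rng.random() < spec.superfamily_mix[0] else "Gypsy"
        )
        domain_order = "PR-INT-RT" if superfamily == "Copia" else "PR-RT-INT"
        eid = f"ltr{i:05d}"
        elements.append(
            LtrElement(
                element_id=eid,
                ltr5=ltr5,
                ltr3=ltr3,
                domain_order=domain_order,
                superfamily=superfamily,
                flank_motif="TGCA" if is_tgca else "other",
                source="simulated",
            )
        )
        truth_rows.append(
            {
                "element_id": eid,
                "true_age_years": ages[i],
                "true_age_mya": ages[i] / 1e6,
                "superfamily": superfamily,
                "tgca": is_tgca,
            }
        )
    return elements, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# annotated genome


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family to plant: ``count`` features of ``length_bp``.

    ``overlap_fraction`` of the features are placed half-overlapping their
    predecessor; ``nesting_fraction`` are placed strictly inside it.  Both
    inflate naive coverage relative to union coverage by a known amount.
    """

    name: str
    repeat_class: str
    count: int
    length_bp: int
    overlap_fraction: float = 0.0
    nesting_fraction: float = 0.0


@dataclass(frozen=True)
class GenomeSimSpec:
    n_seqs: int = 5
    seq_len_bp: int = 100_000
    n_genes: int = 40
    exon_counts: tuple = (1, 2, 3, 4, 5)
    exon_count_weights: tuple = (0.1, 0.35, 0.25, 0.2, 0.1)
    exon_len_range: tuple = (90, 300)
    intron_len_range: tuple = (60, 600)
    full_length_fraction: float = 0.62
    aed_below_half_fraction: float = 0.95
    repeat_families: tuple = (
        RepeatFamilySpec("Gypsy-1", "LTR/Gypsy", 40, 900, 0.3, 0.1),
        RepeatFamilySpec("Copia-1", "LTR/Copia", 30, 700, 0.2, 0.1),
        RepeatFamilySpec("L1-1", "LINE/L1", 30, 500, 0.1, 0.0),
    )
    ssr_density_per_mbp: float = 250.0
    ssr_motifs: tuple = ("AC", "AT", "AAG", "AGAT")
    ssr_copies: int = 6
    gc: float = DEFAULT_GC
    overlap_calibration: tuple = (0.20, 59.0 / 300.0)
    seed: int = 0


@dataclass
class SimulatedGenome:
    records: list
    models: list
    repeats: list
    ssr_truth: pd.DataFrame
    stats_truth: dict
    calibration_truth: pd.DataFrame
    gff_text: str
    rm_out_text: str

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "genome.fa")
        (out / "genome.gff3").write_text(self.gff_text)
        (out / "repeats.out").write_text(self.rm_out_text)
        write_table(self.ssr_truth, out / "ssr_truth.tsv")
        write_table(pd.DataFrame([self.stats_truth]), out / "stats_truth.tsv")
        write_table(self.calibration_truth, out / "calibration_truth.tsv")
        with open(out / "genome.lengths.tsv", "w") as fh:
            for rec in self.records:
                fh.write(f"{rec.id}\t{len(rec.seq)}\n")


def _ssr_free_background(
    rng: np.random.Generator, n: int, gc: float, params: SsrParams
) -> str:
    """Random DNA with every perfect SSR (per ``params``) knocked out by
    point changes, re-scanned until clean."""
    seq = list(_random_dna(rng, n, gc))
    for _ in range(50):
        loci = find_ssrs(SequenceRecord(id="bg", seq="".join(seq)), params)
        if not loci:
            return "".join(seq)
        for locus in loci:
            mid = (locus.interval.start + locus.interval.end) // 2
            current = seq[mid]
            choices = [b for b in "ACGT" if b != current]
            seq[mid] = choices[rng.integers(0, 3)]
    raise RuntimeError("could not build an SSR-free background")


def simulate_annotated_genome(
    spec: GenomeSimSpec, out_dir=None
) -> SimulatedGenome:
    """Generate a genome with planted genes, repeats and SSRs plus truth.

    Genes are laid head-to-tail with gaps on the first sequences; exon
    coordinates, completeness flags and AED values are planted and
    recorded.  Repeat annotations are laid out with controlled pairwise
    overlap and nesting; true naive bp is the summed lengths and true
    union bp is measured on an independent per-base bitmask at generation
    time.  SSR tracts (with guard bases) are planted in an SSR-free
    background.  ``overlap_calibration`` plants single-exon calibration
    genes whose CDS is covered by a repeat at exactly the given fractions
    (default: one at the 0.20 classification boundary, one just below).
    """
    rng = child_rng(spec.seed, "genome")
    ssr_params = SsrParams()
    seq_ids = [f"scaf{i+1:03d}" for i in range(spec.n_seqs)]

    # --- background sequences, SSR-free then SSRs planted with guards
    sequences = {
        sid: list(_ssr_free_background(rng, spec.seq_len_bp, spec.gc, ssr_params))
        for sid in seq_ids
    }
    ssr_rows = []
    n_ssrs = int(round(spec.ssr_density_per_mbp * spec.n_seqs * spec.seq_len_bp / 1e6))
    slot = 0
    per_seq_cursor = {sid: 100 for sid in seq_ids}
    for i in range(n_ssrs):
        sid = seq_ids[slot % len(seq_ids)]
        slot += 1
        motif = spec.ssr_motifs[i % len(spec.ssr_motifs)]
        tract = motif * spec.ssr_copies
        start = per_seq_cursor[sid] + int(rng.integers(20, 120))
        end = start + len(tract)
        if end + len(motif) + 2 >= spec.seq_len_bp - 100:
            continue  # sequence full
        seq = sequences[sid]
        seq[start:end] = list(tract)
        # guard bases: a letter absent from the motif on both flanks, one
        # full period deep, so the tract can extend in neither direction
        guard = next(b for b in "CGTA" if b not in motif)
        k = len(motif)
        for off in range(1, k + 1):
            seq[start - off] = guard
            seq[end + off - 1] = guard
        per_seq_cursor[sid] = end + k + 20
        from .ssr_scan import canonical_motif

        ssr_rows.append(
            {
                "seq_id": sid,
                "start": start,
                "end": end,
                "motif": canonical_motif(motif),
                "motif_len": len(motif),
                "repeat_count": spec.ssr_copies,
            }
        )
    ssr_truth = pd.DataFrame(
        ssr_rows,
        columns=["seq_id", "start", "end", "motif", "motif_len", "repeat_count"],
    )

    # planting may create incidental perfect repeats at guard boundaries;
    # knock out any scan hit that is not a planted tract
    planted = {
        sid: [(r["start"], r["end"], r["motif_len"]) for r in ssr_rows
              if r["seq_id"] == sid]
        for sid in seq_ids
    }
    for sid in seq_ids:
        seq = sequences[sid]
        for _ in range(20):
            found = find_ssrs(SequenceRecord(id=sid, seq="".join(seq)), ssr_params)
            extras = [
                l
                for l in found
                if (l.interval.start, l.interval.end, l.motif_len)
                not in planted[sid]
            ]
            if not extras:
                break
            for l in extras:
                if any(
                    l.interval.start < e + ml and l.interval.end > s - ml
                    for s, e, ml in planted[sid]
                ):
                    raise RuntimeError(
                        "incidental SSR collides with a planted tract; "
                        "use a different seed or lower density"
                    )
                mid = (l.interval.start + l.interval.end) // 2
                seq[mid] = next(b for b in "ACGT" if b != seq[mid])
        else:
            raise RuntimeError("could not remove incidental SSR loci")

    # --- genes
    gff_lines = ["##gff-version 3"]
    models = []
    exon_total = 0
    intron_total_bp = 0
    intron_lens_all = []
    n_full = 0
    aed_below = 0
    cursor = {sid: 50 for sid in seq_ids}
    weights = np.asarray(spec.exon_count_weights) / sum(spec.exon_count_weights)
    for g in range(spec.n_genes):
        sid = seq_ids[g % len(seq_ids)]
        n_exons = int(rng.choice(spec.exon_counts, p=weights))
        exon_lens = rng.integers(
            spec.exon_len_range[0], spec.exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            spec.intron_len_range[0], spec.intron_len_range[1] + 1,
            size=max(0, n_exons - 1),
        )
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursor[sid]
        if start + span + 50 >= spec.seq_len_bp:
            raise ValueError(
                "infeasible packing: genes exceed sequence space; "
                "reduce n_genes or lengthen sequences"
            )
        gid = f"gene{g+1:05d}"
        exons = []
        pos = start
        for e in range(n_exons):
            exons.append(
                GenomicInterval(sid, pos, pos + int(exon_lens[e]), "+")
            )
            pos += int(exon_lens[e])
            if e < n_exons - 1:
                pos += int(intron_lens[e])
        cursor[sid] = pos + int(rng.integers(80, 400))
        full = bool(rng.random() < spec.full_length_fraction)
        # round to the 4 decimals the GFF carries, keeping the draw on the
        # intended side of the 0.5 quality cutoff
        if rng.random() < spec.aed_below_half_fraction:
            aed = round(float(rng.uniform(0.0, 0.4999)), 4)
        else:
            aed = round(float(rng.uniform(0.5, 0.9999)), 4)
        models.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(sid, start, pos, "+"),
                exons=tuple(exons),
                cds=tuple(exons),
                aed=aed,
                has_start=full,
                has_stop=full,
            )
        )
        exon_total += n_exons
        intron_total_bp += int(intron_lens.sum())
        intron_lens_all.extend(int(x) for x in intron_lens)
        n_full += int(full)
        aed_below += int(aed < 0.5)
        mid = f"{gid}.mRNA1"
        gff_lines.append(
            f"{sid}\tsim\tgene\t{start+1}\t{pos}\t.\t+\t.\tID={gid}"
        )
        flag = "1" if full else "0"
        gff_lines.append(
            f"{sid}\tsim\tmRNA\t{start+1}\t{pos}\t.\t+\t.\t"
            f"ID={mid};Parent={gid};_AED={aed:.4f};has_start={flag};has_stop={flag}"
        )
        for e, iv in enumerate(exons):
            gff_lines.append(
                f"{sid}\tsim\texon\t{iv.start+1}\t{iv.end}\t.\t+\t.\t"
                f"ID={mid}.exon{e+1};Parent={mid}"
            )
            gff_lines.append(
                f"{sid}\tsim\tCDS\t{iv.start+1}\t{iv.end}\t.\t+\t0\t"
                f"ID={mid}.cds;Parent={mid}"
            )

    # --- calibration genes with exact repeat-overlap fractions
    calib_repeats = []
    calib_truth = []
    for ci, frac in enumerate(spec.overlap_calibration):
        sid = seq_ids[ci % len(seq_ids)]
        cds_len = 300
        start = cursor[sid] + 100
        if start + cds_len + 50 >= spec.seq_len_bp:
            raise ValueError("infeasible packing for calibration genes")
        gid = f"calib{ci+1:03d}"
        iv = GenomicInterval(sid, start, start + cds_len, "+")
        models.append(
            GeneModel(
                gene_id=gid,
                interval=iv,
                exons=(iv,),
                cds=(iv,),
                aed=0.1,
                has_start=True,
                has_stop=True,
            )
        )
        exon_total += 1
        aed_below += 1
        n_full += 1
        mid = f"{gid}.mRNA1"
        gff_lines.append(
            f"{sid}\tsim\tgene\t{start+1}\t{start+cds_len}\t.\t+\t.\tID={gid}"
        )
        gff_lines.append(
            f"{sid}\tsim\tmRNA\t{start+1}\t{start+cds_len}\t.\t+\t.\t"
            f"ID={mid};Parent={gid};_AED=0.1000;has_start=1;has_stop=1"
        )
        gff_lines.append(
            f"{sid}\tsim\texon\t{start+1}\t{start+cds_len}\t.\t+\t.\t"
            f"ID={mid}.exon1;Parent={mid}"
        )
        gff_lines.append(
            f"{sid}\tsim\tCDS\t{start+1}\t{start+cds_len}\t.\t+\t0\t"
            f"ID={mid}.cds;Parent={mid}"
        )
        overlap_bp = int(round(frac * cds_len))
        calib_repeats.append(
            RepeatFeature(
                interval=GenomicInterval(sid, start, start + overlap_bp, "+"),
                repeat_name="CalibRep",
                repeat_class="LTR/Gypsy",
                percent_divergence=10.0,
                score=1000.0,
            )
        )
        calib_truth.append(
            {
                "gene_id": gid,
                "overlap_fraction": overlap_bp / cds_len,
                "is_repeat_associated": overlap_bp / cds_len >= 0.20,
            }
        )
        cursor[sid] = start + cds_len + 100

    # --- repeats with controlled overlap and nesting (kept clear of genes)
    repeats = list(calib_repeats)
    masks = {sid: np.zeros(spec.seq_len_bp, dtype=bool) for sid in seq_ids}
    for r in calib_repeats:
        masks[r.interval.seq_id][r.interval.start : r.interval.end] = True
    rep_cursor = {sid: cursor[sid] + 200 for sid in seq_ids}
    slot = 0
    for fam in spec.repeat_families:
        prev_by_seq: dict[str, RepeatFeature] = {}
        for i in range(fam.count):
            sid = seq_ids[slot % len(seq_ids)]
            slot += 1
            u = rng.random()
            prev = prev_by_seq.get(sid)
            if prev is not None:
                if u < fam.nesting_fraction and prev.length > fam.length_bp // 2 + 2:
                    start = prev.interval.start + 1
                    length = min(fam.length_bp // 2, prev.length - 2)
                    iv = GenomicInterval(sid, start, start + length, "+")
                    repeats.append(_mk_repeat(fam, iv, i))
                    masks[sid][iv.start : iv.end] = True
                    continue
                if u < fam.nesting_fraction + fam.overlap_fraction:
                    start = prev.interval.start + prev.length // 2
                    end = start + fam.length_bp
                    if end < spec.seq_len_bp:
                        iv = GenomicInterval(sid, start, end, "+")
                        r = _mk_repeat(fam, iv, i)
                        repeats.append(r)
                        masks[sid][iv.start : iv.end] = True
                        prev_by_seq[sid] = r
                        rep_cursor[sid] = max(rep_cursor[sid], end + 30)
                        continue
            start = rep_cursor[sid]
            end = start + fam.length_bp
            if end + 10 >= spec.seq_len_bp:
                raise ValueError(
                    "infeasible packing: repeats exceed sequence space"
                )
            iv = GenomicInterval(sid, start, end, "+")
            r = _mk_repeat(fam, iv, i)
            repeats.append(r)
            masks[sid][iv.start : iv.end] = True
            rep_cursor[sid] = end + int(rng.integers(30, 120))
            prev_by_seq[sid] = r

    naive_bp = sum(r.length for r in repeats)
    union_bp = int(sum(int(m.sum()) for m in masks.values()))
    genome_bp = spec.n_seqs * spec.seq_len_bp

    # --- RepeatMasker .out text
    rm_lines = [
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat",
        "score   div. del. ins.  sequence   begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID",
        "",
    ]
    for i, r in enumerate(repeats, start=1):
        iv = r.interval
        left = spec.seq_len_bp - iv.end
        rm_lines.append(
            f"{r.score:7.0f} {r.percent_divergence:5.1f}  0.0  0.0  {iv.seq_id}"
            f"  {iv.start+1}  {iv.end}  ({left})  +  {r.repeat_name}"
            f"  {r.repeat_class}  1  {iv.length}  (0)  {i}"
        )

    intron_fraction = (
        intron_total_bp / (intron_total_bp + sum(m.exon_bp for m in models))
    )
    stats_truth = {
        "n_genes": len(models),
        "n_exons": exon_total,
        "n_introns": len(intron_lens_all),
        "n_full_length": n_full,
        "n_trunc_both": len(models) - n_full,
        "mean_intron_len_bp": (
            float(np.mean(intron_lens_all)) if intron_lens_all else 0.0
        ),
        "max_intron_len_bp": max(intron_lens_all) if intron_lens_all else 0,
        "intron_total_bp": intron_total_bp,
        "intron_fraction_of_gene_space": intron_fraction,
        "aed_below_half_fraction": aed_below / len(models),
        "n_ssr_loci": len(ssr_truth),
        "naive_repeat_bp": naive_bp,
        "union_repeat_bp": union_bp,
        "genome_bp": genome_bp,
        "naive_repeat_fraction": naive_bp / genome_bp,
        "union_repeat_fraction": union_bp / genome_bp,
        "n_repeat_features": len(repeats),
    }
    sim = SimulatedGenome(
        records=[
            SequenceRecord(id=sid, seq="".join(sequences[sid])) for sid in seq_ids
        ],
        models=models,
        repeats=repeats,
        ssr_truth=ssr_truth,
        stats_truth=stats_truth,
        calibration_truth=pd.DataFrame(
            calib_truth,
            columns=["gene_id", "overlap_fraction", "is_repeat_associated"],
        ),
        gff_text="\n".join(gff_lines) + "\n",
        rm_out_text="\n".join(rm_lines) + "\n",
    )
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def _mk_repeat(fam: RepeatFamilySpec, iv: GenomicInterval, i: int) -> RepeatFeature:
    return RepeatFeature(
        interval=iv,
        repeat_name=f"{fam.name}#{i+1}",
        repeat_class=fam.repeat_class,
        percent_divergence=15.0,
        score=500.0,
    )


# ---------------------------------------------------------------------------
# GO count matrices


@dataclass(frozen=True)
class GoSimSpec:
    """Binomial GO-count generator with planted between-species effects.

    Baseline per-term proportions are log-uniform between
    ``baseline_range``; each of ``n_effect_terms`` terms has its
    proportion multiplied by ``fold_change`` in ``n_affected_species``
    species.
    """

    n_species: int = 11
    n_terms: int = 2000
    total_per_species: int = 30_000
    baseline_range: tuple = (5e-4, 5e-3)
    n_effect_terms: int = 0
    fold_change: float = 3.0
    n_affected_species: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.n_terms < 1:
            raise ValueError("invalid GoSimSpec")
        lo, hi = self.baseline_range
        if not (0 < lo <= hi < 1):
            raise ValueError("baseline_range must lie in (0, 1)")
        if hi * self.fold_change >= 1:
            raise ValueError("baseline proportion x fold_change must stay < 1")
        if self.n_effect_terms > self.n_terms:
            raise ValueError("more effect terms than terms")


def simulate_go_counts(
    spec: GoSimSpec,
) -> tuple[GoCountMatrix, list[str]]:
    """Draw a GO count matrix; returns (matrix, planted effect-term ids)."""
    rng = child_rng(spec.seed, "go")
    species = tuple(f"sp{i+1:02d}" for i in range(spec.n_species))
    terms = tuple(f"GO:{i:07d}" for i in range(1, spec.n_terms + 1))
    lo, hi = spec.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_terms))
    probs = np.tile(baseline, (spec.n_species, 1))
    effect_idx = rng.choice(
        spec.n_terms, size=spec.n_effect_terms, replace=False
    )
    for j in effect_idx:
        affected = rng.choice(
            spec.n_species, size=spec.n_affected_species, replace=False
        )
        probs[affected, j] *= spec.fold_change
    counts = rng.binomial(spec.total_per_species, probs)
    totals = np.full(spec.n_species, spec.total_per_species, dtype=np.int64)
    matrix = GoCountMatrix(species, terms, counts, totals)
    return matrix, [terms[j] for j in sorted(effect_idx)]
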