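"""Exhaustive perfect-microsatellite (SSR) detection.

Finds every maximal perfect tandem run of a primitive 2-8 bp motif with at
least ``min_repeats`` complete copies — the GMATo-style exhaustive scan, as
opposed to TRF's probabilistic alignment model.  A run is reported exactly
once, at its primitive period ((AT)8 is one dinucleotide locus, never a
tetranucleotide "ATAT" locus) and at its leftmost start; a trailing partial
copy truncates the reported interval to complete copies.  Non-ACGT
characters break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import GenomicInterval, SequenceRecord

__all__ = [
    "SsrParams",
    "SsrLocus",
    "canonical_motif",
    "is_primitive",
    "find_ssrs",
    "scan_records",
    "ssr_density",
    "ssr_motif_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SsrParams:
    """Scan parameters: motif length range and minimum complete copies."""

    min_motif: int = 2
    max_motif: int = 8
    min_repeats: int = 5
    fold_revcomp: bool = False

    def __post_init__(self):
        if not (1 <= self.min_motif <= self.max_motif):
            raise ValueError("require 1 <= min_motif <= max_motif")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")


@dataclass(frozen=True)
class SsrLocus:
    """A maximal perfect tandem repeat: ``interval`` spans exactly
    ``repeat_count`` complete copies; ``motif`` is the canonical
    (lexicographically smallest rotation) primitive motif."""

    seq_id: str
    interval: GenomicInterval
    motif: str
    motif_len: int
    repeat_count: int


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter one."""
    n = len(motif)
    for period in range(1, n):
        if n % period == 0 and motif == motif[:period] * (n // period):
            return False
    return True


def canonical_motif(motif: str, fold_revcomp: bool = False) -> str:
    """Lexicographically smallest rotation of the motif.

    With ``fold_revcomp``, rotations of the reverse complement compete too,
    so a motif and its opposite-strand reading share one canonical form.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    if fold_revcomp:
        rc = motif.translate(_COMPLEMENT)[::-1]
        candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def find_ssrs(
    record: SequenceRecord | str, params: SsrParams = SsrParams()
) -> list[SsrLocus]:
    """All maximal perfect tandem repeats in one sequence.

    For each period k the scan marks positions j where s[j] == s[j+k] (both
    ACGT); a maximal stretch of L marks starting at i is a periodic region
    of length L+k whose motif is s[i:i+k].  The region yields a locus when
    the motif is primitive (longer-period aliases of a shorter repeat are
    skipped) and (L+k)//k complete copies meet ``min_repeats``.  Maximality
    is per-base: the periodicity extends neither left nor right by a single
    position, which also makes the reported start leftmost.
    """
    if isinstance(record, str):
        record = SequenceRecord(id="seq", seq=record) if record else None
        if record is None:
            return []
    s = record.seq
    n = len(s)
    loci: list[SsrLocus] = []
    acgt = [c in "ACGT" for c in s]
    for k in range(params.min_motif, params.max_motif + 1):
        min_region = params.min_repeats * k
        j = 0
        limit = n - k
        while j < limit:
            if s[j] == s[j + k] and acgt[j]:
                run_start = j
                while j < limit and s[j] == s[j + k] and acgt[j]:
                    j += 1
                region_len = (j - run_start) + k  # periodic span
                copies = region_len // k
                if region_len >= min_region:
                    motif = s[run_start : run_start + k]
                    if is_primitive(motif):
                        loci.append(
                            SsrLocus(
                                seq_id=record.id,
                                interval=GenomicInterval(
                                    record.id, run_start, run_start + copies * k
                                ),
                                motif=canonical_motif(
                                    motif, fold_revcomp=params.fold_revcomp
                                ),
                                motif_len=k,
                                repeat_count=copies,
                            )
                        )
            else:
                j += 1
    loci.sort(key=lambda l: (l.interval.start, l.motif_len))
    return loci


def scan_records(
    records: Iterable[SequenceRecord], params: SsrParams = SsrParams()
) -> list[SsrLocus]:
    out: list[SsrLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, params))
    return out


def ssr_density(loci: Sequence[SsrLocus], total_bp: int) -> float:
    """Loci per megabase: count * 1e6 / total_bp."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    return len(loci) * 1e6 / total_bp


def ssr_motif_table(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """Counts and total bp per (motif_len, canonical motif), most common first."""
    agg: dict[tuple[int, str], list[int]] = {}
    for locus in loci:
        key = (locus.motif_len, locus.motif)
        if key not in agg:
            agg[key] = [0, 0]
        agg[key][0] += 1
        agg[key][1] += locus.interval.length
    rows = [
        {"motif_len": k, "motif": m, "count": c, "total_bp": bp}
        for (k, m), (c, bp) in agg.items()
    ]
    df = pd.DataFrame(rows, columns=["motif_len", "motif", "count", "total_bp"])
    if len(df):
        df = df.sort_values(
            ["count", "motif_len", "motif"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
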