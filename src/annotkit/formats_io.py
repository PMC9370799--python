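"""Readers and writers for the standard annotation formats, plus the shared
genomic-interval model.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GFF3 and RepeatMasker ``.out`` files are 1-based inclusive on disk; the
conversion happens here, at the parse/write boundary, and nowhere else.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomicInterval",
    "RepeatFeature",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_repeatmasker_out",
    "read_seq_lengths",
    "write_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence. ``seq`` is uppercased on construction."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker-style repeat annotation.

    ``repeat_class`` is the raw class/family column (e.g. ``LTR/Gypsy``);
    ``class_name``/``family`` split it at the first ``/`` (a bare class
    doubles as its own family).  ``percent_divergence`` is the divergence
    from the library consensus in percent, as printed by RepeatMasker.
    """

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    percent_divergence: float = 0.0
    score: float = 0.0

    def __post_init__(self):
        if self.percent_divergence < 0:
            raise ValueError("percent_divergence must be >= 0")

    @property
    def class_name(self) -> str:
        return self.repeat_class.split("/", 1)[0]

    @property
    def family(self) -> str:
        parts = self.repeat_class.split("/", 1)
        return parts[1] if len(parts) == 2 else parts[0]

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A gene with its representative mRNA's exon/CDS structure.

    ``aed`` is the annotation edit distance (0 = perfect agreement with
    evidence) when the source annotation carries one, else ``None``.
    ``has_start``/``has_stop`` flag start/stop-codon presence; both True
    means a full-length model.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple
    cds: tuple = ()
    aed: float | None = None
    has_start: bool = False
    has_stop: bool = False

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda iv: iv.start))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda iv: iv.start))
        )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if self.aed is not None and not (0.0 <= self.aed <= 1.0):
            raise ValueError(f"gene {self.gene_id}: AED {self.aed} outside [0,1]")

    @property
    def span(self) -> int:
        return self.interval.length

    @property
    def exon_bp(self) -> int:
        return sum(iv.length for iv in self.exons)

    @property
    def cds_bp(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def is_full_length(self) -> bool:
        return self.has_start and self.has_stop


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped.  An empty file yields
    an empty list; sequence data before the first header is a
    :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError(f"{path}: sequence data before first FASTA header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description
        if desc == rec.id:
            desc = ""  # bare header: no description beyond the id
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, line_width: int = 60
) -> None:
    """Write records as FASTA with ``line_width`` characters per sequence line."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id + " "):
                    desc = desc[len(rec.id) + 1 :]
                header = f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_AED_KEYS = ("_AED", "AED", "aed")
_TRUE_STRINGS = {"1", "true", "True", "TRUE", "yes"}


def _parse_bool_attr(attrs, key: str) -> bool:
    vals = attrs.get(key)
    if not vals:
        return False
    return str(vals[0]) in _TRUE_STRINGS


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a MAKER-style GFF3 into one :class:`GeneModel` per gene.

    GFF3 1-based inclusive coordinates become 0-based half-open.  The
    gene -> mRNA -> exon/CDS hierarchy is resolved through ``Parent``
    attributes with :mod:`gffutils`; when a gene carries several mRNAs the
    one with the longest summed CDS is kept as the representative model.
    AED is read from any of ``_AED``/``AED``/``aed`` on the mRNA;
    completeness from ``has_start``/``has_stop`` attributes (a model counts
    as full-length only when explicitly flagged).
    """
    import gffutils

    path = Path(path)
    if path.read_text().strip() == "":
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various internal errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    for feat in db.all_features():
        if feat.start > feat.end:
            raise FormatError(
                f"{path}: feature {feat.id or feat.featuretype} has start > end"
            )

    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        best = None  # (cds_bp, mrna, exons, cds)
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand or ".")
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            cds = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand or ".")
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            if not exons and cds:
                exons = list(cds)
            if not exons:
                warnings.warn(f"mRNA {mrna.id} has no exons; skipped")
                continue
            cds_bp = sum(iv.length for iv in cds)
            key = (cds_bp, sum(iv.length for iv in exons))
            if best is None or key > best[0]:
                best = (key, mrna, exons, cds)
        if best is None:
            warnings.warn(f"gene {gene.id} has no usable mRNA; skipped")
            continue
        _, mrna, exons, cds = best
        aed = None
        for key in _AED_KEYS:
            vals = mrna.attributes.get(key)
            if vals:
                try:
                    aed = float(vals[0])
                except ValueError:
                    aed = None
                break
        model = GeneModel(
            gene_id=gene.id,
            interval=GenomicInterval(
                gene.seqid, gene.start - 1, gene.end, gene.strand or "."
            ),
            exons=tuple(exons),
            cds=tuple(cds),
            aed=aed,
            has_start=_parse_bool_attr(mrna.attributes, "has_start"),
            has_stop=_parse_bool_attr(mrna.attributes, "has_stop"),
        )
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` report.

    The dialect is 3 header lines followed by whitespace-delimited columns
    (score, div%, del%, ins%, query, qbegin, qend, qleft, strand, repeat
    name, class/family, ...).  Query coordinates are 1-based inclusive and
    are converted; complement strand ``C`` maps to ``-``.
    """
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split(None, 1)[0]
            try:
                float(first)
            except ValueError:
                # header / banner line
                continue
            cols = stripped.split()
            if len(cols) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 11 columns, got {len(cols)}"
                )
            score = float(cols[0])
            div = float(cols[1])
            seq_id = cols[4]
            qbegin = int(cols[5])
            qend = int(cols[6])
            strand = "-" if cols[8] in ("C", "-") else "+"
            repeat_name = cols[9]
            repeat_class = cols[10]
            if qbegin > qend:
                raise FormatError(f"{path}:{lineno}: qbegin > qend")
            features.append(
                RepeatFeature(
                    interval=GenomicInterval(seq_id, qbegin - 1, qend, strand),
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    percent_divergence=div,
                    score=score,
                )
            )
    return features


def read_seq_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read a ``.fai``-style TSV (seq_id, length in the first two columns)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.split("\t")
            lengths[cols[0]] = int(cols[1])
    return lengths


# ---------------------------------------------------------------------------
# Tables


def write_table(rows, path: str | os.PathLike) -> None:
    """Write rows (DataFrame, or iterable of dicts) as a headered TSV.

    Column order follows the DataFrame / first row; floats are rendered
    with 6 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else None)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
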