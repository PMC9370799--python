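"""Insertion-time dating of LTR retrotransposons from 5'/3' LTR divergence.

When an LTR retrotransposon inserts, its two flanking long terminal repeats
are identical; they then accumulate substitutions independently.  The
observed difference fraction p between the two LTRs, corrected for multiple
hits with the Jukes-Cantor model,

    d = -(3/4) * ln(1 - 4p/3),        T = d / (2 * mu),

gives the insertion age T in years (both copies diverge simultaneously,
hence the factor 2).  The default substitution rate is the conifer
synonymous rate mu = 1.57e-8 per site per year.

Identity between the two LTRs is computed by global (Needleman-Wunsch)
alignment with free terminal gaps; identity = matches / alignment columns,
counting terminal-gap columns.  Pairs too diverged to align globally
therefore fall to identity near 0, land in the p >= 3/4 saturation domain
of the JC correction, and are excluded from summaries rather than assigned
a meaningless age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import SequenceRecord, read_fasta, read_table

__all__ = [
    "JCParams",
    "LtrElement",
    "AgeEstimate",
    "AgeSummary",
    "SaturationError",
    "pairwise_identity",
    "jc_distance",
    "insertion_time",
    "date_element",
    "date_library",
    "classify_flank_motif",
    "classify_superfamily",
    "summarize_ages",
    "load_ltr_library",
    "deduplicate_library",
]

#: observed difference fraction at which the JC correction diverges
SATURATION_P = 0.75


class SaturationError(ValueError):
    """p >= 3/4: the JC correction is undefined (saturated divergence)."""


@dataclass(frozen=True)
class JCParams:
    """Jukes-Cantor clock: substitution rate per site per year."""

    mu: float = 1.57e-8

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class LtrElement:
    """A retroelement represented by its two flanking LTR sequences."""

    element_id: str
    ltr5: str
    ltr3: str
    domain_order: str | None = None
    superfamily: str = "unknown"
    flank_motif: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if not self.ltr5 or not self.ltr3:
            raise ValueError(f"element {self.element_id}: empty LTR sequence")
        self.ltr5 = self.ltr5.upper()
        self.ltr3 = self.ltr3.upper()


@dataclass(frozen=True)
class AgeEstimate:
    """identity -> p -> d -> T chain for one element.

    ``saturated`` elements (p >= 3/4) carry NaN for d and T and are
    excluded from summaries.
    """

    element_id: str
    identity: float
    p: float
    d: float
    t_years: float
    t_mya: float
    saturated: bool = False


@dataclass(frozen=True)
class AgeSummary:
    stratum: str
    n: int
    mean_mya: float
    median_mya: float
    histogram: tuple  # of (bin_start_mya, bin_end_mya, count)


# ---------------------------------------------------------------------------
# alignment identity

_ALPHABET = "ACGTN"


def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -5.0  # gap open -4 plus first extension -1
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in seq)


def alignment_score(a: str, b: str) -> float:
    """Optimal ends-free global alignment score (match +1, mismatch -1,
    gap open -4, gap extend -1, terminal gaps free)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _ALIGNER.score(_sanitize(a), _sanitize(b))


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two DNA sequences.

    identity = matched columns / total alignment columns, counting gap
    columns (terminal ones included).  Non-ACGT letters never match,
    not even themselves.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(_sanitize(a), _sanitize(b))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(
        1 for c1, c2 in zip(s1, s2) if c1 == c2 and c1 in "ACGT"
    )
    return matches / len(s1)


# ---------------------------------------------------------------------------
# Jukes-Cantor chain


def jc_distance(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 3/4; strictly increasing, d >= p.
    """
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    if p >= SATURATION_P:
        raise SaturationError(f"p = {p} >= 3/4: JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def insertion_time(d: float, params: JCParams = JCParams()) -> float:
    """Insertion age in years, T = d / (2 mu)."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    return d / (2.0 * params.mu)


def date_element(el: LtrElement, params: JCParams = JCParams()) -> AgeEstimate:
    """Chain identity -> p -> d -> T for one element.

    Saturated pairs (p >= 3/4) get ``saturated=True`` with NaN age.
    """
    identity = pairwise_identity(el.ltr5, el.ltr3)
    p = 1.0 - identity
    if p >= SATURATION_P:
        return AgeEstimate(el.element_id, identity, p, math.nan, math.nan,
                           math.nan, saturated=True)
    d = jc_distance(p)
    t = insertion_time(d, params)
    return AgeEstimate(el.element_id, identity, p, d, t, t / 1e6)


def date_library(
    elements: Iterable[LtrElement], params: JCParams = JCParams()
) -> list[AgeEstimate]:
    return [date_element(el, params) for el in elements]


# ---------------------------------------------------------------------------
# classification


def classify_flank_motif(el: LtrElement) -> str:
    """``TGCA`` iff both LTRs start with TG and end with CA; ``unknown``
    when either LTR is shorter than 4 bp; else ``other``."""
    if len(el.ltr5) < 4 or len(el.ltr3) < 4:
        return "unknown"
    for seq in (el.ltr5, el.ltr3):
        if not (seq.startswith("TG") and seq.endswith("CA")):
            return "other"
    return "TGCA"


def classify_superfamily(domain_order: str | None) -> str:
    """Map internal protein domain order to superfamily.

    Copia elements carry protease-integrase-reverse transcriptase
    (PR-INT-RT); Gypsy carry PR-RT-INT.  Case- and separator-insensitive.
    """
    if not domain_order:
        return "unknown"
    key = "".join(c for c in domain_order.upper() if c.isalpha())
    if key == "PRINTRT":
        return "Copia"
    if key == "PRRTINT":
        return "Gypsy"
    return "unknown"


# ---------------------------------------------------------------------------
# summaries


def _median(values: Sequence[float]) -> float:
    # even n: arithmetic mean of the two central values
    return float(np.median(values))


def summarize_ages(
    estimates: Iterable[AgeEstimate],
    strata: Mapping[str, str] | None = None,
    bin_width_mya: float = 0.5,
) -> list[AgeSummary]:
    """Per-stratum age summaries (n, mean, median, contiguous histogram).

    Saturated estimates are dropped.  ``strata`` maps element_id to a
    stratum label (e.g. superfamily or flank motif); an ``all`` stratum
    covering every dated element is always included.  Histogram bins start
    at 0 MYA with fixed width ``bin_width_mya``.
    """
    if bin_width_mya <= 0:
        raise ValueError("bin_width_mya must be > 0")
    dated = [e for e in estimates if not e.saturated]
    groups: dict[str, list[float]] = {"all": [e.t_mya for e in dated]}
    if strata is not None:
        for e in dated:
            label = strata.get(e.element_id)
            if label is None:
                continue
            groups.setdefault(str(label), []).append(e.t_mya)
    summaries = []
    for stratum in sorted(groups):
        ages = groups[stratum]
        if not ages:
            warnings.warn(f"stratum {stratum!r} is empty; omitted")
            continue
        n_bins = max(1, math.ceil(max(ages) / bin_width_mya))
        if max(ages) == n_bins * bin_width_mya:
            n_bins += 1  # keep the max age inside a half-open bin
        edges = [i * bin_width_mya for i in range(n_bins + 1)]
        counts, _ = np.histogram(ages, bins=edges)
        hist = tuple(
            (edges[i], edges[i + 1], int(counts[i])) for i in range(n_bins)
        )
        summaries.append(
            AgeSummary(
                stratum=stratum,
                n=len(ages),
                mean_mya=float(np.mean(ages)),
                median_mya=_median(ages),
                histogram=hist,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# library ingestion

_SUFFIX_5 = "_5LTR"
_SUFFIX_3 = "_3LTR"


def load_ltr_library(
    fasta_path, meta_path=None
) -> list[LtrElement]:
    """Load an LTR library from FASTA, pairing ``*_5LTR``/``*_3LTR`` records.

    Optional metadata TSV (columns ``element_id`` and any of
    ``domain_order``, ``superfamily``, ``source``) annotates elements;
    superfamily falls back to :func:`classify_superfamily` on the domain
    order.  Records without a partner, and metadata rows pointing at
    missing elements, are rejected with a report of the offending ids.
    """
    records = read_fasta(fasta_path)
    ltr5: dict[str, str] = {}
    ltr3: dict[str, str] = {}
    orphans: list[str] = []
    for rec in records:
        if rec.id.endswith(_SUFFIX_5):
            ltr5[rec.id[: -len(_SUFFIX_5)]] = rec.seq
        elif rec.id.endswith(_SUFFIX_3):
            ltr3[rec.id[: -len(_SUFFIX_3)]] = rec.seq
        else:
            orphans.append(rec.id)
    unpaired = sorted(set(ltr5) ^ set(ltr3))
    if orphans or unpaired:
        raise ValueError(
            "unpaired LTR library records: "
            + ", ".join(orphans + [f"{eid} (missing partner)" for eid in unpaired])
        )
    meta: dict[str, dict] = {}
    if meta_path is not None:
        df = read_table(meta_path)
        missing = sorted(set(df["element_id"]) - set(ltr5))
        if missing:
            raise ValueError(
                "metadata rows for unknown elements: " + ", ".join(missing)
            )
        meta = {row["element_id"]: dict(row) for _, row in df.iterrows()}
    elements = []
    for eid in ltr5:  # insertion order = file order
        row = meta.get(eid, {})
        domain_order = row.get("domain_order") or None
        superfamily = row.get("superfamily") or classify_superfamily(domain_order)
        el = LtrElement(
            element_id=eid,
            ltr5=ltr5[eid],
            ltr3=ltr3[eid],
            domain_order=domain_order,
            superfamily=superfamily,
            source=str(row.get("source", "")),
        )
        el.flank_motif = classify_flank_motif(el)
        elements.append(el)
    return elements


def deduplicate_library(
    new_elements: Sequence[LtrElement],
    existing: Sequence[LtrElement],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> tuple[list[LtrElement], list[tuple[str, str]]]:
    """Merge a second library into an existing one, dropping near-duplicates.

    A new element is a duplicate when its 5' LTR aligns to an existing
    element's 5' LTR at >= ``min_identity`` identity over >= ``min_coverage``
    of the shorter sequence.  Returns (retained new elements, list of
    (duplicate_id, matching_existing_id)).
    """
    kept: list[LtrElement] = []
    duplicates: list[tuple[str, str]] = []
    for el in new_elements:
        hit = None
        for ex in existing:
            aln = _ALIGNER.align(_sanitize(el.ltr5), _sanitize(ex.ltr5))[0]
            s1, s2 = str(aln[0]), str(aln[1])
            matches = sum(
                1 for c1, c2 in zip(s1, s2) if c1 == c2 and c1 in "ACGT"
            )
            aligned_cols = sum(
                1 for c1, c2 in zip(s1, s2) if c1 != "-" and c2 != "-"
            )
            shorter = min(len(el.ltr5), len(ex.ltr5))
            if aligned_cols == 0:
                continue
            if (
                matches / aligned_cols >= min_identity
                and aligned_cols / shorter >= min_coverage
            ):
                hit = ex.element_id
                break
        if hit is None:
            kept.append(el)
        else:
            duplicates.append((el.element_id, hit))
    return kept, duplicates
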