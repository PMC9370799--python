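"""Repeat-landscape summaries over RepeatMasker-style annotations.

The central contrast: the *naive* repeat fraction simply sums feature
lengths (overlapping and nested repeat hits are double-counted, so the
fraction can exceed 1), while the *union* fraction merges overlapping
intervals per sequence before counting, giving the true fraction of bases
covered.  On fragmented conifer assemblies the two differ substantially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval, RepeatFeature

__all__ = [
    "RepeatLandscape",
    "naive_repeat_fraction",
    "union_repeat_fraction",
    "merge_intervals",
    "family_table",
    "length_histogram",
    "repeat_landscape",
]


@dataclass(frozen=True)
class RepeatLandscape:
    per_family: pd.DataFrame
    genome_total_bp: int
    naive_fraction: float
    union_fraction: float | None


def naive_repeat_fraction(
    features: Sequence[RepeatFeature], genome_total_bp: int
) -> float:
    """Summed feature length / total bp, with no de-overlapping.

    May exceed 1 when repeats overlap or nest.
    """
    if genome_total_bp <= 0:
        raise ValueError("genome_total_bp must be > 0")
    return sum(f.length for f in features) / genome_total_bp


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent [start, end) intervals (sort + sweep)."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def union_repeat_fraction(
    features: Sequence[RepeatFeature], seq_lengths: Mapping[str, int]
) -> tuple[float, dict[str, int]]:
    """Fraction of bases covered by the union of repeat intervals.

    Overlaps and nested repeats are counted once.  Returns the overall
    fraction (denominator = sum of ``seq_lengths``) and per-sequence
    covered bp.  Features on sequences absent from ``seq_lengths`` are an
    error (silent denominator mistakes are the main hazard here).
    """
    unknown = sorted({f.interval.seq_id for f in features} - set(seq_lengths))
    if unknown:
        raise KeyError(f"features on sequences without a length: {unknown}")
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_seq.setdefault(f.interval.seq_id, []).append(
            (f.interval.start, f.interval.end)
        )
    covered = {seq_id: 0 for seq_id in seq_lengths}
    for seq_id, ivs in by_seq.items():
        covered[seq_id] = sum(e - s for s, e in merge_intervals(ivs))
    total = sum(seq_lengths.values())
    if total <= 0:
        raise ValueError("total sequence length must be > 0")
    return sum(covered.values()) / total, covered


def family_table(features: Sequence[RepeatFeature]) -> pd.DataFrame:
    """Per-(class, family) counts, total bp and mean length.

    Sorted by total bp descending (ties by class then family) so the table
    is deterministic.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for f in features:
        key = (f.class_name, f.family)
        if key not in rows:
            rows[key] = [0, 0]
        rows[key][0] += 1
        rows[key][1] += f.length
    records = [
        {
            "class": cls,
            "family": fam,
            "count": count,
            "total_bp": bp,
            "mean_length_bp": bp / count,
        }
        for (cls, fam), (count, bp) in rows.items()
    ]
    df = pd.DataFrame(
        records, columns=["class", "family", "count", "total_bp", "mean_length_bp"]
    )
    if len(df):
        df = df.sort_values(
            ["total_bp", "class", "family"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def length_histogram(
    features: Sequence[RepeatFeature], bins: Sequence[float]
) -> pd.DataFrame:
    """Per-family feature-length histogram over contiguous ``bins`` edges.

    Useful for spotting bimodal length distributions (full-length elements
    vs truncated fragments).  Counts conserve: features outside the edges
    fall in open-ended flanking bins.
    """
    edges = list(bins)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bins must be an increasing sequence of edges")
    full_edges = [-np.inf] + edges + [np.inf]
    rows = []
    by_family: dict[str, list[int]] = {}
    for f in features:
        by_family.setdefault(f.family, []).append(f.length)
    for family in sorted(by_family):
        counts, _ = np.histogram(by_family[family], bins=full_edges)
        for i in range(len(full_edges) - 1):
            if counts[i] == 0 and (i == 0 or i == len(full_edges) - 2):
                continue
            rows.append(
                {
                    "family": family,
                    "bin_start": full_edges[i],
                    "bin_end": full_edges[i + 1],
                    "count": int(counts[i]),
                }
            )
    return pd.DataFrame(rows, columns=["family", "bin_start", "bin_end", "count"])


def repeat_landscape(
    features: Sequence[RepeatFeature],
    genome_total_bp: int,
    seq_lengths: Mapping[str, int] | None = None,
    exclude_classes: Sequence[str] = (),
) -> RepeatLandscape:
    """Full landscape: family table plus naive and (optionally) union coverage."""
    if exclude_classes:
        excluded = set(exclude_classes)
        features = [f for f in features if f.class_name not in excluded]
    union = None
    if seq_lengths is not None:
        union, _ = union_repeat_fraction(features, seq_lengths)
    return RepeatLandscape(
        per_family=family_table(features),
        genome_total_bp=genome_total_bp,
        naive_fraction=naive_repeat_fraction(features, genome_total_bp)
        if features
        else 0.0,
        union_fraction=union,
    )
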