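"""Cross-species comparison of per-GO-term gene abundance.

Given, for each species, the number of genes annotated with each GO term
and the species' total number of annotated genes, terms present in every
species are tested for equality of proportions with a k-sample chi-square
homogeneity test (df = S - 1, no continuity correction).  P-values get
dual false-discovery-rate control: Benjamini-Hochberg step-up adjustment
and Storey q-values (pi0 estimated with a smoother over a lambda grid).
A term is called significant when it clears both thresholds
(default q < 0.005 and BH-adjusted p < 0.01, both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GoCountMatrix",
    "GoTermTest",
    "SignificanceConfig",
    "shared_terms",
    "proportion_test",
    "bh_adjust",
    "storey_qvalues",
    "test_terms",
    "select_significant",
    "group_contrast",
    "load_count_matrix",
]


@dataclass(frozen=True)
class GoCountMatrix:
    """Per-species GO-term gene counts.

    ``counts`` is S x G (species by terms); ``totals`` holds the number of
    annotated genes per species (the test denominator).
    """

    species: tuple
    terms: tuple
    counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        totals = np.asarray(self.totals, dtype=np.int64)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "totals", totals)
        S, G = counts.shape
        if S != len(self.species) or G != len(self.terms):
            raise ValueError("counts shape does not match species/terms")
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if np.any(totals <= 0):
            raise ValueError("all species totals must be positive")
        if np.any(counts < 0) or np.any(counts > totals[:, None]):
            raise ValueError("counts must satisfy 0 <= count <= species total")


@dataclass(frozen=True)
class GoTermTest:
    term: str
    statistic: float
    df: int
    p: float
    p_bh: float
    q: float
    per_species_pct: tuple
    low_support: bool = False


@dataclass(frozen=True)
class SignificanceConfig:
    q_threshold: float = 0.005
    p_bh_threshold: float = 0.01

    def __post_init__(self):
        for v in (self.q_threshold, self.p_bh_threshold):
            if not (0 < v < 1) and v != 1.0:
                raise ValueError("thresholds must be in (0, 1]")


def shared_terms(matrix: GoCountMatrix) -> list[str]:
    """Terms with a nonzero count in every species."""
    mask = np.all(matrix.counts > 0, axis=0)
    return [t for t, m in zip(matrix.terms, mask) if m]


def proportion_test(
    term_counts: Sequence[int], totals: Sequence[int]
) -> tuple[float, int, float]:
    """k-sample chi-square test of equal proportions.

    Builds the S x 2 table (count, total - count) and returns
    (statistic, df = S - 1, upper-tail p).  No continuity correction, so
    identical proportions give statistic exactly 0 and p = 1.
    """
    counts = np.asarray(term_counts, dtype=float)
    totals_arr = np.asarray(totals, dtype=float)
    if counts.shape != totals_arr.shape or counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need S >= 2 matched counts and totals")
    if np.any(totals_arr <= 0):
        raise ValueError("all totals must be positive")
    if np.any(counts < 0) or np.any(counts > totals_arr):
        raise ValueError("counts must lie in [0, total]")
    stat, p, df, _ = _chi2_table(counts, totals_arr)
    return stat, df, p


def _chi2_table(counts, totals):
    pooled = counts.sum() / totals.sum()
    expected1 = totals * pooled
    expected0 = totals * (1.0 - pooled)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0, len(counts) - 1, False
    with np.errstate(invalid="ignore"):
        stat = float(
            np.sum((counts - expected1) ** 2 / expected1)
            + np.sum(((totals - counts) - expected0) ** 2 / expected0)
        )
    df = len(counts) - 1
    p = float(stats.chi2.sf(stat, df))
    low_support = bool(np.any(expected1 < 1.0) or np.any(expected0 < 1.0))
    return stat, p, df, low_support


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


def storey_qvalues(
    pvals: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[np.ndarray, float]:
    """Storey q-values with a smoother-based pi0 estimate.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) m) is computed over the
    grid, smoothed with a cubic spline and read off at the largest lambda
    (the lambda -> 1 extrapolation), then clipped to (0, 1].  q-values are
    pi0 * m * p / rank with the step-up cumulative minimum, so pi0 = 1
    reduces exactly to BH.  Fewer than 10 p-values: pi0 falls back to 1
    with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    grid = np.asarray(lambda_grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie in (0, 1)")
    if m < 10:
        warnings.warn("fewer than 10 p-values; using pi0 = 1 (BH-equivalent)")
        pi0 = 1.0
    else:
        pi0 = estimate_pi0(p, grid)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def estimate_pi0(p: np.ndarray, grid: np.ndarray) -> float:
    """Smoother estimate of the true-null proportion pi0.

    Falls back to the single-lambda estimate at 0.5 when the spline is
    degenerate (e.g. a constant grid).
    """
    from scipy.interpolate import UnivariateSpline

    grid = np.sort(grid)
    m = p.size
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in grid]
    )
    try:
        if len(grid) < 4:
            raise ValueError("grid too small for a cubic smoother")
        spline = UnivariateSpline(grid, pi0_lambda, k=3)
        pi0 = float(spline(grid[-1]))
    except Exception:
        pi0 = float(np.mean(p > 0.5) / 0.5)
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = float(np.mean(p > 0.5) / 0.5)
    return float(min(max(pi0, 1.0 / m), 1.0))


def test_terms(
    matrix: GoCountMatrix,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    mode: str = "joint",
) -> list[GoTermTest]:
    """Run the proportion test on every shared term with BH and Storey control.

    ``mode='joint'`` (default) tests all species jointly; ``'pairwise'``
    tests each species against the pooled rest with a two-proportion
    z-test and keeps the smallest Bonferroni-adjusted p per term (a
    sensitivity-analysis variant).
    """
    terms = shared_terms(matrix)
    if not terms:
        return []
    idx = {t: i for i, t in enumerate(matrix.terms)}
    totals = matrix.totals.astype(float)
    stats_list = []
    pvals = []
    lows = []
    for t in terms:
        counts = matrix.counts[:, idx[t]].astype(float)
        if mode == "joint":
            stat, p, df, low = _chi2_table(counts, totals)
        elif mode == "pairwise":
            stat, p, df, low = _pairwise_vs_rest(counts, totals)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        stats_list.append((stat, df))
        pvals.append(p)
        lows.append(low)
    pvals_arr = np.asarray(pvals)
    p_bh = bh_adjust(pvals_arr)
    q, _pi0 = storey_qvalues(pvals_arr, lambda_grid)
    results = []
    for i, t in enumerate(terms):
        counts = matrix.counts[:, idx[t]]
        results.append(
            GoTermTest(
                term=t,
                statistic=stats_list[i][0],
                df=stats_list[i][1],
                p=float(pvals_arr[i]),
                p_bh=float(p_bh[i]),
                q=float(q[i]),
                per_species_pct=tuple(counts / matrix.totals),
                low_support=lows[i],
            )
        )
    return results


def _pairwise_vs_rest(counts, totals):
    S = len(counts)
    best_p = 1.0
    best_z = 0.0
    low = False
    for s in range(S):
        c1, n1 = counts[s], totals[s]
        c2, n2 = counts.sum() - c1, totals.sum() - n1
        pooled = (c1 + c2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        if se == 0:
            continue
        z = (c1 / n1 - c2 / n2) / se
        p = 2 * stats.norm.sf(abs(z))
        low = low or min(n1 * pooled, n2 * pooled) < 1
        p_adj = min(1.0, p * S)
        if p_adj < best_p:
            best_p, best_z = p_adj, z
    return float(abs(best_z)), float(best_p), S - 1, low


def select_significant(
    matrix: GoCountMatrix,
    config: SignificanceConfig = SignificanceConfig(),
    mode: str = "joint",
) -> list[GoTermTest]:
    """Shared terms passing BOTH q < q_threshold and BH p < p_bh_threshold."""
    return [
        t
        for t in test_terms(matrix, mode=mode)
        if t.q < config.q_threshold and t.p_bh < config.p_bh_threshold
    ]


def group_contrast(
    tests: Sequence[GoTermTest],
    species: Sequence[str],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-term group summaries (e.g. deciduous vs evergreen medians).

    ``grouping`` maps every species to a group label; unassigned species
    are an error.  Returns one row per term with each group's per-species
    percentages and their median.
    """
    unassigned = [s for s in species if s not in grouping]
    if unassigned:
        raise ValueError(f"species without a group: {unassigned}")
    labels = sorted(set(grouping.values()))
    rows = []
    for t in tests:
        row = {"term": t.term}
        for g in labels:
            pct = [
                t.per_species_pct[i]
                for i, s in enumerate(species)
                if grouping[s] == g
            ]
            row[f"{g}_pct"] = tuple(pct)
            row[f"{g}_median"] = float(np.median(pct))
        rows.append(row)
    return pd.DataFrame(rows)


def load_count_matrix(counts_dir, totals_path) -> GoCountMatrix:
    """Assemble a :class:`GoCountMatrix` from one TSV per species.

    Each ``<species>.tsv`` in ``counts_dir`` has columns (term_id,
    gene_count); ``totals_path`` is a TSV with columns (species, total).
    Terms absent from a species' file count 0 there.
    """
    totals_df = pd.read_csv(totals_path, sep="\t")
    species = list(totals_df.iloc[:, 0].astype(str))
    totals = totals_df.iloc[:, 1].to_numpy(dtype=np.int64)
    per_species = {}
    all_terms: list[str] = []
    seen = set()
    for sp in species:
        path = Path(counts_dir) / f"{sp}.tsv"
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
        per_species[sp] = counts
        for term in counts:
            if term not in seen:
                seen.add(term)
                all_terms.append(term)
    matrix = np.zeros((len(species), len(all_terms)), dtype=np.int64)
    for i, sp in enumerate(species):
        for j, term in enumerate(all_terms):
            matrix[i, j] = per_species[sp].get(term, 0)
    return GoCountMatrix(tuple(species), tuple(all_terms), matrix, totals)
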