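"""Haplogroup frequency tables, pooling and chi-square homogeneity tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FrequencyTable:
    """Per-group haplogroup frequencies (%) with sample sizes.

    ``freq`` is a groups x haplogroups DataFrame in percent; ``sizes`` maps
    group label to sample size; ``counts`` (optional) holds the integer
    counts the frequencies derive from.  Cells above 100% are flagged rather
    than silently accepted (frequency tables in print occasionally carry
    decimal-point misprints).
    """

    freq: pd.DataFrame
    sizes: Mapping[str, int]
    counts: pd.DataFrame | None = None

    def flag_suspect_cells(self) -> list[tuple[str, str, float]]:
        out = []
        for g in self.freq.index:
            for h in self.freq.columns:
                v = self.freq.loc[g, h]
                if pd.notna(v) and v > 100:
                    out.append((g, h, float(v)))
        return out

    def check_sums(self, partition: Sequence[str], tol: float = 0.2) -> dict[str, bool]:
        """Whether frequencies over a complete haplogroup partition sum to
        100 within rounding tolerance, per group."""
        sums = self.freq[list(partition)].sum(axis=1)
        return {g: bool(abs(s - 100.0) <= tol) for g, s in sums.items()}

    def pooled(self, groups: Sequence[str], haplogroup: str) -> float:
        return pooled_frequency([float(self.freq.loc[g, haplogroup]) for g in groups],
                                [int(self.sizes[g]) for g in groups])


def pooled_frequency(freqs: Sequence[float], sizes: Sequence[int]) -> float:
    """Sample-size-weighted pooled frequency, reported at 1 d.p.

    ``sum(n_i * f_i) / sum(n_i)`` — a convex combination, so the result
    always lies between the smallest and largest input frequency.
    """
    if len(freqs) != len(sizes):
        raise ValueError("freqs and sizes must have equal length")
    if len(freqs) == 0 or any(n <= 0 for n in sizes):
        raise ValueError("need at least one group with positive size")
    f = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    return round(float((f * n).sum() / n.sum()), 1)


def chi2_homogeneity(counts) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on a group x haplogroup table.

    Haplogroup categories whose pooled expected count falls below 1 are
    merged into an "other" column before testing (sparse categories make
    the chi-square approximation unreliable).  Returns (statistic, df, p).
    """
    table = np.asarray(pd.DataFrame(counts).values, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if table.sum() == 0:
        raise ValueError("all-zero table")

    grand = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / grand
    weak = expected.min(axis=0) < 1.0
    if weak.any() and (~weak).any():
        merged = table[:, ~weak]
        other = table[:, weak].sum(axis=1, keepdims=True)
        table = np.hstack([merged, other])
    # drop all-zero columns (their expected counts are zero)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 informative categories after merging")

    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def branch_share(freq_a: float, freq_b: float, total: float) -> int:
    """Share of a haplogroup's carriers on two branches, integer percent:
    ``(freq_a + freq_b) / total * 100``."""
    if total <= 0:
        raise ValueError("total frequency must be positive")
    return int(round((freq_a + freq_b) / total * 100.0))
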