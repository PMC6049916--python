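"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops over plain Python containers, on
purpose: these functions must stay structurally independent of the
vectorized implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd


def naive_zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for row_id in values.index:
        row = [float(v) for v in values.loc[row_id]]
        m = sum(row) / len(row)
        var = sum((v - m) ** 2 for v in row) / (len(row) - 1)
        sd = math.sqrt(var)
        if sd <= 1e-12 * max(1.0, max(abs(v) for v in row)):
            continue
        out[row_id] = [(v - m) / sd for v in row]
    return pd.DataFrame.from_dict(out, orient="index", columns=values.columns)


def naive_indices(
    values: pd.DataFrame,
    annotation: dict[str, str],
    sets: dict[str, set[str]],
    category_of: dict[str, str],
    overlap: set[str],
    category_order: tuple[str, ...],
    min_genes: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loop reimplementation of the full index pipeline.

    Returns (publication table on full sets, consolidated table with
    overlap genes removed).
    """
    z = naive_zscore_rows(values)
    # average transcripts per gene, re-z-score
    genes: dict[str, list[str]] = {}
    for row_id in z.index:
        sym = annotation.get(row_id)
        if sym:
            genes.setdefault(sym.upper(), []).append(row_id)
    averaged = {}
    for sym, rows in genes.items():
        cols = []
        for s in z.columns:
            cols.append(sum(float(z.loc[r, s]) for r in rows) / len(rows))
        averaged[sym] = cols
    gene_df = pd.DataFrame.from_dict(averaged, orient="index", columns=z.columns)
    gene_z = naive_zscore_rows(gene_df)

    def set_means(active_sets: dict[str, set[str]]) -> pd.DataFrame:
        cols = {}
        for tag in sorted(active_sets):
            matched = sorted(
                g.upper() for g in active_sets[tag] if g.upper() in gene_z.index
            )
            if len(matched) < min_genes:
                continue
            cols[tag] = [
                sum(float(gene_z.loc[g, s]) for g in matched) / len(matched)
                for s in gene_z.columns
            ]
        return pd.DataFrame(cols, index=list(gene_z.columns))

    pub = set_means({t: set(s) for t, s in sets.items()})
    filtered = {t: {g for g in s if g not in overlap} for t, s in sets.items()}
    filtered = {t: s for t, s in filtered.items() if s}
    pub_f = set_means(filtered)
    cons = {}
    for cat in category_order:
        tags = [t for t in pub_f.columns if category_of[t] == cat]
        if tags:
            cons[cat] = [
                sum(float(pub_f.loc[s, t]) for t in tags) / len(tags)
                for s in pub_f.index
            ]
    return pub, pd.DataFrame(cons, index=list(pub_f.index))


def brute_force_cross_category(rows: list[tuple[str, str, str]]) -> set[str]:
    """Exhaustive (gene, category) pair scan."""
    found = set()
    for g1, c1, _ in rows:
        for g2, c2, _ in rows:
            if g1 == g2 and c1 != c2:
                found.add(g1)
    return found


def stepup_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            m * pvals[j] / (pos)
            for pos, j in enumerate(order, start=1)
            if pos >= rank_pos
        ]
        q[i] = min(1.0, min(candidates))
    return q


def fisher_twosided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by probability-mass enumeration.

    Conditions on all margins; sums hypergeometric probabilities of tables
    whose probability does not exceed the observed table's. Pure-Fraction
    arithmetic, so ties are exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = pmf(k)
        if pk <= p_obs:
            total += pk
    return total


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (X'X)^-1 X'y via explicit inverse."""
    xtx = X.T @ X
    return np.linalg.inv(xtx) @ X.T @ y
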