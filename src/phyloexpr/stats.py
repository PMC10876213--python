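"""Shared statistics: BH false-discovery control, Spearman correlations to
reference species, and Mann-Whitney U comparison of correlation distributions.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = ["bh_fdr", "spearman_to_references", "mwu_compare", "EXACT_MWU_MAX_N"]

EXACT_MWU_MAX_N = 12  # combined sample size up to which MWU p is enumerated


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values; input order
    is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_to_references(
    species_expr: pd.DataFrame,
    gene_set,
    references,
    species=None,
) -> pd.DataFrame:
    """Spearman rank correlation of each species' expression to reference
    species, over a stated gene set (average ranks on ties).

    ``species_expr`` is a gene x species matrix (e.g. mean log2-CPM).
    """
    genes = list(gene_set)
    if len(genes) < 3:
        raise ValueError("gene set must contain at least 3 genes")
    missing = [g for g in genes if g not in species_expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    sub = species_expr.loc[genes]
    if species is None:
        species = list(sub.columns)
    for name in list(references) + list(species):
        if name not in sub.columns:
            raise ValueError(f"species {name!r} absent from matrix")
    rows = []
    for ref in references:
        for sp in species:
            rho = sps.spearmanr(sub[ref], sub[sp]).statistic
            rows.append({"species": sp, "reference": ref, "rho": float(rho)})
    return pd.DataFrame(rows)


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled values.

    Handles ties naturally because the enumeration is over the observed
    pooled values themselves.
    """
    pooled = np.concatenate([a, b])
    n1, total = len(a), len(pooled)
    n_arr = comb(total, n1)
    le = ge = 0
    idx = np.arange(total)
    for pick in combinations(range(total), n1):
        mask = np.zeros(total, dtype=bool)
        mask[list(pick)] = True
        ga, gb = pooled[mask], pooled[~mask]
        u = _u_statistic(ga, gb)
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    del idx
    return min(1.0, 2.0 * min(le, ge) / n_arr)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a, b) pairs with a < b counts 0 ... standard
    Mann-Whitney U = sum over pairs of [a > b] + 0.5 [a == b]."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mwu_compare(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is <= 12 (ties handled by
    enumerating the observed pooled values); normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    if a.size + b.size <= EXACT_MWU_MAX_N:
        p = _exact_mwu_p(a, b, u)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, p
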