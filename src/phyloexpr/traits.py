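"""Brain-size analysis: ECV-to-mass conversion, PCA of species-mean
expression, PC-vs-trait regression with AIC model selection, and gene-loading
extraction.

Endocranial volume (ml) converts to brain mass at 1.036 g/ml.  Brain mass
spans two orders of magnitude across primates, so the regression trait
defaults to log10 mass (a raw-scale flag is provided).  The PCA is centered
but not scaled — species profiles share log2-CPM units — with a flag to
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ECV_TO_MASS_G_PER_ML
from .normalize import top_variable_genes

__all__ = [
    "PCAResult",
    "TraitRegressionResult",
    "ecv_to_mass",
    "pca_species",
    "regress_trait_on_pcs",
    "gene_loadings",
]


def ecv_to_mass(ecv_ml):
    """Brain mass (g) from endocranial volume (ml): mass = 1.036 * ECV."""
    ecv = np.asarray(ecv_ml, dtype=float)
    if (ecv < 0).any():
        raise ValueError("ECV must be non-negative")
    out = ecv * ECV_TO_MASS_G_PER_ML
    return float(out) if out.ndim == 0 else out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # species x PCs
    loadings: pd.DataFrame  # genes x PCs, columns orthonormal
    variance_fraction: np.ndarray  # sums to 1 over all PCs
    genes: list  # the top-variable genes the PCA used


def pca_species(
    species_expr: pd.DataFrame, n_genes: int = 500, scale: bool = False
) -> PCAResult:
    """PCA of species-mean expression restricted to the ``n_genes`` most
    variable genes (by SD across species).

    Columns (genes) are centered; unit-variance scaling is off by default.
    Sign convention: each loading vector's largest-magnitude element is made
    positive, so results are reproducible across eigensolvers.
    """
    if species_expr.shape[1] < 3:
        raise ValueError("PCA requires at least 3 species")
    if n_genes > species_expr.shape[0]:
        raise ValueError(
            f"requested {n_genes} genes, matrix has {species_expr.shape[0]}")
    genes = top_variable_genes(species_expr, n_genes)
    X = species_expr.loc[genes].to_numpy(dtype=float).T  # species x genes
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # drop numerically-null components
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    signs = np.sign(Vt[np.arange(Vt.shape[0]),
                       np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    pcs = [f"PC{i + 1}" for i in range(s.size)]
    var = s ** 2
    return PCAResult(
        scores=pd.DataFrame(U * s, index=species_expr.columns, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=genes, columns=pcs),
        variance_fraction=var / var.sum(),
        genes=genes,
    )


@dataclass
class TraitRegressionResult:
    per_pc: pd.DataFrame  # pc, r2, adj_r2, aic
    full_r2: float
    selected_pc: str  # argmin single-predictor AIC


def regress_trait_on_pcs(
    pca: PCAResult, trait: pd.Series, n_pcs: int | None = None
) -> TraitRegressionResult:
    """OLS of a species trait on PC scores.

    Fits each single-PC model (adjusted R^2, AIC) and the joint ``n_pcs``
    model (R^2); the selected PC minimizes single-predictor AIC.
    """
    species = list(pca.scores.index)
    missing = [s for s in species if s not in trait.index]
    if missing:
        raise ValueError(f"trait missing species: {missing[:5]}")
    y = trait.loc[species].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant: regression undefined")
    if n_pcs is None:
        n_pcs = pca.scores.shape[1]
    if n_pcs > pca.scores.shape[1]:
        raise ValueError(f"only {pca.scores.shape[1]} PCs available")
    pcs = list(pca.scores.columns[:n_pcs])
    rows = []
    for pc in pcs:
        X = sm.add_constant(pca.scores[pc].to_numpy())
        res = sm.OLS(y, X).fit()
        rows.append({"pc": pc, "r2": float(res.rsquared),
                     "adj_r2": float(res.rsquared_adj),
                     "aic": float(res.aic)})
    per_pc = pd.DataFrame(rows)
    Xf = sm.add_constant(pca.scores[pcs].to_numpy())
    full = sm.OLS(y, Xf).fit()
    selected = per_pc.loc[per_pc["aic"].idxmin(), "pc"]
    return TraitRegressionResult(per_pc=per_pc, full_r2=float(full.rsquared),
                                 selected_pc=str(selected))


def gene_loadings(pca: PCAResult, pc: str) -> pd.DataFrame:
    """Genes ranked by descending signed loading on one PC (ties by id)."""
    if pc not in pca.loadings.columns:
        raise ValueError(f"unknown PC {pc!r}")
    lo = pca.loadings[pc]
    order = sorted(lo.index, key=lambda g: (-lo[g], g))
    out = pd.DataFrame({"gene": order, "loading": lo.loc[order].to_numpy()})
    out["rank"] = np.arange(1, len(out) + 1)
    return out
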