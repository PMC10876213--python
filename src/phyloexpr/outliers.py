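"""Species-specific outlier expression against the fitted evolutionary mean
and variance, plus exclusive gene-set intersection counts (UpSet data).

A gene preferred by the single-optimum OU model has an estimated optimum
theta-hat (the evolutionary mean) and stationary variance sigma2-hat /
(2 alpha-hat) (the evolutionary variance).  A focal species' deviation is
scored as Z = (x_focal - mu-hat)/sqrt(v-hat) with a two-sided normal p; genes
are flagged when |Z| exceeds the threshold and p is below its threshold.
q-values are reported but the |Z|/p rule is the operative flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .io import Phylogeny
from .ou import GeneFit, SIGMA2_FLOOR, classify_selection, fit_genes
from .stats import bh_fdr

__all__ = [
    "EvolutionaryMoments",
    "evolutionary_moments",
    "score_outliers",
    "intersect_gene_sets",
]


@dataclass(frozen=True)
class EvolutionaryMoments:
    mean: float  # theta-hat, log2-CPM
    variance: float  # sigma2-hat / (2 alpha-hat)
    usable: bool


def evolutionary_moments(fit: GeneFit) -> EvolutionaryMoments:
    """Evolutionary mean and stationary variance of a fitted OU1 gene.

    Refuses BM fits (no finite stationary variance exists; use the BM root
    state and sigma2*T directly if needed).  Degenerate fits (sigma2 at its
    floor) are returned flagged unusable.
    """
    if fit.model != "OU1":
        raise ValueError(
            f"evolutionary moments are defined for OU1 fits, got {fit.model}; "
            "a BM gene has no stationary variance"
        )
    usable = not fit.degenerate and fit.params.sigma2 > SIGMA2_FLOOR
    v = fit.params.sigma2 / (2.0 * fit.params.alpha)
    return EvolutionaryMoments(mean=fit.params.x0, variance=v, usable=usable)


def score_outliers(
    tree: Phylogeny,
    species_means: pd.DataFrame,
    focal: str,
    fits_bm: dict[str, GeneFit] | None = None,
    fits_ou: dict[str, GeneFit] | None = None,
    min_mean_cpm: float = 5.0,
    z_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr: float = 0.05,
    leave_one_out: bool = False,
    tip_variance: bool = False,
) -> pd.DataFrame:
    """Z-score the focal species' expression against each gene's fitted
    evolutionary mean and variance.

    Genes are restricted to OU-preferred fits (OU1 vs BM at q < fdr) whose
    back-transformed evolutionary mean is at least ``min_mean_cpm``.  By
    default the focal species participates in the fit; ``leave_one_out``
    refits on the pruned tree for sensitivity analysis.  ``tip_variance``
    replaces the stationary variance with the model's tip variance
    sigma2/(2 alpha) (1 - e^{-2 alpha T}).
    """
    if focal not in species_means.columns:
        raise ValueError(f"focal species {focal!r} absent from matrix")
    if focal not in tree.tip_labels:
        raise ValueError(f"focal species {focal!r} absent from tree")

    if fits_bm is None or fits_ou is None:
        fits_bm = fit_genes(tree, species_means, "BM")
        fits_ou = fit_genes(tree, species_means, "OU1")
    cls = classify_selection(fits_bm, fits_ou, fdr=fdr).set_index("gene")

    moment_fits = fits_ou
    if leave_one_out:
        import dendropy

        pruned = tree.dendropy_tree.clone(depth=1)
        pruned.prune_taxa_with_labels([focal])
        ptree = Phylogeny(pruned)
        moment_fits = fit_genes(
            ptree, species_means.drop(columns=[focal]), "OU1")

    rows = []
    for gene in species_means.index:
        fit = moment_fits[gene]
        mom = evolutionary_moments(fit)
        ou_pass = bool(cls.loc[gene, "q"] < fdr) and mom.usable
        cpm_pass = bool(2.0 ** mom.mean >= min_mean_cpm)
        v = mom.variance
        if tip_variance:
            a = fit.params.alpha
            v = v * -np.expm1(-2.0 * a * tree.depth)
        x = float(species_means.loc[gene, focal])
        z = (x - mom.mean) / np.sqrt(v) if mom.usable and v > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "gene": gene, "focal": focal, "x_focal": x,
            "evolutionary_mean": mom.mean, "evolutionary_variance": v,
            "z": z, "p": p, "ou_pass": ou_pass, "cpm_pass": cpm_pass,
        })
    out = pd.DataFrame(rows)
    scored = out["ou_pass"] & out["cpm_pass"] & out["z"].notna()
    out["scored"] = scored
    out["q"] = np.nan
    if scored.any():
        out.loc[scored, "q"] = bh_fdr(out.loc[scored, "p"].to_numpy())
    out["outlier"] = (
        scored & (out["z"].abs() > z_threshold) & (out["p"] < p_threshold)
    )
    return out


def intersect_gene_sets(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes over every non-empty combination of sets
    (the counts behind an UpSet plot), plus per-set totals in ``attrs``.

    Each gene is counted once, under exactly the combination of sets it
    belongs to; exclusive counts therefore sum to the size of the union.
    """
    if not sets:
        raise ValueError("at least one set is required")
    names = list(sets)
    membership: dict[str, tuple] = {}
    for gene in set().union(*sets.values()):
        key = tuple(n for n in names if gene in sets[n])
        membership.setdefault(key, []).append(gene)
    rows = [
        {"combination": "&".join(key), "degree": len(key),
         "count": len(genes)}
        for key, genes in membership.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["degree", "combination"]).reset_index(drop=True)
    out.attrs["set_totals"] = {n: len(sets[n]) for n in names}
    return out
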