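"""Count filtering, TMM normalization to log2-CPM, variable-gene selection,
and species-mean aggregation.

TMM (trimmed mean of M-values) computes a per-library composition factor
against a reference library: per gene, M is the log2 expression ratio and A
the average log2 abundance; genes in the extreme 30% of M or 5% of A are
trimmed and the rest averaged with inverse asymptotic-variance weights.
Factors are rescaled to unit geometric mean so they are pure composition
corrections on top of library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .io import ExpressionMatrix, SampleTable, ValidationError

__all__ = [
    "NormalizedExpression",
    "SpeciesExpression",
    "filter_expressed",
    "tmm_factors",
    "log_cpm",
    "cpm",
    "top_variable_genes",
    "species_means",
]

TMM_TRIM_M = 0.30  # two-sided trim fraction on M-values
TMM_TRIM_A = 0.05  # two-sided trim fraction on A-values


def filter_expressed(
    counts: ExpressionMatrix, min_count: float = 1, min_cpm: float = 1.0
) -> ExpressionMatrix:
    """Keep genes with count >= min_count AND CPM > min_cpm in every sample.

    CPM here is computed on raw library sizes (the filter runs before
    normalization).  Gene order is preserved; an empty result warns rather
    than fails.
    """
    if counts.scale != "counts":
        raise ValidationError("filter_expressed requires a counts matrix")
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    cpm_mat = arr / lib[None, :] * 1e6
    keep = (arr >= min_count).all(axis=1) & (cpm_mat > min_cpm).all(axis=1)
    if not keep.any():
        warnings.warn("no genes pass the expression filter", UserWarning,
                      stacklevel=2)
    return ExpressionMatrix(counts.values.loc[keep], scale="counts")


def _pick_reference(arr: np.ndarray, samples) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper-quartile."""
    lib = arr.sum(axis=0)
    f75 = np.array([
        np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])
    ])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_one(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
             lib_ref: float) -> float:
    """TMM factor of one library against the reference (log2 scale inside)."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    p_o, p_r = o / lib_obs, r / lib_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M per gene
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = M.size
    if n == 0:
        return 1.0
    lo_m = np.floor(n * TMM_TRIM_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * TMM_TRIM_A) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(M)
    rank_a = sps.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = (M[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: ExpressionMatrix, reference_sample: str = "auto"
) -> pd.Series:
    """Per-sample TMM factors, rescaled to unit geometric mean.

    ``reference_sample='auto'`` picks the sample whose upper-quartile CPM is
    closest to the across-sample mean upper-quartile.
    """
    if counts.scale != "counts":
        raise ValidationError("tmm_factors requires a counts matrix")
    if len(counts.samples) < 2:
        raise ValidationError("TMM requires at least two samples")
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("zero library size")
    if reference_sample == "auto":
        ref_j = _pick_reference(arr, counts.samples)
    else:
        if reference_sample not in counts.samples:
            raise ValidationError(f"unknown reference sample {reference_sample!r}")
        ref_j = counts.samples.index(reference_sample)
    factors = np.array([
        _tmm_one(arr[:, j], arr[:, ref_j], lib[j], lib[ref_j])
        for j in range(arr.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


@dataclass
class NormalizedExpression:
    """log2-CPM matrix with the TMM factors and effective library sizes
    that produced it."""

    log2cpm: pd.DataFrame
    factors: pd.Series
    effective_lib_sizes: pd.Series
    prior_count: float

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError("factors must have unit geometric mean")

    def as_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.log2cpm, scale="log2cpm")


def cpm(counts: ExpressionMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over effective (factor-scaled) library sizes."""
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if factors is not None:
        lib = lib * factors.loc[counts.samples].to_numpy()
    return pd.DataFrame(arr / lib[None, :] * 1e6,
                        index=counts.genes, columns=counts.samples)


def log_cpm(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> NormalizedExpression:
    """log2-CPM with a prior count: log2((c + prior)/(L_eff + 2 prior) * 1e6).

    The prior keeps zero counts finite; L_eff is library size times the TMM
    factor (unit factors when none are given).
    """
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if factors is None:
        factors = pd.Series(1.0, index=counts.samples)
    eff = lib * factors.loc[counts.samples].to_numpy()
    vals = np.log2((arr + prior_count) / (eff[None, :] + 2 * prior_count) * 1e6)
    return NormalizedExpression(
        log2cpm=pd.DataFrame(vals, index=counts.genes, columns=counts.samples),
        factors=factors.loc[counts.samples],
        effective_lib_sizes=pd.Series(eff, index=counts.samples),
        prior_count=prior_count,
    )


def top_variable_genes(expr: pd.DataFrame, n: int = 500) -> list[str]:
    """The n most variably expressed genes by standard deviation across
    samples, descending; ties broken by gene id."""
    if n > expr.shape[0]:
        raise ValidationError(f"requested {n} genes, matrix has {expr.shape[0]}")
    sd = expr.std(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-sd[g], g))
    return order[:n]


@dataclass
class SpeciesExpression:
    """Gene x species mean log2-CPM with replicate counts and within-species
    variances (unbiased; absent where a species has a single replicate)."""

    means: pd.DataFrame  # genes x species
    n_reps: pd.Series  # per species
    variances: pd.DataFrame | None = None  # genes x species (NaN if n=1)

    @property
    def species(self) -> list[str]:
        return list(self.means.columns)

    def within(self) -> pd.DataFrame:
        """Measurement variance of each species mean, s_i^2 / n_i.

        Zero where a species has one replicate (no estimate available).
        """
        if self.variances is None:
            return pd.DataFrame(0.0, index=self.means.index,
                                columns=self.means.columns)
        w = self.variances.div(self.n_reps, axis=1)
        return w.fillna(0.0)


def species_means(
    expr: pd.DataFrame,
    metadata: SampleTable,
    region: str | None = None,
) -> SpeciesExpression:
    """Per-species arithmetic means of log2-CPM, optionally within a region."""
    meta = metadata.table
    samples = [s for s in expr.columns if s in meta.index]
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[samples]
    if region is not None:
        keep = meta["region"] == region
        if not keep.any():
            raise ValidationError(f"no samples in region {region!r}")
        meta = meta.loc[keep]
        samples = list(meta.index)
    sub = expr[samples]
    groups = meta["species"]
    means = sub.T.groupby(groups).mean().T
    n = groups.value_counts().reindex(means.columns)
    var = sub.T.groupby(groups).var(ddof=1).T
    return SpeciesExpression(means=means, n_reps=n, variances=var)
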