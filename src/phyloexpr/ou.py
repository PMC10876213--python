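"""Ornstein-Uhlenbeck and Brownian-motion models of expression evolution.

Per-gene species-mean expression x (log2-CPM) is modelled as a multivariate
normal over the tips of a rooted time tree:

- **BM** (neutral drift): mean x0 * 1, covariance sigma2 * t_a(i, j), where
  t_a is the shared root-to-MRCA time.
- **OU** (stabilizing selection, root conditioned at the root optimum):
  dx = -alpha (x - theta) dt + sigma dW with x(0) = theta_root; the tip mean
  is the Hansen weighting of the regime optima along each tip's root path and
  the covariance is

      V_ij = sigma2/(2 alpha) * exp(-alpha ((d_i - t_a) + (d_j - t_a)))
                               * (1 - exp(-2 alpha t_a)),

  which reduces to the familiar ultrametric form
  sigma2/(2 alpha) e^{-2 alpha (T - t_a)} (1 - e^{-2 alpha t_a}) and to the BM
  covariance in the alpha -> 0 limit.  This root-conditioned variant nests BM
  exactly, so the OU-vs-BM likelihood-ratio test is well defined; the
  stationary-root variant is available via ``stationary_root=True`` and is
  documented as non-nested.

Optima are profiled out by generalized least squares given alpha; sigma2 is
concentrated analytically when no within-species variances are supplied and
optimized numerically otherwise.  alpha is maximized over a 40-point log grid
on [1e-3/T, 1e2/T] followed by bounded refinement.  Likelihoods carry full
constants, so AIC/BIC and likelihood-ratio tests are comparable across
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats as sps
from scipy.optimize import minimize_scalar

from .io import Phylogeny
from .stats import bh_fdr

__all__ = [
    "RegimePainting",
    "OUParams",
    "GeneFit",
    "ou_covariance",
    "bm_covariance",
    "regime_weights",
    "fit_gene",
    "fit_genes",
    "compare_models",
    "classify_selection",
    "de_by_regime",
    "msd_vs_distance",
    "SIGMA2_FLOOR",
    "ALPHA_GRID_SIZE",
]

SIGMA2_FLOOR = 1e-12
ALPHA_GRID_SIZE = 40
_ALPHA_NEAR_ZERO = 1e-9  # in units of 1/T: boundary point that recovers BM


# ---------------------------------------------------------------------------
# Regime paintings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimePainting:
    """Assignment of a selective regime to every tree edge.

    Edges are identified by their child node id (tip label or internal node
    id as assigned by :class:`~phyloexpr.io.Phylogeny`).  The root itself
    carries ``root_regime``, which by convention is the background (ancestral)
    regime when a focal shift is painted.
    """

    edge_regimes: dict
    root_regime: str

    def regimes(self) -> list[str]:
        others = sorted(set(self.edge_regimes.values()) - {self.root_regime})
        return [self.root_regime] + others

    def validate(self, tree: Phylogeny) -> None:
        missing = [e for e in tree.edge_ids if e not in self.edge_regimes]
        if missing:
            raise ValueError(f"unpainted edges: {missing[:5]}")
        unknown = [e for e in self.edge_regimes if e not in tree.edge_ids]
        if unknown:
            raise ValueError(f"painting references unknown edges: {unknown[:5]}")

    @classmethod
    def single(cls, tree: Phylogeny, label: str = "all") -> "RegimePainting":
        return cls({e: label for e in tree.edge_ids}, root_regime=label)

    @classmethod
    def focal_clade(
        cls,
        tree: Phylogeny,
        focal_tips,
        focal_label: str = "focal",
        background_label: str = "background",
    ) -> "RegimePainting":
        """Paint the edges of the clade spanned by ``focal_tips`` as focal.

        An edge is focal iff every tip below it is in the focal set; the root
        regime is the background.  A single species paints its terminal edge.
        """
        focal = set(focal_tips)
        unknown = focal - set(tree.tip_labels)
        if unknown:
            raise ValueError(f"focal tips not in tree: {sorted(unknown)}")
        if focal == set(tree.tip_labels):
            raise ValueError("focal regime covers all tips: degenerate contrast")
        edge_regimes = {}
        tipsets = _edge_tipsets(tree)
        for edge in tree.edge_ids:
            below = tipsets[edge]
            edge_regimes[edge] = (
                focal_label if below <= focal else background_label
            )
        return cls(edge_regimes, root_regime=background_label)


def _edge_tipsets(tree: Phylogeny) -> dict:
    """Map each edge (child node id) to the set of tip labels below it."""
    out = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            out[node._pid] = {node._pid}
        else:
            out[node._pid] = set().union(*(out[c._pid] for c in node.child_nodes()))
    return out


# ---------------------------------------------------------------------------
# Covariance and mean structure
# ---------------------------------------------------------------------------

def bm_covariance(tree: Phylogeny, sigma2: float) -> pd.DataFrame:
    """BM tip covariance: V_ij = sigma2 * t_a(i, j)."""
    return sigma2 * tree.mrca_times


def ou_covariance(
    tree: Phylogeny,
    alpha: float,
    sigma2: float,
    within: pd.Series | None = None,
    stationary_root: bool = False,
) -> pd.DataFrame:
    """Root-conditioned OU tip covariance; optional within-species term.

    ``within`` is a per-tip measurement variance s_i^2/n_i added to the
    diagonal.  ``stationary_root=True`` instead draws the root from the
    stationary distribution, dropping the (1 - e^{-2 alpha t_a}) depletion
    (this variant does not nest BM).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive; use bm_covariance for alpha=0")
    ta = tree.mrca_times.to_numpy()
    d = tree.depths.to_numpy()
    decay = np.exp(-alpha * (d[:, None] - ta) - alpha * (d[None, :] - ta))
    if stationary_root:
        v = sigma2 / (2.0 * alpha) * decay
    else:
        # -expm1(-2 a t)/(2 a) -> t as a -> 0: numerically exact BM limit
        v = sigma2 * decay * (-np.expm1(-2.0 * alpha * ta)) / (2.0 * alpha)
    mat = pd.DataFrame(v, index=tree.tip_labels, columns=tree.tip_labels)
    if within is not None:
        mat = mat.add(pd.DataFrame(np.diag(within.loc[tree.tip_labels]),
                                   index=tree.tip_labels,
                                   columns=tree.tip_labels))
    return mat


def regime_weights(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> pd.DataFrame:
    """Hansen weight matrix W (tips x regimes); tip mean = W @ theta.

    Each segment [t_b, t_e] on a tip's root path contributes
    e^{-alpha (d_i - t_e)} - e^{-alpha (d_i - t_b)} to its regime's column;
    the root contributes e^{-alpha d_i} to the root regime.  Rows telescope
    to 1 for every alpha > 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    painting.validate(tree)
    regimes = painting.regimes()
    r_index = {r: k for k, r in enumerate(regimes)}
    W = np.zeros((len(tree), len(regimes)))
    for i, tip in enumerate(tree.tip_labels):
        d_i = tree.depths[tip]
        W[i, r_index[painting.root_regime]] += np.exp(-alpha * d_i)
        for t_b, t_e, edge in tree.root_paths[tip]:
            k = r_index[painting.edge_regimes[edge]]
            W[i, k] += np.exp(-alpha * (d_i - t_e)) - np.exp(-alpha * (d_i - t_b))
    return pd.DataFrame(W, index=tree.tip_labels, columns=regimes)


# ---------------------------------------------------------------------------
# Maximum likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class OUParams:
    alpha: float  # selection strength, 1/time (0 for BM)
    sigma2: float  # drift variance per time
    theta: dict  # regime label -> optimum (BM: {"x0": root state})
    x0: float  # root state; equals theta[root regime] for OU


@dataclass
class GeneFit:
    model: str  # "BM" | "OU1" | "OU-regime"
    params: OUParams
    lnL: float
    n_params: int
    n_tips: int
    converged: bool = True
    degenerate: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.lnL

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_tips) - 2 * self.lnL


def _mvn_profile(
    C: np.ndarray, X: np.ndarray, x: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Profile lnL for x ~ N(X beta, sigma2 C) with sigma2 concentrated.

    Returns (lnL, beta_hat, sigma2_hat).  Rank-deficient designs (e.g. a
    regime whose weights vanish as alpha -> 0) are resolved by least squares.
    """
    n = x.size
    cho = sla.cho_factor(C, lower=True)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    Ci_X = sla.cho_solve(cho, X)
    Ci_x = sla.cho_solve(cho, x)
    XtCiX = X.T @ Ci_X
    XtCix = X.T @ Ci_x
    beta, *_ = np.linalg.lstsq(XtCiX, XtCix, rcond=None)
    r = x - X @ beta
    q = float(r @ sla.cho_solve(cho, r))
    sigma2 = max(q / n, SIGMA2_FLOOR)
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + q / sigma2)
    return lnL, beta, sigma2


def _mvn_fixed(
    C_of_sigma2, X: np.ndarray, x: np.ndarray, sigma2: float
) -> tuple[float, np.ndarray]:
    """lnL for x ~ N(X beta, V(sigma2)) with beta GLS'd, sigma2 given."""
    n = x.size
    V = C_of_sigma2(sigma2)
    cho = sla.cho_factor(V, lower=True)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    Ci_X = sla.cho_solve(cho, X)
    Ci_x = sla.cho_solve(cho, x)
    beta, *_ = np.linalg.lstsq(X.T @ Ci_X, X.T @ Ci_x, rcond=None)
    r = x - X @ beta
    q = float(r @ sla.cho_solve(cho, r))
    lnL = -0.5 * (n * np.log(2 * np.pi) + logdet + q)
    return lnL, beta


def _fit_given_structure(C, X, x, within):
    """Fit (lnL, beta, sigma2) for covariance sigma2*C + diag(within)."""
    if within is None:
        return _mvn_profile(C, X, x)
    D = np.diag(within)

    def vmat(s2):
        return s2 * C + D

    var0 = max(float(np.var(x)), 1e-8)
    lo, hi = np.log(SIGMA2_FLOOR), np.log(var0 * 1e4)

    def neg(logs2):
        return -_mvn_fixed(vmat, X, x, np.exp(logs2))[0]

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    s2 = float(np.exp(res.x))
    lnL, beta = _mvn_fixed(vmat, X, x, s2)
    return lnL, beta, s2


class GeneFitter:
    """Shared-structure ML fitter for one tree (and optional painting).

    Caches the alpha grid's covariance/weight structures so that fitting many
    genes on the same tree reuses the per-alpha Cholesky factors.  Only valid
    when no within-species variances are supplied (those make the covariance
    gene-specific).
    """

    def __init__(self, tree: Phylogeny, painting: RegimePainting | None = None):
        self.tree = tree
        self.painting = painting
        self.n = len(tree)
        T = tree.depth
        grid = np.geomspace(1e-3 / T, 1e2 / T, ALPHA_GRID_SIZE)
        self.alpha_grid = np.concatenate([[_ALPHA_NEAR_ZERO / T], grid])
        self._cache: dict[float, tuple] = {}
        self._ta = tree.mrca_times.to_numpy()
        self._ones = np.ones((self.n, 1))

    def _design(self, alpha: float) -> np.ndarray:
        if self.painting is None:
            return self._ones
        return regime_weights(self.tree, self.painting, alpha).to_numpy()

    def _corr(self, alpha: float) -> np.ndarray:
        return ou_covariance(self.tree, alpha, 1.0).to_numpy()

    def _structures(self, alpha: float):
        key = float(alpha)
        if key not in self._cache:
            self._cache[key] = (self._corr(alpha), self._design(alpha))
        return self._cache[key]

    def profile_lnL(self, alpha: float, x: np.ndarray):
        C, X = self._structures(alpha)
        return _mvn_profile(C, X, x)

    def fit_bm(self, x: np.ndarray) -> GeneFit:
        lnL, beta, s2 = _mvn_profile(self._ta, self._ones, x)
        degenerate = s2 <= SIGMA2_FLOOR
        x0 = float(beta[0])
        return GeneFit("BM", OUParams(0.0, s2, {"x0": x0}, x0), lnL,
                       n_params=2, n_tips=self.n, degenerate=degenerate)

    def fit_ou(self, x: np.ndarray) -> GeneFit:
        lnLs = np.array([self.profile_lnL(a, x)[0] for a in self.alpha_grid])
        best = int(np.argmax(lnLs))
        a_best = self.alpha_grid[best]
        # bounded refinement between neighbouring grid points, in log-alpha
        lo = self.alpha_grid[max(best - 1, 0)]
        hi = self.alpha_grid[min(best + 1, len(self.alpha_grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda la: -self.profile_lnL(np.exp(la), x)[0],
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-7},
            )
            a_ref = float(np.exp(res.x))
            if -res.fun > lnLs[best]:
                a_best = a_ref
        lnL, beta, s2 = self.profile_lnL(a_best, x)
        regimes = (self.painting.regimes() if self.painting is not None
                   else ["all"])
        theta = {r: float(b) for r, b in zip(regimes, np.atleast_1d(beta))}
        root_reg = (self.painting.root_regime if self.painting is not None
                    else "all")
        model = "OU-regime" if self.painting is not None and len(regimes) > 1 \
            else "OU1"
        k = 2 + len(regimes)
        return GeneFit(model, OUParams(float(a_best), s2, theta, theta[root_reg]),
                       lnL, n_params=k, n_tips=self.n,
                       degenerate=s2 <= SIGMA2_FLOOR)


def fit_gene(
    tree: Phylogeny,
    x: pd.Series,
    model: str,
    painting: RegimePainting | None = None,
    within: pd.Series | None = None,
) -> GeneFit:
    """Maximum-likelihood fit of one gene's tip values under one model.

    ``x`` must be indexed by tip label.  ``within`` supplies per-tip
    measurement variances s_i^2/n_i added to the covariance diagonal.
    """
    xv = x.loc[tree.tip_labels].to_numpy(dtype=float)
    if not np.isfinite(xv).all():
        raise ValueError("non-finite values in tip data")
    if len(tree) < 4:
        warnings.warn("fewer than 4 tips: estimates will be unstable",
                      UserWarning, stacklevel=2)
    w = None
    if within is not None:
        w = within.loc[tree.tip_labels].to_numpy(dtype=float)
        if not w.any():
            w = None

    n = len(tree)
    if model == "BM":
        C = tree.mrca_times.to_numpy()
        lnL, beta, s2 = _fit_given_structure(C, np.ones((n, 1)), xv, w)
        x0 = float(beta[0])
        return GeneFit("BM", OUParams(0.0, s2, {"x0": x0}, x0), lnL,
                       n_params=2, n_tips=n, degenerate=s2 <= SIGMA2_FLOOR)

    if model not in ("OU1", "OU-regime"):
        raise ValueError(f"unknown model {model!r}")
    if model == "OU1":
        painting = None
    elif painting is None:
        raise ValueError("OU-regime requires a painting")

    if w is None:
        fitter = GeneFitter(tree, painting)
        return fitter.fit_ou(xv)

    # within-variance path: covariance is gene specific, optimize per alpha
    T = tree.depth
    grid = np.concatenate([[_ALPHA_NEAR_ZERO / T],
                           np.geomspace(1e-3 / T, 1e2 / T, ALPHA_GRID_SIZE)])

    def eval_alpha(a):
        C = ou_covariance(tree, a, 1.0).to_numpy()
        X = (regime_weights(tree, painting, a).to_numpy()
             if painting is not None else np.ones((n, 1)))
        return _fit_given_structure(C, X, xv, w), X

    results = [eval_alpha(a)[0][0] for a in grid]
    best = int(np.argmax(results))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    a_best = grid[best]
    if hi > lo:
        res = minimize_scalar(lambda la: -eval_alpha(np.exp(la))[0][0],
                              bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-7})
        if -res.fun > results[best]:
            a_best = float(np.exp(res.x))
    (lnL, beta, s2), X = eval_alpha(a_best)
    regimes = painting.regimes() if painting is not None else ["all"]
    theta = {r: float(b) for r, b in zip(regimes, np.atleast_1d(beta))}
    root_reg = painting.root_regime if painting is not None else "all"
    mdl = "OU-regime" if painting is not None and len(regimes) > 1 else "OU1"
    return GeneFit(mdl, OUParams(float(a_best), s2, theta, theta[root_reg]),
                   lnL, n_params=2 + len(regimes), n_tips=n,
                   degenerate=s2 <= SIGMA2_FLOOR)


def fit_genes(
    tree: Phylogeny,
    expr: pd.DataFrame,
    model: str,
    painting: RegimePainting | None = None,
    within: pd.DataFrame | None = None,
) -> dict[str, GeneFit]:
    """Fit every row (gene) of a gene x species matrix under one model.

    Shares per-alpha covariance structures across genes when no
    within-species variances are given.
    """
    expr = expr[tree.tip_labels]
    if within is not None:
        return {
            g: fit_gene(tree, expr.loc[g], model, painting,
                        within.loc[g] if g in within.index else None)
            for g in expr.index
        }
    if model == "BM":
        fitter = GeneFitter(tree, None)
        return {g: fitter.fit_bm(expr.loc[g].to_numpy(dtype=float))
                for g in expr.index}
    fitter = GeneFitter(tree, painting if model == "OU-regime" else None)
    return {g: fitter.fit_ou(expr.loc[g].to_numpy(dtype=float))
            for g in expr.index}


# ---------------------------------------------------------------------------
# Model comparison and classification
# ---------------------------------------------------------------------------

def compare_models(fit_null: GeneFit, fit_alt: GeneFit, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: Lambda = 2 (lnL_alt - lnL_null).

    p is the chi-square(df) upper tail; testing alpha on its boundary makes
    this conservative relative to the point-mass/chi-square mixture.
    """
    lam = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if lam < -1e-6:
        raise RuntimeError(
            f"alternative lnL below null ({fit_alt.lnL} < {fit_null.lnL}): "
            "optimizer contract breach"
        )
    lam = max(lam, 0.0)
    return lam, float(sps.chi2.sf(lam, df))


def classify_selection(
    fits_bm: dict[str, GeneFit],
    fits_ou: dict[str, GeneFit],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Stabilizing-selection vs drift verdict per gene (OU1 vs BM LRT, BH).

    Genes whose OU fit does not improve on BM by both AIC and BIC are marked
    ``aic_bic_pass=False`` and are excluded from downstream regime analyses.
    """
    genes = list(fits_bm)
    rows = []
    for g in genes:
        lam, p = compare_models(fits_bm[g], fits_ou[g], df=1)
        rows.append({
            "gene": g,
            "lnL_bm": fits_bm[g].lnL,
            "lnL_ou": fits_ou[g].lnL,
            "lrt": lam,
            "p": p,
            "aic_bic_pass": (fits_ou[g].aic < fits_bm[g].aic)
                            and (fits_ou[g].bic < fits_bm[g].bic),
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["classification"] = np.where(out["q"] < fdr, "stabilizing", "drift")
    out.attrs["fraction_stabilizing"] = float(
        (out["classification"] == "stabilizing").mean()
    )
    return out


def de_by_regime(
    tree: Phylogeny,
    species_expr: pd.DataFrame,
    painting: RegimePainting,
    fdr: float = 0.05,
    focal_regime: str | None = None,
    within: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regime-based differential expression: OU-regime vs BM per gene.

    Returns per gene the primary LRT (regime-OU vs BM, df = K regimes), the
    secondary contrast vs the single-optimum OU (df = K - 1), BH q-values,
    and the direction of the focal shift (sign of theta_focal - mean of the
    other optima).  Gene sets at q < fdr feed UpSet intersection counts.
    """
    regimes = painting.regimes()
    K = len(regimes)
    if K < 2:
        raise ValueError("painting defines a single regime: nothing to contrast")
    if focal_regime is None:
        non_root = [r for r in regimes if r != painting.root_regime]
        focal_regime = non_root[0]
    fits_bm = fit_genes(tree, species_expr, "BM", within=within)
    fits_ou1 = fit_genes(tree, species_expr, "OU1", within=within)
    fits_reg = fit_genes(tree, species_expr, "OU-regime", painting, within=within)
    rows = []
    for g in species_expr.index:
        fb, f1, fr = fits_bm[g], fits_ou1[g], fits_reg[g]
        # warm-start guarantee: the regime design spans the constant mean, so
        # at OU1's alpha the regime profile is at least OU1's; enforce it
        if fr.lnL < f1.lnL:
            fitter = GeneFitter(tree, painting)
            lnL, beta, s2 = fitter.profile_lnL(
                max(f1.params.alpha, _ALPHA_NEAR_ZERO / tree.depth),
                species_expr.loc[g, tree.tip_labels].to_numpy(dtype=float),
            )
            if lnL > fr.lnL:
                theta = {r: float(b) for r, b in zip(regimes, beta)}
                fr = GeneFit("OU-regime",
                             OUParams(f1.params.alpha, s2, theta,
                                      theta[painting.root_regime]),
                             lnL, n_params=2 + K, n_tips=len(tree))
        lam_bm, p_bm = compare_models(fb, fr, df=K)
        lam_ou1, p_ou1 = compare_models(f1, fr, df=K - 1)
        th = fr.params.theta
        background = np.mean([th[r] for r in regimes if r != focal_regime])
        delta = th[focal_regime] - background
        rows.append({
            "gene": g,
            "lrt_vs_bm": lam_bm, "p_vs_bm": p_bm,
            "lrt_vs_ou1": lam_ou1, "p_vs_ou1": p_ou1,
            "theta_focal": th[focal_regime],
            "theta_background": float(background),
            "delta_theta": float(delta),
            "direction": "up" if delta > 0 else ("down" if delta < 0 else "none"),
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p_vs_bm"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def de_gene_sets(de_table: pd.DataFrame) -> dict[str, set]:
    """Significant gene sets (all/up/down) from a DE table, for UpSet counts."""
    sig = de_table[de_table["significant"]]
    return {
        "all": set(sig["gene"]),
        "up": set(sig.loc[sig["direction"] == "up", "gene"]),
        "down": set(sig.loc[sig["direction"] == "down", "gene"]),
    }


# ---------------------------------------------------------------------------
# Divergence vs evolutionary distance
# ---------------------------------------------------------------------------

def msd_vs_distance(
    species_expr: pd.DataFrame,
    tree: Phylogeny,
    reference_species: str,
) -> pd.DataFrame:
    """Mean squared expression difference of each species to a reference,
    paired with its patristic distance to that reference.

    Under BM, E[(x_ref - x_s)^2] = sigma2 * d(ref, s), so the curve rises
    linearly with distance for neutrally evolving genes.
    """
    if reference_species not in species_expr.columns:
        raise ValueError(f"reference {reference_species!r} absent from matrix")
    dist = tree.patristic_distances()[reference_species]
    ref = species_expr[reference_species]
    rows = []
    for sp in species_expr.columns:
        msd = float(((species_expr[sp] - ref) ** 2).mean())
        rows.append({"species": sp, "distance": float(dist[sp]), "msd": msd})
    return pd.DataFrame(rows)
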