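"""Synthetic expression data with the statistical structure the pipeline
assumes: species-mean log2-CPM evolving on a tree under BM or OU (optionally
with regime-specific optima), within-species replicate noise, negative-
binomial count sampling with unequal library sizes, and a planted gene module
linearly coupled to a species trait.

Simulation is defined on the log2-CPM scale, where the downstream OU fits
operate, and optionally mapped to counts.  Every output is fully determined
by (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Phylogeny, SampleTable, TraitTable
from .ou import RegimePainting, bm_covariance, ou_covariance, regime_weights

__all__ = [
    "GeneSimSpec",
    "TruthTable",
    "simulate_expression",
    "sample_counts",
    "plant_trait_module",
    "make_specs",
    "make_metadata",
    "primate_tree",
    "birth_tree",
    "PRIMATE_NEWICK",
    "HOMINOIDS",
    "STREPSIRRHINES",
]


# 18-tip primate topology (5 hominoids, 4 cercopithecoids, 4 platyrrhines,
# 5 strepsirrhines), ultrametric with branch lengths in Myr; synthetic
# consensus-style time calibration, assembled clade by clade.
_HOMINOIDS_NWK = "((((Human:7,Chimpanzee:7):2,Gorilla:9):7,Orangutan:16):4,Siamang:20)"
_CERCOPITHECOIDS_NWK = "(Colobus:18,(Vervet:14,(Rhesus:12,Baboon:12):2):4)"
_PLATYRRHINES_NWK = "(Marmoset:16,(SquirrelMonkey:14,(Capuchin:12,OwlMonkey:12):2):2)"
_STREPSIRRHINES_NWK = (
    "(Galago:69,(AyeAye:59,(MouseLemur:38,"
    "(RingtailedLemur:18,BlackLemur:18):20):21):10)"
)
PRIMATE_NEWICK = (
    f"((({_HOMINOIDS_NWK}:10,{_CERCOPITHECOIDS_NWK}:12):13,"
    f"{_PLATYRRHINES_NWK}:27):31,{_STREPSIRRHINES_NWK}:5);"
)

HOMINOIDS = ("Human", "Chimpanzee", "Gorilla", "Orangutan", "Siamang")
STREPSIRRHINES = ("Galago", "AyeAye", "MouseLemur", "RingtailedLemur",
                  "BlackLemur")


def primate_tree() -> Phylogeny:
    """The bundled 18-species ultrametric primate tree (depth 74 Myr)."""
    return Phylogeny.from_newick(PRIMATE_NEWICK)


def birth_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Seeded pure-birth (Yule) ultrametric tree with ``n_tips`` tips."""
    import random

    from dendropy.model import birthdeath

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=rng,
    )
    return Phylogeny(tree)


@dataclass(frozen=True)
class GeneSimSpec:
    """Per-gene generative parameters.

    For OU genes, ``theta`` maps regime labels to optima (log2-CPM) and the
    root state defaults to the root regime's optimum, mirroring the fitting
    model.  ``within_sd`` is the replicate noise s; ``trait_offsets`` holds a
    per-species additive mean shift used by planted trait modules.
    """

    gene_id: str
    model: str  # "BM" | "OU"
    sigma2: float
    alpha: float = 0.0
    theta: dict = field(default_factory=dict)  # regime -> optimum
    x0: float = 0.0
    within_sd: float = 0.0
    painting_id: str = "single"
    trait_offsets: dict = field(default_factory=dict)  # species -> shift
    trait_module: bool = False

    def __post_init__(self):
        if self.model not in ("BM", "OU"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "OU" and self.alpha <= 0:
            raise ValueError("OU genes require alpha > 0")
        if self.sigma2 < 0 or self.within_sd < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class TruthTable:
    """Generative truth: per-gene specs plus realized species means."""

    specs: pd.DataFrame  # one row per gene
    species_means: pd.DataFrame  # genes x species
    library_sizes: pd.Series | None = None


def make_specs(
    n_genes: int,
    frac_ou: float = 0.5,
    alpha: float = 0.03,
    sigma2: float = 0.2,
    theta_mean: float = 5.0,
    theta_sd: float = 2.0,
    within_sd: float = 0.25,
    seed: int = 0,
    painting_id: str = "single",
) -> list[GeneSimSpec]:
    """Standard mixed BM/OU gene panel with gene-specific baseline levels.

    Baselines (root states / optima) are drawn around ``theta_mean`` so that
    genes span a realistic range of expression; the first
    ``round(frac_ou * n_genes)`` genes are OU, the rest BM.
    """
    rng = np.random.default_rng(seed)
    n_ou = int(round(frac_ou * n_genes))
    specs = []
    base = rng.normal(theta_mean, theta_sd, size=n_genes)
    for i in range(n_genes):
        gid = f"g{i + 1:05d}"
        if i < n_ou:
            specs.append(GeneSimSpec(gid, "OU", sigma2=sigma2, alpha=alpha,
                                     theta={"all": float(base[i])},
                                     x0=float(base[i]), within_sd=within_sd,
                                     painting_id=painting_id))
        else:
            specs.append(GeneSimSpec(gid, "BM", sigma2=sigma2,
                                     x0=float(base[i]), within_sd=within_sd,
                                     painting_id=painting_id))
    return specs


def _tip_moments(
    tree: Phylogeny, spec: GeneSimSpec, paintings: dict[str, RegimePainting]
) -> tuple[np.ndarray, np.ndarray]:
    """(mean vector, covariance matrix) of tip species-means for one gene."""
    if spec.model == "BM":
        mean = np.full(len(tree), spec.x0)
        cov = bm_covariance(tree, spec.sigma2).to_numpy()
        return mean, cov
    painting = paintings.get(spec.painting_id)
    if painting is None:
        if spec.painting_id != "single" or len(spec.theta) != 1:
            raise ValueError(f"unknown painting {spec.painting_id!r}")
        painting = RegimePainting.single(tree, next(iter(spec.theta)))
    W = regime_weights(tree, painting, spec.alpha)
    missing = [r for r in W.columns if r not in spec.theta]
    if missing:
        raise ValueError(f"spec {spec.gene_id}: no optimum for regimes {missing}")
    theta = np.array([spec.theta[r] for r in W.columns])
    mean = W.to_numpy() @ theta
    cov = ou_covariance(tree, spec.alpha, spec.sigma2).to_numpy()
    return mean, cov


def simulate_expression(
    tree: Phylogeny,
    specs: list[GeneSimSpec],
    reps_per_species: dict[str, int] | int,
    seed: int,
    paintings: dict[str, RegimePainting] | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw per-gene species means from the model-implied multivariate normal
    and expand them into replicate samples with Normal(0, s^2) noise.

    Sample ids are ``<species>_<replicate>``; a zero-variance gene (sigma2=0,
    s=0) reproduces its mean exactly in every sample.
    """
    paintings = paintings or {}
    if isinstance(reps_per_species, int):
        reps = {sp: reps_per_species for sp in tree.tip_labels}
    else:
        reps = dict(reps_per_species)
    unknown = set(reps) - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"replicate map references unknown tips: {sorted(unknown)}")
    if any(r < 1 for r in reps.values()):
        raise ValueError("at least one replicate per species is required")

    rng = np.random.default_rng(seed)
    species = tree.tip_labels
    sample_ids = [f"{sp}_{r + 1}" for sp in species for r in range(reps[sp])]
    sample_species = np.array([sp for sp in species for _ in range(reps[sp])])

    n_genes = len(specs)
    means = np.empty((n_genes, len(species)))
    values = np.empty((n_genes, len(sample_ids)))
    for gi, spec in enumerate(specs):
        mu, cov = _tip_moments(tree, spec, paintings)
        if spec.trait_offsets:
            mu = mu + np.array([spec.trait_offsets.get(sp, 0.0)
                                for sp in species])
        if spec.sigma2 > 0:
            # eigh-based sqrt: robust to the singular BM root (zero row/col)
            evals, evecs = np.linalg.eigh(cov)
            evals = np.clip(evals, 0.0, None)
            z = rng.standard_normal(len(species))
            x = mu + evecs @ (np.sqrt(evals) * z)
        else:
            x = mu.copy()
        means[gi] = x
        row = np.repeat(x, [reps[sp] for sp in species])
        if spec.within_sd > 0:
            row = row + rng.normal(0.0, spec.within_sd, size=row.size)
        values[gi] = row

    gene_ids = [s.gene_id for s in specs]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        scale="log2cpm",
    )
    spec_rows = pd.DataFrame([
        {
            "gene": s.gene_id, "model": s.model, "alpha": s.alpha,
            "sigma2": s.sigma2, "x0": s.x0, "within_sd": s.within_sd,
            "painting_id": s.painting_id, "trait_module": s.trait_module,
            "theta": ";".join(f"{k}={v:.6g}" for k, v in sorted(s.theta.items())),
        }
        for s in specs
    ]).set_index("gene", drop=False)
    truth = TruthTable(
        specs=spec_rows,
        species_means=pd.DataFrame(means, index=gene_ids, columns=species),
    )
    # keep the sample->species map retrievable from the matrix itself
    expr.values.attrs["species"] = dict(zip(sample_ids, sample_species))
    return expr, truth


def make_metadata(tree: Phylogeny, reps_per_species: dict[str, int] | int,
                  region: str = "PFC") -> SampleTable:
    """Metadata matching simulate_expression's sample naming."""
    if isinstance(reps_per_species, int):
        reps = {sp: reps_per_species for sp in tree.tip_labels}
    else:
        reps = dict(reps_per_species)
    rows = []
    for sp in tree.tip_labels:
        for r in range(reps[sp]):
            rows.append({
                "sample_id": f"{sp}_{r + 1}", "species": sp, "region": region,
                "individual": f"{sp}_ind{r + 1}", "sex": "NA", "age_class": "adult",
            })
    return SampleTable(pd.DataFrame(rows))


def sample_counts(
    log2cpm: ExpressionMatrix,
    library_sizes: pd.Series,
    dispersion: float,
    seed: int,
) -> ExpressionMatrix:
    """Negative-binomial count sampling from log2-CPM abundances.

    mean = 2^log2cpm * libsize / 1e6 and var = mean + dispersion * mean^2;
    dispersion 0 degenerates to Poisson.  -inf log2-CPM encodes zero CPM.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    lib = library_sizes.loc[log2cpm.samples].to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(seed)
    mu = np.exp2(log2cpm.values.to_numpy(dtype=float)) * lib[None, :] / 1e6
    mu = np.where(np.isfinite(mu), mu, 0.0)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / dispersion
        # NB as Gamma-Poisson mixture; zero-mean cells stay exactly zero
        lam = np.where(mu > 0, rng.gamma(size, 1.0, size=mu.shape) * mu / size, 0.0)
        counts = rng.poisson(lam)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=log2cpm.genes, columns=log2cpm.samples),
        scale="counts",
    )


def plant_trait_module(
    specs: list[GeneSimSpec],
    tree: Phylogeny,
    trait: TraitTable,
    k_genes: int,
    slope: float,
    seed: int,
) -> list[GeneSimSpec]:
    """Couple ``k_genes`` randomly chosen genes to log10 brain mass.

    Each planted gene's expected species mean becomes its baseline plus
    ``slope`` times the standardized log10 mass; membership is flagged so the
    truth table records the module.
    """
    if k_genes > len(specs):
        raise ValueError(f"k_genes={k_genes} exceeds the {len(specs)}-gene panel")
    missing = set(tree.tip_labels) - set(trait.table["species"])
    if missing:
        raise ValueError(f"trait table missing species: {sorted(missing)}")
    lm = trait.log10_mass().loc[tree.tip_labels]
    z = (lm - lm.mean()) / lm.std(ddof=0)
    offsets = (slope * z).to_dict()
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(specs), size=k_genes, replace=False).tolist())
    out = []
    for i, s in enumerate(specs):
        if i in chosen:
            out.append(replace(s, trait_offsets=offsets if slope != 0 else {},
                               trait_module=True))
        else:
            out.append(s)
    return out
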