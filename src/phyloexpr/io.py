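"""Trees, expression matrices, metadata and trait tables, plus config/logging.

The container types here are deliberately thin wrappers around pandas
DataFrames and a dendropy tree: they add ID validation, the time bookkeeping
the Ornstein-Uhlenbeck machinery needs (tip depths, root-to-MRCA times, root
paths with per-segment times), and lossless TSV round-trips with a provenance
header. All tabular I/O is TSV with '.' decimals, which keeps round-trips
locale-proof.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Phylogeny",
    "ExpressionMatrix",
    "SampleTable",
    "TraitTable",
    "TreeFormatError",
    "ValidationError",
    "read_tree",
    "read_counts",
    "read_metadata",
    "read_traits",
    "read_aliases",
    "write_table",
    "read_table",
    "load_config",
    "setup_logging",
    "BRAIN_REGIONS",
]

BRAIN_REGIONS = ("PFC", "V1", "HIP", "CBL")

logger = logging.getLogger("phyloexpr")


class TreeFormatError(ValueError):
    """Raised when a newick string cannot be parsed into a valid tree."""


class ValidationError(ValueError):
    """Raised when tabular inputs violate their contract (IDs, types, joins)."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path) -> dict:
    """Read a YAML key-value config file; an empty file yields {}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree with branch lengths, indexed for comparative analyses.

    Wraps a dendropy tree and precomputes, in a fixed tip order:

    - ``depths``: root-to-tip time for every tip,
    - ``mrca_times``: matrix of root-to-MRCA times t_a(i, j) (the diagonal is
      the tip's own depth),
    - root paths per tip as (start_time, end_time, edge_id) segments, used to
      build Hansen regime weight matrices.

    Internal nodes without labels are assigned stable generated ids so that
    regime paintings (edge ``child node id`` -> regime) are well defined.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise TreeFormatError("empty tree")
        self._tree = tree
        self._index()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=False,
                terminating_semicolon_required=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            pos = ""
            for attr in ("line_num", "col_num", "stream_offset"):
                val = getattr(exc, attr, None)
                if val is not None:
                    pos += f" {attr}={val}"
            raise TreeFormatError(f"unparseable newick:{pos or ''} {exc}") from exc
        return cls(tree)

    def _index(self) -> None:
        tree = self._tree
        # stable node ids: taxon label for tips, existing label or generated
        # for internal nodes
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeFormatError("tip without a label")
                node._pid = node.taxon.label
            else:
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    counter += 1
                    label = f"_node{counter}"
                node._pid = label
            if node.parent_node is not None and node.edge.length is None:
                raise TreeFormatError(
                    f"missing branch length on edge above node '{node._pid}'"
                )
            if node.parent_node is not None and node.edge.length < 0:
                raise TreeFormatError(
                    f"negative branch length on edge above node '{node._pid}'"
                )

        # depths (root->node times)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                node._depth = 0.0
            else:
                node._depth = node.parent_node._depth + node.edge.length

        tips = list(tree.leaf_node_iter())
        self.tip_labels: list[str] = [n._pid for n in tips]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeFormatError("duplicate tip labels")
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self.depths = pd.Series(
            [n._depth for n in tips], index=self.tip_labels, dtype=float
        )
        self.depth = float(self.depths.max())

        n = len(tips)
        # root-to-MRCA times via postorder sweep: when two tips first meet in
        # a common ancestor, that ancestor's depth is t_a(i, j)
        ta = np.full((n, n), np.nan)
        np.fill_diagonal(ta, self.depths.to_numpy())
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node._tipset = [self._tip_index[node._pid]]
                continue
            children = node.child_nodes()
            sets = [c._tipset for c in children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            ta[i, j] = ta[j, i] = node._depth
            node._tipset = [i for s in sets for i in s]
        self.mrca_times = pd.DataFrame(
            ta, index=self.tip_labels, columns=self.tip_labels
        )

        # root paths: per tip, segments (t_start, t_end, edge_id) from root
        self.root_paths: dict[str, list[tuple[float, float, str]]] = {}
        for tip in tips:
            segs = []
            node = tip
            while node.parent_node is not None:
                segs.append((node.parent_node._depth, node._depth, node._pid))
                node = node.parent_node
            segs.reverse()
            self.root_paths[tip.taxon.label] = segs
        self.edge_ids: list[str] = [
            n._pid for n in tree.preorder_node_iter() if n.parent_node is not None
        ]
        self.root_id: str = tree.seed_node._pid

        tol = 1e-6 * self.depth if self.depth > 0 else 1e-6
        self.is_ultrametric = bool(
            (self.depths.max() - self.depths.min()) <= tol
        )
        if not self.is_ultrametric:
            warnings.warn(
                "tree is not ultrametric: tip depths span "
                f"[{self.depths.min():.6g}, {self.depths.max():.6g}]",
                UserWarning,
                stacklevel=3,
            )

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tip_labels)

    def patristic_distances(self) -> pd.DataFrame:
        """Pairwise path-length (patristic) distances between tips.

        d(i, j) = depth(i) + depth(j) - 2 t_a(i, j); symmetric, zero diagonal.
        """
        d = self.depths.to_numpy()
        mat = d[:, None] + d[None, :] - 2.0 * self.mrca_times.to_numpy()
        np.fill_diagonal(mat, 0.0)
        return pd.DataFrame(mat, index=self.tip_labels, columns=self.tip_labels)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def read_tree(path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths.

    Warns (does not fail) if the tree is non-ultrametric beyond a relative
    tolerance of 1e-6 of the maximum depth.
    """
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


# ---------------------------------------------------------------------------
# Tabular containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of counts, CPM or log2-CPM values."""

    values: pd.DataFrame  # genes in rows, samples in columns
    scale: str = "counts"  # counts | cpm | log2cpm

    def __post_init__(self):
        if self.scale not in ("counts", "cpm", "log2cpm"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing cells")
        if self.scale == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValidationError("negative counts")
            frac = arr - np.floor(arr)
            if (frac != 0).any():
                g, s = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}: "
                    f"{arr[g, s]}"
                )
            self.values = self.values.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def library_sizes(self) -> pd.Series:
        if self.scale != "counts":
            raise ValidationError("library sizes are defined for counts only")
        return self.values.sum(axis=0)


@dataclass
class SampleTable:
    """Per-sample metadata: species, brain region, individual, sex, age class."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "species", "region", "individual")
    OPTIONAL = ("sex", "age_class")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[
                self.table["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        self.table = self.table.set_index("sample_id", drop=False)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every metadata sample must exist in the matrix and vice versa."""
        meta = set(self.table["sample_id"])
        mat = set(expr.samples)
        extra = sorted(meta - mat)
        if extra:
            raise ValidationError(f"metadata samples absent from matrix: {extra}")
        absent = sorted(mat - meta)
        if absent:
            raise ValidationError(f"matrix samples absent from metadata: {absent}")

    def species_of(self, samples) -> pd.Series:
        return self.table.loc[list(samples), "species"]

    def map_species(self, aliases: dict[str, str]) -> "SampleTable":
        """Rename species via an explicit alias map (exact match otherwise)."""
        t = self.table.copy()
        t["species"] = t["species"].map(lambda s: aliases.get(s, s))
        return SampleTable(t.reset_index(drop=True))


ECV_TO_MASS_G_PER_ML = 1.036


@dataclass
class TraitTable:
    """Species endocranial volumes (ml) and derived brain masses (g)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("species", "ecv_ml") if c not in self.table.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        if self.table["species"].duplicated().any():
            raise ValidationError("duplicate species in trait table")
        if (self.table["ecv_ml"] <= 0).any():
            raise ValidationError("ECV must be positive")
        t = self.table.copy()
        t["brain_mass_g"] = t["ecv_ml"] * ECV_TO_MASS_G_PER_ML
        self.table = t.set_index("species", drop=False)

    def mass(self) -> pd.Series:
        return self.table["brain_mass_g"]

    def log10_mass(self) -> pd.Series:
        return np.log10(self.table["brain_mass_g"])


def read_counts(path) -> ExpressionMatrix:
    """Read a TSV gene x sample count matrix (genes in rows, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df, scale="counts")
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_metadata(path, expr: ExpressionMatrix | None = None) -> SampleTable:
    tab = SampleTable(pd.read_csv(path, sep="\t", dtype=str))
    if expr is not None:
        tab.validate_against(expr)
    return tab


def read_traits(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t"))


def read_aliases(path) -> dict[str, str]:
    """Two-column TSV (from, to) mapping metadata species names to tree tips."""
    df = pd.read_csv(path, sep="\t", header=None, names=["from", "to"], dtype=str)
    return dict(zip(df["from"], df["to"]))


# ---------------------------------------------------------------------------
# Generic results tables with provenance header
# ---------------------------------------------------------------------------

from . import __version__ as _pkg_version  # noqa: E402  (single-module cycle-free)


def _config_hash(meta: dict) -> str:
    payload = yaml.safe_dump(meta, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a results table as TSV with a '#'-prefixed provenance header."""
    meta = dict(meta or {})
    meta.setdefault("tool_version", _pkg_version)
    meta["config_hash"] = _config_hash(meta)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a provenance-headed TSV back into (DataFrame, meta)."""
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, val = line[2:].rstrip("\n").partition(": ")
                meta[key] = val
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    return df, meta
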