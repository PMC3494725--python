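"""Domain types and file I/O for coevolution-based pair prediction.

The pipeline works on four kinds of input: per-protein gene trees (newick,
with branch lengths), one reference species tree ("Tree of Life"), a binary
presence/absence profile matrix (proteins x species), and a gold-standard
pair-label table.  All tabular formats are TSV; trees are newick.

Trees are stored internally as (possibly rooted) dendropy trees but every
metric downstream treats them as unrooted: patristic distances and
agreement-subtree sizes are invariant to root placement, so any rooting in
the input is recorded on the tree object and otherwise ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("coevoppi")

__all__ = [
    "ValidationError",
    "ParseError",
    "NotComputable",
    "SpeciesUniverse",
    "PhyloProfile",
    "GeneTree",
    "DistanceMatrix",
    "PairLabel",
    "PairFeatureVector",
    "TREE_FEATURE_NAMES",
    "PROFILE_FEATURE_NAMES",
    "COUNT_FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "canonical_pair",
    "read_newick",
    "write_newick",
    "read_tree_dir",
    "read_profiles",
    "write_profiles",
    "read_pair_labels",
    "write_pair_labels",
    "read_feature_table",
    "write_feature_table",
    "read_score_table",
    "write_score_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries position information."""


class NotComputable(Exception):
    """Signals that a feature is undefined for this input (it will be
    missing-masked in the feature table, never silently set to a number)."""


# ---------------------------------------------------------------------------
# Feature name registry: 7 tree features + 25 profile quality measures +
# 3 raw counts = 35 slots, in canonical column order.
# ---------------------------------------------------------------------------

TREE_FEATURE_NAMES: tuple[str, ...] = (
    "mirror",
    "mirror_A",
    "mirror_B",
    "tol_mirror",
    "icong",
    "icong_A",
    "icong_B",
)

#: The 25 association-quality measures.  Nine asymmetric measures appear in
#: both directions (suffix 1 = A->B, suffix 2 = B->A); confidence/recall are
#: each other's reversal and therefore appear once each.
PROFILE_FEATURE_NAMES: tuple[str, ...] = (
    "confidence",
    "recall",
    "lift",
    "dice",
    "pearson",
    "GI",
    "IQC",
    "confidenceCentered1",
    "confidenceCentered2",
    "leastContradiction1",
    "leastContradiction2",
    "jaccard1",
    "jaccard2",
    "loevinger1",
    "loevinger2",
    "tec1",
    "tec2",
    "LAP1",
    "LAP2",
    "GAN1",
    "GAN2",
    "Zhang1",
    "Zhang2",
    "Pearl1",
    "Pearl2",
)

COUNT_FEATURE_NAMES: tuple[str, ...] = ("n_A", "n_B", "n_AB")

ALL_FEATURE_NAMES: tuple[str, ...] = (
    TREE_FEATURE_NAMES + PROFILE_FEATURE_NAMES + COUNT_FEATURE_NAMES
)

assert len(ALL_FEATURE_NAMES) == 35

#: Number of significant digits used when serializing real-valued columns.
REAL_FORMAT = "%.10g"
#: Literal used for missing feature values in TSV tables.
NA_TOKEN = "NA"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) identity of an unordered pair."""
    if a == b:
        raise ValidationError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesUniverse:
    """The ordered set of genomes under study.

    ``N`` (the total number of species) enters several profile quality
    measures directly; the minimum of 7 reflects the smallest species set on
    which the congruence index downstream is defined.
    """

    species_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.species_ids)
        object.__setattr__(self, "species_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species identifiers in universe")
        if len(ids) < 7:
            raise ValidationError(f"universe needs >= 7 species, got {len(ids)}")

    @property
    def N(self) -> int:
        return len(self.species_ids)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species_ids)}

    def __len__(self) -> int:
        return self.N

    def __contains__(self, item: str) -> bool:
        return item in self.species_ids


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/absence vector of a protein's orthologs over the universe."""

    protein_id: str
    present: np.ndarray  # uint8, length N, aligned to universe order
    universe: SpeciesUniverse

    def __post_init__(self) -> None:
        arr = np.asarray(self.present)
        if arr.shape != (self.universe.N,):
            raise ValidationError(
                f"profile {self.protein_id!r}: length {arr.shape} != universe N {self.universe.N}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"profile {self.protein_id!r}: values must be 0/1")
        object.__setattr__(self, "present", arr.astype(np.uint8))

    @property
    def n(self) -> int:
        """Number of species where the protein is present."""
        return int(self.present.sum())

    def species_set(self) -> frozenset[str]:
        ids = self.universe.species_ids
        return frozenset(ids[i] for i in np.flatnonzero(self.present))


@dataclass
class GeneTree:
    """Leaf-labelled tree with branch lengths for one protein's orthologs.

    Wraps a dendropy tree; leaf labels are species identifiers.  The tree is
    treated as unrooted by all downstream metrics.
    """

    protein_id: str
    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(
                f"tree {self.protein_id!r}: duplicate leaf label(s) {dup}"
            )

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def validate_against(self, profile: PhyloProfile) -> None:
        """Check that the leaf set equals the profile's present-species set."""
        if self.leaf_set() != profile.species_set():
            raise ValidationError(
                f"tree/profile mismatch for {self.protein_id!r}: "
                f"tree leaves {sorted(self.leaf_set())} vs profile "
                f"{sorted(profile.species_set())}"
            )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic (or species-tree) distance matrix.

    ``signed=True`` relaxes the non-negativity invariant; it is used for the
    residual matrices produced by species-tree background correction, which
    keep the symmetric zero-diagonal structure but may go negative.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        d = np.asarray(self.d, dtype=float)
        n = len(labels)
        if d.shape != (n, n):
            raise ValidationError(f"matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if not self.signed and np.any(d < -1e-12):
            raise ValidationError("negative distances")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.labels)

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Sub-matrix on the given labels, in the given order."""
        idx = {l: i for i, l in enumerate(self.labels)}
        try:
            sel = [idx[l] for l in labels]
        except KeyError as e:
            raise ValidationError(f"label {e.args[0]!r} not in matrix") from e
        return DistanceMatrix(tuple(labels), self.d[np.ix_(sel, sel)], self.signed)

    def upper(self) -> np.ndarray:
        """Strictly-upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]


@dataclass(frozen=True)
class PairLabel:
    protein_a: str
    protein_b: str
    label: str  # "pos" | "neg"

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValidationError(f"self-pair: {self.protein_a!r}")
        if self.label not in ("pos", "neg"):
            raise ValidationError(f"label must be pos/neg, got {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.protein_a, self.protein_b)


@dataclass
class PairFeatureVector:
    """The 35 named features for one pair; ``None`` marks a missing value."""

    protein_a: str
    protein_b: str
    features: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_a, self.protein_b = canonical_pair(self.protein_a, self.protein_b)
        missing = set(ALL_FEATURE_NAMES) - set(self.features)
        extra = set(self.features) - set(ALL_FEATURE_NAMES)
        if missing or extra:
            raise ValidationError(
                f"feature vector must have exactly the 35 named slots; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _byte_offset(text: str, line: int | None, col: int | None) -> int | None:
    if line is None:
        return None
    lines = text.splitlines(keepends=True)
    off = sum(len(l) for l in lines[: max(line - 1, 0)])
    return off + (col or 0)


def read_newick(path: str | Path, protein_id: str | None = None) -> GeneTree:
    """Read one newick tree.

    Missing branch lengths default to 0.0 (with a warning) so patristic sums
    stay defined; duplicate leaf labels are rejected.
    """
    path = Path(path)
    text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several error types
        if "Duplicate taxon" in str(e) or "Multiple occurrences" in str(e):
            raise ValidationError(f"{path}: duplicate leaf label: {e}") from e
        line = getattr(e, "line_num", None)
        col = getattr(e, "col_num", None)
        off = _byte_offset(text, line, col)
        where = f" at byte offset {off}" if off is not None else ""
        raise ParseError(f"malformed newick in {path}{where}: {e}") from e
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} branch length(s) missing, defaulted to 0.0",
            stacklevel=2,
        )
    if protein_id is None:
        protein_id = path.stem
    return GeneTree(protein_id=protein_id, tree=tree)


def write_newick(gtree: GeneTree, path: str | Path) -> None:
    s = gtree.tree.as_string(schema="newick", suppress_rooting=True,
                             unquoted_underscores=True)
    Path(path).write_text(s)


def read_tree_dir(path: str | Path, pattern: str = "*.nwk") -> dict[str, GeneTree]:
    """Read every newick file in a directory; protein id = file stem."""
    out: dict[str, GeneTree] = {}
    for p in sorted(Path(path).glob(pattern)):
        out[p.stem] = read_newick(p)
    return out


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------


def read_profiles(
    path: str | Path, universe: SpeciesUniverse | None = None
) -> tuple[SpeciesUniverse, list[PhyloProfile]]:
    """Read a proteins x species 0/1 TSV.

    The first column holds protein ids; remaining columns are species.  If a
    universe is supplied, the file's columns must be exactly that species set
    (any order); profiles are re-aligned to universe order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected protein column + species columns")
    prot_col = df.columns[0]
    species_cols = list(df.columns[1:])
    if universe is None:
        universe = SpeciesUniverse(tuple(species_cols))
    else:
        if set(species_cols) != set(universe.species_ids):
            unknown = sorted(set(species_cols) - set(universe.species_ids))
            missing = sorted(set(universe.species_ids) - set(species_cols))
            raise ValidationError(
                f"{path}: species columns do not match universe "
                f"(unknown={unknown}, missing={missing})"
            )
    vals = df[list(universe.species_ids)].to_numpy()
    profiles: list[PhyloProfile] = []
    for r in range(vals.shape[0]):
        row = vals[r]
        bad = [c for c, v in zip(universe.species_ids, row) if v not in ("0", "1")]
        if bad:
            raise ValidationError(
                f"{path}: non-binary cell at row {r} (protein "
                f"{df.iloc[r, 0]!r}), column(s) {bad}"
            )
        profiles.append(
            PhyloProfile(
                protein_id=str(df.iloc[r][prot_col]),
                present=row.astype(np.uint8),
                universe=universe,
            )
        )
    return universe, profiles


def write_profiles(profiles: Sequence[PhyloProfile], path: str | Path) -> None:
    if not profiles:
        raise ValidationError("no profiles to write")
    universe = profiles[0].universe
    rows = {p.protein_id: p.present for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=universe.species_ids)
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pair-label I/O
# ---------------------------------------------------------------------------


def read_pair_labels(path: str | Path) -> list[PairLabel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_a", "protein_b", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    labels: list[PairLabel] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        pl = PairLabel(str(row["protein_a"]), str(row["protein_b"]), str(row["label"]))
        if pl.pair in seen:
            raise ValidationError(f"{path}: duplicate unordered pair {pl.pair}")
        seen.add(pl.pair)
        labels.append(pl)
    n_pos = sum(1 for l in labels if l.label == "pos")
    logger.info(
        "read %d pair labels from %s: %d pos, %d neg",
        len(labels), path, n_pos, len(labels) - n_pos,
    )
    return labels


def write_pair_labels(labels: Sequence[PairLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.protein_a, l.protein_b, l.label) for l in labels],
        columns=["protein_a", "protein_b", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature / score table I/O
#
# Tables are keyed on the canonical (sorted) pair; reals carry 10 significant
# digits; missing values are the literal "NA".
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pair x feature table (index = (protein_a, protein_b))."""
    if list(table.columns) != list(ALL_FEATURE_NAMES):
        raise ValidationError(
            f"feature table must have exactly the 35 canonical columns, got {list(table.columns)}"
        )
    out = table.reset_index()
    out.columns = ["protein_a", "protein_b", *ALL_FEATURE_NAMES]
    out.to_csv(path, sep="\t", index=False, float_format=REAL_FORMAT,
               na_rep=NA_TOKEN)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                     dtype={"protein_a": str, "protein_b": str})
    if list(df.columns) != ["protein_a", "protein_b", *ALL_FEATURE_NAMES]:
        raise ParseError(f"{path}: unexpected feature-table header")
    return df.set_index(["protein_a", "protein_b"])


SCORE_COLUMNS = ("mean_score", "sd_score", "n_pos_mode", "P_neg_mean", "kept")


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    if list(table.columns) != list(SCORE_COLUMNS):
        raise ValidationError(f"score table columns must be {SCORE_COLUMNS}")
    out = table.reset_index()
    out.columns = ["protein_a", "protein_b", *SCORE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format=REAL_FORMAT,
               na_rep=NA_TOKEN)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                     dtype={"protein_a": str, "protein_b": str})
    if list(df.columns) != ["protein_a", "protein_b", *SCORE_COLUMNS]:
        raise ParseError(f"{path}: unexpected score-table header")
    df["kept"] = df["kept"].astype(bool)
    return df.set_index(["protein_a", "protein_b"])
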