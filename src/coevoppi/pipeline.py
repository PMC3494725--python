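"""Feature-table assembly: eligibility filters + pair x 35 feature matrix.

Inclusion rules applied before any feature is computed:

* a protein must be present in at least 7 species;
* a pair must share at least 7 species (n_AB >= 7).

Both bounds are inclusive and mirror the validity domain of the congruence
index.  Pairs in the gold standard that fail these rules are dropped with a
logged count, not an error.  Output rows are sorted on the canonical pair
identity so that the table is reproducible; the seed feeds only the
congruence permutation nulls.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_FEATURE_NAMES,
    GeneTree,
    PairLabel,
    PhyloProfile,
    TREE_FEATURE_NAMES,
    canonical_pair,
)
from .profile_features import profile_feature_block
from .tree_features import DEFAULT_PERMUTATIONS, TolModel, tree_feature_block

logger = logging.getLogger("coevoppi")

__all__ = [
    "MIN_SPECIES_PER_PROTEIN",
    "MIN_SHARED_SPECIES",
    "eligible_proteins",
    "eligible_pairs",
    "build_feature_table",
]

MIN_SPECIES_PER_PROTEIN = 7
MIN_SHARED_SPECIES = 7


def eligible_proteins(profiles: Iterable[PhyloProfile]) -> set[str]:
    """Proteins present in at least 7 species."""
    kept = {p.protein_id for p in profiles if p.n >= MIN_SPECIES_PER_PROTEIN}
    return kept


def eligible_pairs(
    pairs: Iterable[tuple[str, str]],
    profiles: Mapping[str, PhyloProfile],
) -> set[tuple[str, str]]:
    """Pairs of eligible proteins sharing at least 7 species."""
    ok_prot = eligible_proteins(profiles.values())
    kept: set[tuple[str, str]] = set()
    for a, b in pairs:
        pair = canonical_pair(a, b)
        if pair[0] not in ok_prot or pair[1] not in ok_prot:
            continue
        overlap = int(
            np.sum(profiles[pair[0]].present & profiles[pair[1]].present)
        )
        if overlap >= MIN_SHARED_SPECIES:
            kept.add(pair)
    return kept


def build_feature_table(
    pairs: Sequence[tuple[str, str]] | Sequence[PairLabel],
    trees: Mapping[str, GeneTree],
    profiles: Mapping[str, PhyloProfile],
    tol: GeneTree,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per eligible pair, 35 feature columns, NaN = missing.

    A pair whose protein has no tree gets its 7 tree features masked (the 28
    profile features are still computed) and the run continues with a logged
    warning.  Deterministic given inputs and seed.
    """
    raw_pairs = [
        p.pair if isinstance(p, PairLabel) else canonical_pair(*p) for p in pairs
    ]
    keep = eligible_pairs(raw_pairs, profiles)
    dropped = len(set(raw_pairs)) - len(keep)
    if dropped:
        logger.info(
            "dropped %d pair(s) failing the >=7-species rules; %d remain",
            dropped, len(keep),
        )
    ordered = sorted(keep)

    tol_model = TolModel.from_tree(tol)
    # one child seed per pair, tied to the canonical row order
    seeds = np.random.SeedSequence(seed).spawn(len(ordered))

    rows: list[dict[str, float | None]] = []
    n_no_tree = 0
    for (pa, pb), child_seed in zip(ordered, seeds):
        feats: dict[str, float | None] = {}
        ta, tb = trees.get(pa), trees.get(pb)
        if ta is None or tb is None:
            n_no_tree += 1
            logger.warning(
                "pair (%s, %s): missing gene tree, tree features masked", pa, pb
            )
            feats.update({name: None for name in TREE_FEATURE_NAMES})
        else:
            feats.update(
                tree_feature_block(
                    ta, tb, tol,
                    n_permutations=n_permutations,
                    seed=np.random.default_rng(child_seed),
                    tol_model=tol_model,
                )
            )
        feats.update(profile_feature_block(profiles[pa], profiles[pb]))
        rows.append(feats)
    if n_no_tree:
        logger.info("%d pair(s) had tree features masked for missing trees", n_no_tree)

    index = pd.MultiIndex.from_tuples(ordered, names=["protein_a", "protein_b"])
    table = pd.DataFrame(rows, index=index, columns=list(ALL_FEATURE_NAMES),
                         dtype=float)
    return table
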