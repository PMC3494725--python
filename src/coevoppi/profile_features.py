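"""Phylogenetic-profile features: contingency counts and quality measures.

For a protein pair (A, B) with presence/absence profiles over N genomes the
2x2 contingency table is

    a = #species with both proteins          (n_AB)
    b = #species with A only
    c = #species with B only
    d = #species with neither

with margins n_A = a+b, n_B = a+c.  From these counts 16 association-rule
quality measures are computed; the nine asymmetric ones are evaluated in
both directions (suffix 1 = rule A->B, suffix 2 = rule B->A), and
``confidence``/``recall`` are each other's reversal, giving 25 feature
slots.  Together with the raw counts n_A, n_B, n_AB this block contributes
28 of the 35 pair features.

Degenerate inputs (zero denominators, log of zero, ...) yield a missing
mask on the affected slot only; no exception escapes to the feature table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    COUNT_FEATURE_NAMES,
    PROFILE_FEATURE_NAMES,
    PhyloProfile,
    ValidationError,
)

__all__ = [
    "ContingencyCounts",
    "contingency",
    "quality_measures",
    "profile_feature_block",
]


@dataclass(frozen=True)
class ContingencyCounts:
    a: int  # both present (n_AB)
    b: int  # A only
    c: int  # B only
    d: int  # neither

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"count {name} must be a non-negative integer")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_A(self) -> int:
        return self.a + self.b

    @property
    def n_B(self) -> int:
        return self.a + self.c

    def swapped(self) -> "ContingencyCounts":
        """Counts with the roles of A and B exchanged."""
        return ContingencyCounts(self.a, self.c, self.b, self.d)


def contingency(profile_a: PhyloProfile, profile_b: PhyloProfile) -> ContingencyCounts:
    """Exact 2x2 presence/absence counts over the common species universe."""
    if profile_a.universe is not profile_b.universe and (
        profile_a.universe.species_ids != profile_b.universe.species_ids
    ):
        raise ValidationError(
            f"profiles {profile_a.protein_id!r}/{profile_b.protein_id!r} "
            "are defined on different universes"
        )
    pa = profile_a.present.astype(bool)
    pb = profile_b.present.astype(bool)
    return ContingencyCounts(
        a=int(np.sum(pa & pb)),
        b=int(np.sum(pa & ~pb)),
        c=int(np.sum(~pa & pb)),
        d=int(np.sum(~pa & ~pb)),
    )


def _directional(ct: ContingencyCounts) -> dict[str, float | None]:
    """The asymmetric measures for the rule A -> B (direction 1)."""
    a, b, N = ct.a, ct.b, ct.N
    n_A, n_B = ct.n_A, ct.n_B
    pA = n_A / N
    pB = n_B / N
    pAB = a / N

    confidence = a / n_A if n_A > 0 else None

    out: dict[str, float | None] = {}
    out["confidence"] = confidence
    out["confidenceCentered"] = None if confidence is None else confidence - pB
    out["leastContradiction"] = (a - b) / n_B if n_B > 0 else None
    out["loevinger"] = (
        None if confidence is None or pB == 1.0 else (confidence - pB) / (1.0 - pB)
    )
    out["tec"] = 1.0 - b / a if a > 0 else None
    out["LAP"] = (a + 1) / (n_A + 2)
    out["GAN"] = (a - b) / n_A if n_A > 0 else None
    zden = max(pAB * (1.0 - pB), pB * (pA - pAB))
    out["Zhang"] = (pAB - pA * pB) / zden if zden > 0 else None
    out["Pearl"] = None if confidence is None else pA * abs(confidence - pB)
    return out


def quality_measures(ct: ContingencyCounts) -> dict[str, float | None]:
    """The 25 quality-measure slots; ``None`` marks an undefined slot."""
    if ct.N < 1:
        raise ValidationError("empty contingency table")
    a, b, c, d, N = ct.a, ct.b, ct.c, ct.d, ct.N
    n_A, n_B = ct.n_A, ct.n_B

    out: dict[str, float | None] = {name: None for name in PROFILE_FEATURE_NAMES}

    # symmetric measures
    if n_A > 0 and n_B > 0:
        out["lift"] = a * N / (n_A * n_B)
        out["GI"] = math.log2(a * N / (n_A * n_B)) if a > 0 else None
    if n_A + n_B > 0:
        out["dice"] = 2 * a / (n_A + n_B)
        out["jaccard1"] = out["jaccard2"] = a / (n_A + n_B - a)
    marg = n_A * n_B * (N - n_A) * (N - n_B)
    if marg > 0:
        out["pearson"] = (a * d - b * c) / math.sqrt(marg)
    # Cohen's kappa of the 2x2 table
    pe = (n_A * n_B + (N - n_A) * (N - n_B)) / (N * N)
    if pe != 1.0:
        out["IQC"] = ((a + d) / N - pe) / (1.0 - pe)

    # asymmetric measures, both directions
    d1 = _directional(ct)
    d2 = _directional(ct.swapped())
    out["confidence"] = d1["confidence"]
    out["recall"] = d2["confidence"]  # confidence of the reversed rule
    for meas in ("confidenceCentered", "leastContradiction", "loevinger",
                 "tec", "LAP", "GAN", "Zhang", "Pearl"):
        out[f"{meas}1"] = d1[meas]
        out[f"{meas}2"] = d2[meas]
    return out


def profile_feature_block(
    profile_a: PhyloProfile, profile_b: PhyloProfile
) -> dict[str, float | None]:
    """The 28 profile-derived feature slots for one pair: 25 quality
    measures plus the raw counts n_A, n_B, n_AB."""
    ct = contingency(profile_a, profile_b)
    out = quality_measures(ct)
    out["n_A"] = float(ct.n_A)
    out["n_B"] = float(ct.n_B)
    out["n_AB"] = float(ct.a)
    assert set(out) == set(PROFILE_FEATURE_NAMES) | set(COUNT_FEATURE_NAMES)
    return out
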