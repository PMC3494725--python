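"""Ensemble scoring: classifier bank, repeated stratified CV, score fusion.

The bank holds 8 probabilistic binary classifiers: 4 base learners plus a
bagged version of each.  The originals were rule inducers (JRIP, PART) and
decision trees (J48, RandomForest); here the rule inducers are represented
by depth-restricted decision trees, which realise the same axis-parallel
rule-list hypothesis class, and the ensemble layer is agnostic to the
bank's composition (any object with fit/predict_proba and a random_state
satisfies the contract).

Each repetition of the 3-fold stratified cross-validation scores every pair
exactly once, out-of-fold; 30 repetitions give 30 independent confidence
sets per pair.  Per-classifier confidences P_c (probability of the pos
class) are fused into a single score:

    n_pos = #{c : P_c >= 0.5}          (vote at the 0.5 threshold)
    S_pos = (1/|C|) * sum_{c: P_c >= 0.5} P_c
    S_neg = (1/|C|) * sum_{c: P_c <  0.5} (1 - P_c)
    score = S_pos - S_neg   in [-1, 1]

so a unanimous high-confidence positive scores near 1 while a unanimous but
barely-above-0.5 positive scores much lower.  The negative-pair filter
removes a pair only when no classifier votes positive and the mean negative
confidence P_neg = mean(1 - P_c) exceeds the threshold alpha; alpha = 1
disables filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ValidationError

logger = logging.getLogger("coevoppi")

__all__ = [
    "ClassifierBank",
    "default_bank",
    "CVPlan",
    "EnsembleConfig",
    "ScoredPair",
    "stratified_folds",
    "make_cv_plan",
    "cross_val_confidences",
    "combine_score",
    "filter_pairs",
    "aggregate_repetitions",
    "score_pairs",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ("mean_score", "sd_score", "n_pos_mode", "P_neg_mean", "kept")

VOTE_THRESHOLD = 0.5


@dataclass
class ClassifierBank:
    """Ordered set of named probabilistic binary classifiers."""

    members: list[tuple[str, object]]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValidationError("classifier bank must not be empty")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


def default_bank(seed: int = 0, n_bags: int = 10) -> ClassifierBank:
    """The default 8-member bank: 4 base learners + their bagged versions."""
    ss = np.random.SeedSequence(seed).spawn(8)
    s = [int(x.generate_state(1)[0] % (2**31)) for x in ss]
    base = [
        # shallow tree standing in for a compact rule list (JRIP-like)
        ("jrip", DecisionTreeClassifier(max_depth=3, random_state=s[0])),
        # pruned partial tree (PART-like)
        ("part", DecisionTreeClassifier(criterion="entropy", min_samples_leaf=5,
                                        random_state=s[1])),
        # full C4.5-style tree
        ("j48", DecisionTreeClassifier(criterion="entropy", random_state=s[2])),
        ("rf", RandomForestClassifier(n_estimators=50, random_state=s[3])),
    ]
    bagged = [
        (f"b{name}", BaggingClassifier(estimator=clone(est), n_estimators=n_bags,
                                       random_state=s[4 + i]))
        for i, (name, est) in enumerate(base)
    ]
    return ClassifierBank(members=base + bagged)


# ---------------------------------------------------------------------------
# Cross-validation structure
# ---------------------------------------------------------------------------


def stratified_folds(labels: np.ndarray, n_folds: int = 3, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..n_folds-1) per example, stratified by class.

    Within each class, shuffled members are dealt round-robin from a random
    starting fold, so per-fold class counts differ from perfect proportion
    by less than one example.  Deterministic given the seed.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.full(len(y), -1, dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValidationError(
                f"class {cls!r} has {len(idx)} member(s) < {n_folds} folds"
            )
        rng.shuffle(idx)
        start = int(rng.integers(n_folds))
        assignment[idx] = (start + np.arange(len(idx))) % n_folds
    return assignment


@dataclass
class CVPlan:
    """Repeated stratified k-fold plan: one fold assignment per repetition."""

    n_folds: int
    n_repetitions: int
    rep_seeds: list[int]
    assignments: np.ndarray  # (n_repetitions, n_examples)

    def __post_init__(self) -> None:
        if self.assignments.shape[0] != self.n_repetitions:
            raise ValidationError("one assignment row per repetition required")


def make_cv_plan(
    labels: np.ndarray,
    n_folds: int = 3,
    n_repetitions: int = 30,
    seed: int = 0,
) -> CVPlan:
    ss = np.random.SeedSequence(seed).spawn(n_repetitions)
    rep_seeds = [int(x.generate_state(1)[0] % (2**31)) for x in ss]
    assignments = np.stack(
        [stratified_folds(labels, n_folds, s) for s in rep_seeds]
    )
    return CVPlan(n_folds, n_repetitions, rep_seeds, assignments)


@dataclass
class EnsembleConfig:
    alpha: float = 1.0
    vote_threshold: float = VOTE_THRESHOLD
    imputation: str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")


def _impute_median(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaNs with per-feature medians computed on the training block
    only (test data never leaks into the imputation)."""
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    out_tr = np.where(np.isnan(X_train), med, X_train)
    out_te = np.where(np.isnan(X_test), med, X_test)
    return out_tr, out_te


def cross_val_confidences(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    bank: ClassifierBank,
    plan: CVPlan,
) -> np.ndarray:
    """Out-of-fold pos-class confidences, shape (n_reps, n_pairs, |C|).

    Every pair is scored once per repetition by models never trained on it.
    If a classifier fails on a fold the whole repetition is set to NaN and
    reported; other repetitions are unaffected.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValidationError("features/labels length mismatch")
    n = len(y)
    out = np.full((plan.n_repetitions, n, len(bank)), np.nan)
    for r in range(plan.n_repetitions):
        folds = plan.assignments[r]
        try:
            for f in range(plan.n_folds):
                test = folds == f
                train = ~test
                X_tr, X_te = _impute_median(X[train], X[test])
                y_tr = y[train]
                for ci, (name, template) in enumerate(bank.members):
                    est = clone(template)
                    est.fit(X_tr, y_tr)
                    proba = est.predict_proba(X_te)
                    pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
                    out[r, test, ci] = proba[:, pos_col]
        except Exception as e:  # noqa: BLE001 - fold-level fault isolation
            logger.error("repetition %d aborted: %s", r, e)
            out[r] = np.nan
    return out


# ---------------------------------------------------------------------------
# Score fusion and filtering
# ---------------------------------------------------------------------------


@dataclass
class ScoredPair:
    protein_a: str
    protein_b: str
    p_c: np.ndarray  # per-classifier pos confidence
    n_pos: int = field(init=False)
    n_neg: int = field(init=False)
    s_pos: float = field(init=False)
    s_neg: float = field(init=False)
    score: float = field(init=False)
    p_neg: float = field(init=False)
    kept: bool = True

    def __post_init__(self) -> None:
        parts = combine_score(self.p_c)
        self.n_pos = int(parts["n_pos"])
        self.n_neg = int(parts["n_neg"])
        self.s_pos = float(parts["S_pos"])
        self.s_neg = float(parts["S_neg"])
        self.score = float(parts["score"])
        self.p_neg = float(parts["P_neg"])


def combine_score(p_c: np.ndarray) -> dict[str, np.ndarray]:
    """Fuse per-classifier confidences (last axis) into the combined score.

    Returns n_pos, n_neg, S_pos, S_neg, score and the aggregate negative
    confidence P_neg = mean(1 - P_c) used by the filter.
    """
    pc = np.asarray(p_c, dtype=float)
    if not np.all(np.isfinite(pc)) or np.any(pc < 0) or np.any(pc > 1):
        raise ValidationError("confidences must be finite and in [0, 1]")
    n_clf = pc.shape[-1]
    votes = pc >= VOTE_THRESHOLD  # tie at exactly 0.5 counts as pos
    n_pos = votes.sum(axis=-1)
    s_pos = np.where(votes, pc, 0.0).sum(axis=-1) / n_clf
    s_neg = np.where(~votes, 1.0 - pc, 0.0).sum(axis=-1) / n_clf
    return {
        "n_pos": n_pos,
        "n_neg": n_clf - n_pos,
        "S_pos": s_pos,
        "S_neg": s_neg,
        "score": s_pos - s_neg,
        "P_neg": (1.0 - pc).mean(axis=-1),
    }


def filter_pairs(
    n_pos: np.ndarray, p_neg: np.ndarray, alpha: float
) -> np.ndarray:
    """Kept flags: a pair is removed only when every classifier votes
    negative AND its aggregate negative confidence exceeds alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    n_pos = np.asarray(n_pos)
    p_neg = np.asarray(p_neg)
    return (n_pos > 0) | (p_neg <= alpha)


def aggregate_repetitions(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair mean and sd of the combined score over repetitions.

    Repetitions that failed (all-NaN rows) are excluded; at least two valid
    repetitions are required.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2:
        raise ValidationError("expected (n_repetitions, n_pairs) array")
    valid = ~np.all(np.isnan(s), axis=1)
    s = s[valid]
    if s.shape[0] < 2:
        raise ValidationError("need >= 2 valid repetitions to aggregate")
    return s.mean(axis=0), s.std(axis=0, ddof=1)


def score_pairs(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: EnsembleConfig | None = None,
    bank: ClassifierBank | None = None,
    n_folds: int = 3,
    n_repetitions: int = 30,
) -> dict:
    """End-to-end ensemble scoring of a feature table.

    Returns a dict with the raw confidences (n_reps, n, |C|), the
    per-repetition combined scores (n_reps, n), and an aggregated score
    DataFrame indexed like ``features``.
    """
    config = config or EnsembleConfig()
    bank = bank or default_bank(config.seed)
    y = np.asarray(labels)
    plan = make_cv_plan(y, n_folds=n_folds, n_repetitions=n_repetitions,
                        seed=config.seed)
    conf = cross_val_confidences(features, y, bank, plan)
    parts = combine_score(np.nan_to_num(conf, nan=0.5))
    # NaN repetitions must stay NaN in the per-rep scores
    rep_scores = np.where(np.isnan(conf).any(axis=-1), np.nan, parts["score"])
    mean_score, sd_score = aggregate_repetitions(rep_scores)

    valid = ~np.isnan(conf).any(axis=-1)  # (n_reps, n)
    n_pos = np.ma.masked_array(parts["n_pos"], mask=~valid)
    n_pos_mode = np.asarray(
        [np.bincount(col.compressed().astype(int)).argmax() for col in n_pos.T]
    )
    p_neg_mean = np.ma.masked_array(parts["P_neg"], mask=~valid).mean(axis=0).filled(np.nan)
    kept = filter_pairs(n_pos_mode, p_neg_mean, config.alpha)

    table = pd.DataFrame(
        {
            "mean_score": mean_score,
            "sd_score": sd_score,
            "n_pos_mode": n_pos_mode,
            "P_neg_mean": p_neg_mean,
            "kept": kept,
        },
        index=features.index,
    )
    return {
        "confidences": conf,
        "rep_scores": rep_scores,
        "plan": plan,
        "bank": bank,
        "table": table,
    }
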