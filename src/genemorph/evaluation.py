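"""Classification metrics and the confidence-stratified k-fold protocol.

Morphology models are trained only on high-confidence samples (those with a
clear molecular subtype); low-confidence (Intermediate-tier) samples are
never used for training and are evaluated separately, so performance can be
compared across confidence tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

if TYPE_CHECKING:  # pragma: no cover
    from .morphology import SlideBag, TrainConfig
    from .network import CoexpressionNetwork

__all__ = ["FoldResult", "roc_auc", "sens_spec", "kfold_evaluate", "summarize_folds"]


@dataclass(frozen=True)
class FoldResult:
    fold: int
    split: str  # "validation" | "test"
    tier: str  # "high_confidence" | "low_confidence" | "all"
    auc: float
    sensitivity: float
    specificity: float
    n: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties credited one half."""
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def sens_spec(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity with score >= threshold called positive."""
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("sens/spec require both classes present")
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)


def _metrics_row(fold, split, tier, scores, labels, threshold) -> FoldResult:
    y = np.asarray(labels, dtype=int)
    if len(y) == 0 or y.min() == y.max():
        return FoldResult(fold, split, tier, float("nan"), float("nan"), float("nan"), len(y))
    auc = roc_auc(scores, y)
    se, sp = sens_spec(scores, y, threshold)
    return FoldResult(fold, split, tier, auc, se, sp, len(y))


def kfold_evaluate(
    bags: Sequence["SlideBag"],
    labels: pd.DataFrame,
    network: "CoexpressionNetwork",
    cfg: "TrainConfig",
    k: int = 5,
) -> pd.DataFrame:
    """Confidence-stratified k-fold evaluation of the morphology model.

    Protocol (recorded here because the field reports "validation" and
    "test" columns without defining them): high-confidence slides are
    partitioned by stratified k-fold; each fold trains on the remaining
    high-confidence slides, whose internal 80/20 holdout is the
    "validation" split, while the fold's held-out partition is the "test"
    split. Low-confidence slides are never trained on; they receive their
    own parallel stratified k-fold so each fold also reports a
    low-confidence test partition (its complement is the low-confidence
    validation partition). An "all" tier pools the two test partitions.

    ``labels`` needs columns slide_id, label (0/1), high_confidence (bool).
    Returns per-fold rows plus mean rows (fold == -1) per split x tier.
    """
    from .morphology import MorphologyGeneModel

    lab = labels.set_index("slide_id")
    by_id = {b.slide_id: b for b in bags}
    missing = [s for s in lab.index if s not in by_id]
    if missing:
        raise ValueError(f"labels reference unknown slides: {missing[:5]}")
    hi_ids = [s for s in lab.index if bool(lab.loc[s, "high_confidence"])]
    lo_ids = [s for s in lab.index if not bool(lab.loc[s, "high_confidence"])]
    y_hi = np.array([int(lab.loc[s, "label"]) for s in hi_ids])
    if np.bincount(y_hi, minlength=2).min() < k:
        raise ValueError("insufficient high-confidence class counts for k folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed % (2**31))
    hi_folds = list(skf.split(np.zeros(len(hi_ids)), y_hi))
    if lo_ids:
        y_lo = np.array([int(lab.loc[s, "label"]) for s in lo_ids])
        can_stratify = np.bincount(y_lo, minlength=2).min() >= k
        lo_splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed % (2**31))
        if can_stratify:
            lo_folds = list(lo_splitter.split(np.zeros(len(lo_ids)), y_lo))
        else:  # fall back to round-robin when a class is too small to stratify
            order = np.random.default_rng(cfg.seed).permutation(len(lo_ids))
            lo_folds = [
                (np.setdiff1d(order, order[f::k]), order[f::k]) for f in range(k)
            ]
    else:
        lo_folds = [(np.array([], int), np.array([], int))] * k

    rows: list[FoldResult] = []
    thr = cfg.classifier_threshold
    for f, ((hi_tr, hi_te), (lo_tr, lo_te)) in enumerate(zip(hi_folds, lo_folds)):
        train_bags = [by_id[hi_ids[i]] for i in hi_tr]
        train_y = {hi_ids[i]: int(lab.loc[hi_ids[i], "label"]) for i in hi_tr}
        model = MorphologyGeneModel(train_bags, network, cfg, labels=train_y)
        res = model.fit()

        def scores_for(ids):
            s = res.predict([by_id[i] for i in ids])
            return s, [int(lab.loc[i, "label"]) for i in ids]

        val_ids = res.val_ids
        hi_te_ids = [hi_ids[i] for i in hi_te]
        lo_te_ids = [lo_ids[i] for i in lo_te]
        lo_val_ids = [lo_ids[i] for i in lo_tr]

        sv, yv = scores_for(val_ids)
        rows.append(_metrics_row(f, "validation", "high_confidence", sv, yv, thr))
        st, yt = scores_for(hi_te_ids)
        rows.append(_metrics_row(f, "test", "high_confidence", st, yt, thr))
        if lo_ids:
            slv, ylv = scores_for(lo_val_ids)
            rows.append(_metrics_row(f, "validation", "low_confidence", slv, ylv, thr))
            slt, ylt = scores_for(lo_te_ids)
            rows.append(_metrics_row(f, "test", "low_confidence", slt, ylt, thr))
            rows.append(
                _metrics_row(f, "test", "all", list(st) + list(slt), yt + ylt, thr)
            )
        else:
            rows.append(_metrics_row(f, "test", "all", st, yt, thr))

    df = pd.DataFrame([r.__dict__ for r in rows])
    return pd.concat([df, summarize_folds(df)], ignore_index=True)


def summarize_folds(df: pd.DataFrame) -> pd.DataFrame:
    """Mean rows (fold == -1) per (split, tier); exact arithmetic means."""
    per_fold = df[df["fold"] >= 0]
    means = (
        per_fold.groupby(["split", "tier"], sort=False)[["auc", "sensitivity", "specificity", "n"]]
        .mean()
        .reset_index()
    )
    means.insert(0, "fold", -1)
    return means
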