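"""Hierarchical Monte Carlo gene-module screening.

Three stages discover a compact subtype-discriminative gene module from a
bulk expression matrix:

* **Stage 1** — preliminary filtration in TPM space: drop genes with no
  variance, low median expression, or no co-expression partner
  (|Pearson r| above ``corr_keep`` with at least one other retained gene).
* **Stage 2** — Monte Carlo screening on the z-scored survivors: draw
  random ``subset_size``-gene modules, score each by how well its mean
  aggregate expression bifurcates the cohort into the pre-classified
  subtypes (rank AUC plus a calibrated threshold), and stop early when a
  module reaches ``target_auc``.
* **Stage 3** — refinement: resample ``refine_size``-gene candidates from
  the winning module (with replacement, de-duplicated) and pick the one
  with the best mean test AUC under stratified cross-validation.

Module aggregate = mean (not sum) of the module genes' z-scores, so modules
of different realized sizes are comparable. Threshold calibration is an
exhaustive midpoint grid over the aggregate values, seeded at the
cohort-wide mean: ties in balanced accuracy resolve toward the threshold
nearest the cohort mean, then toward the ``high_is_classical`` orientation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc
from .expression import ExpressionMatrix, zscore_genes

__all__ = [
    "SamplerConfig",
    "GeneModule",
    "ScreenRecord",
    "ScreenTrace",
    "stage1_filter",
    "module_aggregate",
    "calibrate_threshold",
    "score_module",
    "stage2_screen",
    "stage3_refine",
    "GeneModuleScreen",
    "ScreenResults",
]

HIGH_IS_CLASSICAL = "high_is_classical"
HIGH_IS_BASAL = "high_is_basal"


@dataclass
class SamplerConfig:
    """Knobs of the three-stage screen (reference defaults)."""

    subset_size: int = 200
    n_iters: int = 3000
    target_auc: float = 0.85
    min_non_na: int = 2
    abs_min: float = 0.0
    topk_edges: int = 0
    min_median_expr: float = 1.0
    min_var: float = 0.0
    corr_keep: float = 0.5
    refine_size: int = 50
    seed: int = 1337

    def __post_init__(self) -> None:
        if not (self.subset_size >= self.refine_size >= 2):
            raise ValueError("need subset_size >= refine_size >= 2")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if not (0.0 <= self.target_auc <= 1.0):
            raise ValueError("target_auc must be in [0, 1]")


@dataclass
class GeneModule:
    """A screened or refined gene set with its classification metrics."""

    gene_ids: list[str]
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    orientation: str
    stage: str  # "screen" | "refined"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("empty gene module")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in module")

    @property
    def module_hash(self) -> str:
        return hashlib.md5(",".join(sorted(self.gene_ids)).encode()).hexdigest()


@dataclass(frozen=True)
class ScreenRecord:
    iteration: int
    module_hash: str
    auc: float
    sensitivity: float
    specificity: float
    threshold: float


@dataclass
class ScreenTrace:
    records: list[ScreenRecord] = field(default_factory=list)
    stopped_early: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


# ---------------------------------------------------------------------------
# Stage 1


def _pairwise_has_partner(values: np.ndarray, corr_keep: float, min_non_na: int) -> np.ndarray:
    """Boolean per gene: has |r| > corr_keep with >=1 other gene.

    NaN-free matrices use the direct correlation; otherwise pairwise-complete
    correlations with ``min_non_na`` minimum overlapping samples (pairs with
    fewer jointly observed samples contribute no edge).
    """
    if np.isnan(values).any():
        corr = pd.DataFrame(values.T).corr(min_periods=min_non_na).to_numpy()
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    return (np.abs(corr) > corr_keep).any(axis=1)


def stage1_filter(m: ExpressionMatrix, cfg: SamplerConfig) -> ExpressionMatrix:
    """Preliminary filtration in TPM space.

    Keeps genes with variance > ``min_var``, median >= ``min_median_expr``,
    and at least one co-expression partner (|r| > ``corr_keep``) among the
    genes passing the first two filters.
    """
    if m.normalized:
        raise ValueError("stage1_filter expects an un-normalized (TPM) matrix")
    var = np.nanvar(m.values, axis=1)
    med = np.nanmedian(m.values, axis=1)
    # constant rows can carry ~1e-30 round-off variance; treat as zero
    var_floor = 1e-12 * (np.nanmean(m.values, axis=1) ** 2 + 1.0)
    keep = (var > np.maximum(cfg.min_var, var_floor)) & (med >= cfg.min_median_expr)
    if keep.any():
        idx = np.flatnonzero(keep)
        partner = _pairwise_has_partner(m.values[idx], cfg.corr_keep, cfg.min_non_na)
        keep[idx[~partner]] = False
    if not keep.any():
        raise ValueError("stage 1 filtering removed every gene")
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(m.sample_ids), m.values[keep], m.normalized)


# ---------------------------------------------------------------------------
# Module scoring primitives


def module_aggregate(m: ExpressionMatrix, genes: Sequence[str]) -> dict[str, float]:
    """Per-sample mean expression of the module genes."""
    idx = m.gene_indices(genes)
    agg = m.values[idx].mean(axis=0)
    return dict(zip(m.sample_ids, agg.astype(float)))


def _align(agg: Mapping[str, float], labels: Mapping[str, int]):
    missing = set(agg) - set(labels)
    if missing:
        raise ValueError(f"samples without labels: {sorted(missing)[:10]}")
    samples = list(agg)
    x = np.array([agg[s] for s in samples], dtype=float)
    y = np.array([int(labels[s]) for s in samples], dtype=int)
    return x, y


def _calibrate_arrays(x: np.ndarray, y: np.ndarray) -> tuple[float, str, float]:
    """Exhaustive midpoint grid maximizing balanced accuracy.

    Candidate thresholds: midpoints of adjacent distinct sorted aggregate
    values, plus one below the minimum and one above the maximum (all-positive
    / all-negative classifications). For the ``high_is_classical`` orientation
    samples with aggregate >= t predict Classical (1); the opposite
    orientation flips the prediction, so its balanced accuracy is the
    complement — both orientations are searched.
    """
    pos = int(y.sum())
    neg = len(y) - pos
    if pos == 0 or neg == 0:
        raise ValueError("threshold calibration requires both classes")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # candidate t between index i-1 and i => first i samples predicted 0
    cum_pos = np.concatenate([[0], np.cumsum(ys)])  # positives among first i
    i_all = np.arange(len(x) + 1)
    distinct = np.concatenate([[True], xs[1:] > xs[:-1], [True]])
    i_cand = i_all[distinct]
    mids = np.empty(len(x) + 1)
    mids[1:-1] = 0.5 * (xs[:-1] + xs[1:])
    mids[0] = xs[0] - 1.0
    mids[-1] = xs[-1] + 1.0
    t_cand = mids[i_cand]
    tp = pos - cum_pos[i_cand]
    tn = i_cand - cum_pos[i_cand]
    bal_classical = 0.5 * (tp / pos + tn / neg)
    cohort_mean = x.mean()

    best = None  # (bal, dist-to-mean, orientation-pref, t, orient)
    for orient, bal in ((HIGH_IS_CLASSICAL, bal_classical), (HIGH_IS_BASAL, 1.0 - bal_classical)):
        j = np.argmax(bal)
        top = bal[j]
        close = np.flatnonzero(bal >= top - 1e-12)
        dist = np.abs(t_cand[close] - cohort_mean)
        k = close[np.argmin(dist)]
        key = (-bal[k], abs(t_cand[k] - cohort_mean), 0 if orient == HIGH_IS_CLASSICAL else 1)
        if best is None or key < best[0]:
            best = (key, float(t_cand[k]), orient, float(bal[k]))
    return best[1], best[2], best[3]


def calibrate_threshold(
    agg: Mapping[str, float], labels: Mapping[str, int]
) -> tuple[float, str, float]:
    """Calibrated (threshold, orientation, balanced accuracy) for a module
    aggregate against binary subtype labels (1 = Classical)."""
    x, y = _align(agg, labels)
    return _calibrate_arrays(x, y)


def _sens_spec_at(x: np.ndarray, y: np.ndarray, t: float, orientation: str):
    pred = (x >= t).astype(int)
    if orientation == HIGH_IS_BASAL:
        pred = 1 - pred
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _score_arrays(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, str]:
    if np.ptp(x) == 0:
        # constant aggregate carries no information
        t, orient, _ = x[0], HIGH_IS_CLASSICAL, 0.5
        return 0.5, 0.0, 1.0, float(t), orient
    t, orient, _ = _calibrate_arrays(x, y)
    auc_raw = roc_auc(x, y)
    auc = max(auc_raw, 1.0 - auc_raw)  # orientation-corrected
    sens, spec = _sens_spec_at(x, y, t, orient)
    return auc, sens, spec, t, orient


def score_module(
    m: ExpressionMatrix, genes: Sequence[str], labels: Mapping[str, int]
) -> GeneModule:
    """Score a module: orientation-corrected rank AUC of its aggregate plus
    sensitivity/specificity at the calibrated threshold."""
    agg = module_aggregate(m, genes)
    x, y = _align(agg, labels)
    auc, sens, spec, t, orient = _score_arrays(x, y)
    return GeneModule(list(genes), auc, sens, spec, t, orient, stage="screen")


# ---------------------------------------------------------------------------
# Stage 2


def stage2_screen(
    m: ExpressionMatrix, labels: Mapping[str, int], cfg: SamplerConfig
) -> tuple[GeneModule, ScreenTrace]:
    """Monte Carlo screen of random ``subset_size``-gene modules.

    Draws are uniform without replacement within each module, from a seeded
    generator; screening stops as soon as a module's AUC reaches
    ``target_auc``, otherwise the best of ``n_iters`` modules is returned.
    """
    if not m.normalized:
        raise ValueError("stage2_screen expects a z-scored matrix")
    if m.n_genes < cfg.subset_size:
        raise ValueError(
            f"only {m.n_genes} genes available, need subset_size={cfg.subset_size}"
        )
    col = np.array([i for i, s in enumerate(m.sample_ids) if s in labels])
    if col.size == 0:
        raise ValueError("no labeled samples")
    y = np.array([int(labels[m.sample_ids[i]]) for i in col], dtype=int)
    if y.min() == y.max():
        raise ValueError("screening labels contain a single class")
    values = m.values[:, col]

    rng = np.random.default_rng(cfg.seed)
    trace = ScreenTrace()
    best: tuple[float, int, np.ndarray, tuple] | None = None
    for it in range(cfg.n_iters):
        idx = rng.choice(m.n_genes, size=cfg.subset_size, replace=False)
        x = values[idx].mean(axis=0)
        auc, sens, spec, t, orient = _score_arrays(x, y)
        genes_hash = hashlib.md5(
            ",".join(sorted(m.gene_ids[i] for i in idx)).encode()
        ).hexdigest()
        trace.records.append(ScreenRecord(it, genes_hash, auc, sens, spec, t))
        if best is None or auc > best[0]:
            best = (auc, it, idx, (sens, spec, t, orient))
        if auc >= cfg.target_auc:
            trace.stopped_early = True
            break
    auc, _, idx, (sens, spec, t, orient) = best
    module = GeneModule(
        [m.gene_ids[i] for i in idx], auc, sens, spec, t, orient, stage="screen"
    )
    return module, trace


# ---------------------------------------------------------------------------
# Stage 3


def _cv_test_auc(
    x: np.ndarray, y: np.ndarray, folds: Sequence[tuple[np.ndarray, np.ndarray]]
) -> float:
    """Mean test-fold AUC with threshold/orientation calibrated on train."""
    aucs = []
    for tr, te in folds:
        _, orient, _ = _calibrate_arrays(x[tr], y[tr])
        a = roc_auc(x[te], y[te])
        if orient == HIGH_IS_BASAL:
            a = 1.0 - a
        aucs.append(a)
    return float(np.mean(aucs))


def stage3_refine(
    m: ExpressionMatrix,
    labels: Mapping[str, int],
    module200: GeneModule,
    cfg: SamplerConfig,
    n_folds: int = 5,
    n_draws: int | None = None,
    candidates: Sequence[Sequence[str]] | None = None,
) -> GeneModule:
    """Refine the screened module down to ``refine_size`` genes.

    Candidate subsets are drawn from the screened module with replacement
    (so the same gene can be drawn repeatedly) and de-duplicated before
    scoring; each candidate is ranked by its mean test AUC over stratified
    ``n_folds``-fold cross-validation, with the classification threshold
    calibrated on the train folds only. Pass ``candidates`` to score an
    explicit list of gene subsets instead of random draws.
    """
    if len(module200.gene_ids) < cfg.refine_size:
        raise ValueError("screened module smaller than refine_size")
    col = np.array([i for i, s in enumerate(m.sample_ids) if s in labels])
    y = np.array([int(labels[m.sample_ids[i]]) for i in col], dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds minority class count {counts.min()}"
        )
    values = m.values[:, col]
    pool = m.gene_indices(module200.gene_ids)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed % (2**31))
    folds = list(skf.split(np.zeros(len(y)), y))

    if candidates is None:
        n_draws = cfg.n_iters if n_draws is None else n_draws
        rng = np.random.default_rng(cfg.seed + 1)
        candidate_idx = [
            np.unique(rng.choice(pool, size=cfg.refine_size, replace=True))
            for _ in range(n_draws)
        ]
    else:
        candidate_idx = [m.gene_indices(c) for c in candidates]
        bad = [i for i, c in enumerate(candidate_idx) if not set(c) <= set(pool)]
        if bad:
            raise ValueError("candidate subsets must come from the screened module")

    best_idx, best_auc = None, -np.inf
    for cidx in candidate_idx:
        x = values[cidx].mean(axis=0)
        cv_auc = _cv_test_auc(x, y, folds)
        if cv_auc > best_auc:
            best_auc, best_idx = cv_auc, cidx
    x = values[best_idx].mean(axis=0)
    t, orient, _ = _calibrate_arrays(x, y)
    sens, spec = _sens_spec_at(x, y, t, orient)
    return GeneModule(
        [m.gene_ids[i] for i in best_idx],
        float(best_auc),
        sens,
        spec,
        float(t),
        orient,
        stage="refined",
    )


# ---------------------------------------------------------------------------
# statsmodels-style wrapper


class GeneModuleScreen:
    """Model object running the full three-stage screen on a TPM matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Un-normalized TPM matrix.
    labels : mapping sample_id -> {0, 1}
        Pre-classified subtype ground truth (1 = Classical). Samples
        missing from the mapping are excluded from screening.
    config : SamplerConfig
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        labels: Mapping[str, int],
        config: SamplerConfig | None = None,
    ) -> None:
        self.expr = expr
        self.labels = dict(labels)
        self.config = config or SamplerConfig()

    def fit(self, n_folds: int = 5, refine_draws: int | None = None) -> "ScreenResults":
        filtered = stage1_filter(self.expr, self.config)
        z = zscore_genes(filtered)
        best, trace = stage2_screen(z, self.labels, self.config)
        refined = stage3_refine(
            z, self.labels, best, self.config, n_folds=n_folds, n_draws=refine_draws
        )
        return ScreenResults(self, filtered, z, best, refined, trace)


class ScreenResults:
    """Results of :class:`GeneModuleScreen.fit`."""

    def __init__(self, model, filtered, zscored, screen_module, refined_module, trace):
        self.model = model
        self.filtered = filtered
        self.zscored = zscored
        self.screen_module = screen_module
        self.refined_module = refined_module
        self.trace = trace

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Gene module screen",
            "=" * 58,
            f"genes in / after stage 1     {self.model.expr.n_genes:>6} / {self.filtered.n_genes}",
            f"screen iterations run        {len(self.trace):>6} (early stop: {self.trace.stopped_early})",
            f"subset size / refine size    {cfg.subset_size:>6} / {cfg.refine_size}",
            f"screen module AUC            {self.screen_module.auc:>9.3f}",
            f"refined module CV test AUC   {self.refined_module.auc:>9.3f}",
            f"refined sens / spec          {self.refined_module.sensitivity:>9.3f} / "
            f"{self.refined_module.specificity:.3f}",
            f"refined threshold ({self.refined_module.orientation})  "
            f"{self.refined_module.threshold:.4f}",
            "=" * 58,
        ]
        return "\n".join(lines)
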