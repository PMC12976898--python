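"""Subtype labeling from expression: ssGSEA scores and z-score tiers.

Ground-truth basal/classical calls follow the two-signature protocol:
per-sample ssGSEA enrichment for a classical and a basal gene signature,
score = classical - basal, z-scored across the cohort, then thresholded at
|z| = 1 into Classical / Basal / Intermediate. Only non-Intermediate calls
are treated as high-confidence.

The ssGSEA statistic is a weighted Kolmogorov-Smirnov running sum: genes
are ranked by within-sample expression (descending, ties broken by gene ID
so scores are deterministic); member-gene increments are proportional to
rank-weight^alpha (alpha = ``weight_exponent``, default 0.25), non-member
increments are uniform; the score sums the hit-minus-miss ECDF difference
over ranks. If the gene set covers every gene (no miss set), the score is
defined by the hit running sum alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SubtypeLabel",
    "ssgsea_scores",
    "moffitt_score",
    "assign_subtypes",
    "labels_to_frame",
]

CLASSICAL = "Classical"
BASAL = "Basal"
INTERMEDIATE = "Intermediate"


@dataclass(frozen=True)
class SubtypeLabel:
    """Per-sample subtype call with its confidence tier."""

    sample_id: str
    score: float
    zscore: float
    label: str  # Classical | Basal | Intermediate
    high_confidence: bool


def ssgsea_scores(
    m: ExpressionMatrix,
    gene_set: Sequence[str],
    weight_exponent: float = 0.25,
) -> dict[str, float]:
    """Per-sample single-sample enrichment score for ``gene_set``."""
    if m.n_genes < 2:
        raise ValueError("ssGSEA requires a matrix with at least 2 genes")
    members = sorted(set(gene_set))
    present = [g for g in members if g in m._gene_index]
    if not present:
        raise KeyError(f"no gene-set member present in matrix; missing: {members[:10]}")

    n = m.n_genes
    # lexicographic rank of each gene ID, used to break expression ties
    lex_rank = np.empty(n, dtype=int)
    lex_rank[np.argsort(np.asarray(m.gene_ids, dtype=object))] = np.arange(n)
    hit_mask_genes = np.zeros(n, dtype=bool)
    hit_mask_genes[m.gene_indices(present)] = True

    rank_weight = np.arange(n, 0, -1, dtype=float)  # n for top-ranked gene
    scores: dict[str, float] = {}
    for j, sample in enumerate(m.sample_ids):
        vals = m.values[:, j]
        # descending by expression, ascending gene-ID lex order on ties
        order = np.lexsort((lex_rank, -vals))
        hits = hit_mask_genes[order]
        w = np.where(hits, rank_weight**weight_exponent, 0.0)
        hit_cdf = np.cumsum(w) / w.sum()
        n_miss = n - hits.sum()
        if n_miss == 0:
            # degenerate all-gene set: hit running sum alone (documented)
            scores[sample] = float(np.sum(hit_cdf))
            continue
        miss_cdf = np.cumsum(~hits) / n_miss
        scores[sample] = float(np.sum(hit_cdf - miss_cdf))
    return scores


def moffitt_score(
    classical: Mapping[str, float], basal: Mapping[str, float]
) -> dict[str, float]:
    """Per-sample classical-minus-basal enrichment difference."""
    if set(classical) != set(basal):
        extra = set(classical) ^ set(basal)
        raise ValueError(f"sample key mismatch between score maps: {sorted(extra)[:10]}")
    return {s: classical[s] - basal[s] for s in classical}


def assign_subtypes(
    scores: Mapping[str, float], threshold: float = 1.0
) -> list[SubtypeLabel]:
    """Z-score the raw scores across samples and threshold into subtypes.

    z > +threshold -> Classical; z < -threshold -> Basal; the closed
    interval [-threshold, +threshold] -> Intermediate (low confidence).
    """
    if len(scores) < 2:
        raise ValueError("subtype assignment requires at least 2 samples")
    samples = list(scores)
    raw = np.array([scores[s] for s in samples], dtype=float)
    sd = raw.std()  # population
    if sd == 0:
        raise ValueError("zero score variance: z-scores undefined")
    z = (raw - raw.mean()) / sd
    out = []
    for s, r, zi in zip(samples, raw, z):
        if zi > threshold:
            label = CLASSICAL
        elif zi < -threshold:
            label = BASAL
        else:
            label = INTERMEDIATE
        out.append(SubtypeLabel(s, float(r), float(zi), label, label != INTERMEDIATE))
    return out


def labels_to_frame(labels: Sequence[SubtypeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [l.sample_id for l in labels],
            "score": [l.score for l in labels],
            "zscore": [l.zscore for l in labels],
            "label": [l.label for l in labels],
            "high_confidence": [l.high_confidence for l in labels],
        }
    )
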