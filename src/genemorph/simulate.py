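"""Synthetic cohorts with the statistical structure the method assumes.

Two generators make the full pipeline testable without any download:

* :func:`simulate_expression` — a TPM-like bulk expression matrix with two
  latent subtypes. A planted co-expressed module (pairwise correlation
  ``within_module_rho`` via a shared factor) is shifted between subtypes by
  ``effect_size`` standard deviations *per gene*; because idiosyncratic
  noise averages out, the module aggregate separates the subtypes by
  ``effect_size / sqrt(rho + (1 - rho)/m)`` — aggregation amplifies the
  per-gene signal, which is what the screening stage exploits. The
  background contains independent-noise genes, co-expressed but
  subtype-uninformative blocks (so the Stage 1 correlation filter has
  realistic survivors to screen), plus designated zero-variance and
  low-expression genes to exercise the filters. Latent values map to a
  non-negative TPM-like scale through an exponential link.
* :func:`simulate_slides` — per-sample bags of patch embeddings that are
  noisy linear mixtures of a latent gene vector whose covariance follows
  the supplied co-expression network (Sigma = c (I + alpha * Abar), Abar
  the symmetrized row-normalized adjacency) and whose mean shifts with
  subtype along the constant unit vector (the smoothest direction of any
  graph), by ``effect_size`` standard deviations.

A ``low_conf_fraction`` of samples has its subtype shift attenuated by
``low_conf_attenuation`` — molecularly ambiguous, Intermediate-tier cases
that are excluded from training and evaluated separately. All outputs are
fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .morphology import SlideBag
from .network import CoexpressionNetwork

__all__ = ["SimConfig", "simulate_expression", "simulate_slides"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's reference conditions."""

    n_samples: int = 400
    n_genes: int = 1000
    planted_genes: int = 30
    effect_size: float = 1.5
    within_module_rho: float = 0.6
    class_balance: float = 0.65  # fraction Classical
    noise_sd: float = 1.0
    n_zero_variance: int = 5
    n_low_expression: int = 5
    n_correlated_background: int = 80
    background_rho: float = 0.6
    background_block: int = 2
    patches_per_slide: int = 50
    embed_dim: int = 1536
    mixing_rank: int = 50
    embed_noise_sd: float = 0.25
    patch_noise_sd: float = 0.5
    low_conf_fraction: float = 0.25
    low_conf_attenuation: float = 0.3
    seed: int = 0
    log_sd: float = 0.25  # spread of the exponential TPM link
    base_tpm: float = 8.0  # median TPM of expressed genes
    low_expr_tpm: float = 0.1  # median TPM of sub-threshold genes
    network_alpha: float = 0.5  # latent covariance weight on the network

    def __post_init__(self) -> None:
        reserved = self.planted_genes + self.n_zero_variance + self.n_low_expression
        if reserved + self.n_correlated_background > self.n_genes:
            raise ValueError("special gene groups exceed n_genes")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if not (0.0 <= self.within_module_rho < 1.0):
            raise ValueError("within_module_rho must be in [0, 1)")
        if not (0.0 <= self.low_conf_attenuation <= 1.0):
            raise ValueError("low_conf_attenuation must be in [0, 1]")


def _sample_frame(cfg: SimConfig, rng: np.random.Generator):
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    y = (rng.random(cfg.n_samples) < cfg.class_balance).astype(int)  # 1 = Classical
    low = rng.random(cfg.n_samples) < cfg.low_conf_fraction
    shift = np.where(low, cfg.low_conf_attenuation, 1.0) * cfg.effect_size
    labels = pd.DataFrame(
        {
            "sample_id": samples,
            "label": y,
            "subtype": np.where(y == 1, "Classical", "Basal"),
            "high_confidence": ~low,
        }
    )
    return samples, y, shift, labels


def simulate_expression(cfg: SimConfig):
    """Returns (ExpressionMatrix in TPM space, labels DataFrame, truth dict).

    Labels carry columns sample_id, label (1 = Classical), subtype and
    high_confidence; truth records the planted gene IDs and the config.
    """
    rng = np.random.default_rng(cfg.seed)
    samples, y, shift, labels = _sample_frame(cfg, rng)
    n, p = cfg.n_samples, cfg.n_genes

    gene_ids: list[str] = []
    rows = np.empty((p, n))
    r = 0

    # planted module: shared factor + idiosyncratic noise + subtype shift.
    # effect_size is the *marginal*-sd standardized shift: the within-class
    # noise is scaled so each planted gene has unit cohort variance, making
    # the effect invariant under the pipeline's per-gene z-scoring.
    # within_module_rho is the within-class pairwise correlation.
    b, q, a, s = cfg.class_balance, cfg.low_conf_fraction, cfg.low_conf_attenuation, cfg.effect_size
    mean_shift = b * s * ((1 - q) + q * a)
    var_shift = b * s**2 * ((1 - q) + q * a**2) - mean_shift**2
    if var_shift >= 0.95:
        raise ValueError(
            f"effect_size {s} infeasible: subtype shift would explain "
            f"{var_shift:.2f} of unit marginal variance"
        )
    within_sd = np.sqrt(1.0 - var_shift)
    rho = cfg.within_module_rho
    factor = rng.standard_normal(n)
    for k in range(cfg.planted_genes):
        eps = rng.standard_normal(n)
        rows[r] = within_sd * (np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps) + shift * y
        gene_ids.append(f"MOD{k:04d}")
        r += 1

    # co-expressed but uninformative background blocks
    rb = cfg.background_rho
    k = 0
    while k < cfg.n_correlated_background:
        block = min(cfg.background_block, cfg.n_correlated_background - k)
        bf = rng.standard_normal(n)
        for _ in range(block):
            rows[r] = np.sqrt(rb) * bf + np.sqrt(1 - rb) * rng.standard_normal(n)
            gene_ids.append(f"CBG{k:04d}")
            r += 1
            k += 1

    # independent background noise
    n_bg = p - r - cfg.n_zero_variance - cfg.n_low_expression
    for k in range(n_bg):
        rows[r] = cfg.noise_sd * rng.standard_normal(n)
        gene_ids.append(f"BG{k:04d}")
        r += 1

    # exponential link onto a TPM-like scale
    tpm = cfg.base_tpm * np.exp(cfg.log_sd * rows[:r])

    # degenerate genes exercising the Stage 1 filters
    extra = np.empty((cfg.n_zero_variance + cfg.n_low_expression, n))
    for k in range(cfg.n_zero_variance):
        extra[k] = 5.0
        gene_ids.append(f"ZV{k:04d}")
    for k in range(cfg.n_low_expression):
        extra[cfg.n_zero_variance + k] = cfg.low_expr_tpm * np.exp(
            cfg.log_sd * rng.standard_normal(n)
        )
        gene_ids.append(f"LE{k:04d}")

    values = np.vstack([tpm, extra])
    m = ExpressionMatrix(gene_ids, samples, values, normalized=False)
    truth = {
        "planted_genes": [g for g in gene_ids if g.startswith("MOD")],
        "config": asdict(cfg),
    }
    return m, labels, truth


def _latent_covariance(network: CoexpressionNetwork, alpha: float):
    A = network.adjacency
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Arow = np.where(deg[:, None] > 0, A / np.where(deg[:, None] > 0, deg[:, None], 1.0), 0.0)
    Abar = 0.5 * (Arow + Arow.T)
    G = network.n_genes
    sigma = np.eye(G) + alpha * Abar
    # unit variance along the constant shift direction
    u = np.ones(G) / np.sqrt(G)
    c = 1.0 / float(u @ sigma @ u)
    return c * sigma


def simulate_slides(
    labels: pd.DataFrame, network: CoexpressionNetwork, cfg: SimConfig
) -> list[SlideBag]:
    """Per-sample patch-embedding bags driven by a network-aligned latent.

    Each sample draws a latent G-vector from N(mu_class, Sigma) with Sigma
    aligned to the network adjacency; each patch embedding is
    M (latent + patch noise) + embedding noise, with a fixed seeded mixing
    matrix M of rank ``mixing_rank``. Labels (and confidence tiers) are
    copied from the input frame.
    """
    G = network.n_genes
    if cfg.mixing_rank > cfg.embed_dim:
        raise ValueError("mixing_rank cannot exceed embed_dim")
    rng = np.random.default_rng(cfg.seed + 1)
    sigma = _latent_covariance(network, cfg.network_alpha)
    chol = np.linalg.cholesky(sigma)
    u = np.ones(G) / np.sqrt(G)

    r = min(cfg.mixing_rank, G)  # rank is a property of the latent space
    M = (rng.standard_normal((cfg.embed_dim, r)) @ rng.standard_normal((r, G))) / np.sqrt(r * G)

    bags: list[SlideBag] = []
    for _, row in labels.iterrows():
        shift = cfg.effect_size * (1.0 if row["high_confidence"] else cfg.low_conf_attenuation)
        mu = shift * int(row["label"]) * u
        latent = mu + chol @ rng.standard_normal(G)
        patches = latent[None, :] + cfg.patch_noise_sd * rng.standard_normal(
            (cfg.patches_per_slide, G)
        )
        emb = patches @ M.T + cfg.embed_noise_sd * rng.standard_normal(
            (cfg.patches_per_slide, cfg.embed_dim)
        )
        bags.append(
            SlideBag(str(row["sample_id"]), emb.astype(np.float32), int(row["label"]))
        )
    return bags
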