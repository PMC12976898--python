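# genemorph

Graph-constrained gene–morphology alignment for molecular subtyping of
pancreatic ductal adenocarcinoma (PDAC).

Transcriptomic subtypes of PDAC (basal-like vs classical, with basal
carrying the worse prognosis) are defined in expression space, but
sequencing is slow and costly, while an H&E slide exists for essentially
every patient. `genemorph` implements a two-part bridge between the two
modalities, for computational pathologists and cancer genomics researchers:

1. **Gene-module discovery.** A hierarchical Monte Carlo screen over bulk
   TPM expression: Stage 1 filters genes with no variance, low expression
   (< 1 TPM median) or no co-expression partner (|r| > 0.5); Stage 2 draws
   thousands of random gene modules and scores how well each module's mean
   z-score aggregate bifurcates the cohort into ssGSEA-derived subtype
   labels (rank AUC + a calibrated threshold); Stage 3 refines the winner
   to a 50-gene module by resampling with replacement under stratified
   cross-validation.
2. **Morphology-only classification.** The refined module's co-expression
   network (edge weights |Pearson r|, Laplacian L = D − A) regularizes a
   multiple-instance classifier over slide patch embeddings: a shared MLP
   encoder, one linear *gene head* per network gene, mean pooling to a
   slide-level gene-latent vector Ĝ, and a sigmoid classifier, trained with

   ```
   loss = BCE(ŷ, y) + λ_graph · ĜᵀLĜ + λ_dis · ‖G̃ᵀG̃ − I‖_F
   ```

   where ĜᵀLĜ = ½ Σᵢⱼ Aᵢⱼ(Ĝᵢ − Ĝⱼ)² forces latents of co-expressed genes
   to co-vary, and the Frobenius term (on the column-normalized patch-level
   latent matrix) discourages gene heads from collapsing onto one
   direction. Defaults: λ_graph = 1.0, λ_dis = 0.1, Adam lr 1e−4, 30
   epochs, slide-level batch 1, 80/20 split.

Subtype ground truth follows the two-signature protocol: per-sample ssGSEA
for a classical and a basal signature, score = classical − basal, z-scored
across the cohort and thresholded at |z| = 1 into Classical / Basal /
Intermediate; only non-Intermediate (*high-confidence*) samples train
models, Intermediate cases are evaluated separately.

A fully seeded synthetic-data module generates TPM cohorts with a planted
co-expressed module and slide bags whose patch embeddings are noisy linear
mixtures of a network-aligned latent, so the entire pipeline runs and is
tested without any restricted-access data. See `docs/methods.md` for the
model details and design decisions.

## Worked example

Discover a gene module on a synthetic cohort with a planted 20-gene signal:

```python
from genemorph import GeneModuleScreen, SamplerConfig
from genemorph.simulate import SimConfig, simulate_expression

sim = SimConfig(n_samples=200, n_genes=400, planted_genes=20,
                n_correlated_background=60, seed=7)
expr, labels, truth = simulate_expression(sim)
hc = labels[labels.high_confidence]
ymap = dict(zip(hc.sample_id, hc.label))          # 1 = Classical
cfg = SamplerConfig(subset_size=60, n_iters=150, target_auc=1.0,
                    refine_size=25, seed=7)
res = GeneModuleScreen(expr, ymap, cfg).fit(refine_draws=100)
print(res.summary())
```

prints

```
Gene module screen
==========================================================
genes in / after stage 1        400 / 76
screen iterations run           150 (early stop: False)
subset size / refine size        60 / 25
screen module AUC                0.971
refined module CV test AUC       0.980
refined sens / spec              0.926 / 0.920
refined threshold (high_is_classical)  -0.1162
==========================================================
```

Stage 1 kept 76 of 400 genes (the planted module, the co-expressed
background, and nothing constant or low-expressed). The best random
60-gene module separates high-confidence Classical from Basal samples at
AUC 0.971 on the screening cohort — an optimistic, best-of-150 estimate —
while the refined ≤25-gene module reaches 0.980 under 5-fold
cross-validation, the honest figure: refinement discarded weakly
contributing genes without losing accuracy. The threshold is in z-score
aggregate units with the `high_is_classical` orientation (aggregate above
threshold ⇒ Classical).

From here, `CoexpressionNetwork.from_expression(...)` builds the module's
network and `MorphologyGeneModel(bags, network, TrainConfig()).fit()`
trains the slide-level classifier; `fit()` returns a results object with
the per-epoch history, `predict`, `gene_latents` and `summary()`.

The same pipeline is scriptable end to end:

```bash
genemorph run-all --config run.yaml --seed 1 --out-dir run/
```

with YAML sections (`simulate`, `label`, `sample`, `network`, `train`,
`evaluate`) whose keys mirror the stage configurations
(`SUBSET_SIZE`, `TARGET_AUC`, `LAMBDA_GRAPH`, ...); every run writes a
`manifest.json` with config, seeds, content hashes and timings sufficient
to rerun bit-identically.

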