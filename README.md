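# lsphen

Latent-space phenotyping from plot-level field imagery, end to end:

1. **synthetic_data** — generates a whole synthetic field experiment with the
   causal structure the pipeline assumes (genotype → breeding value → trait →
   canopy appearance): founder-mosaic SNP genotypes with controllable MAF,
   missingness and LD; five correlated biomass traits (dry weight, main stem
   length, node count, branch count, plant height) with configurable
   heritability and a multiplicative drought treatment; and procedural RGB +
   DSM plot scenes whose geometry encodes the traits (DSM peak = plant
   height, vegetation area ∝ dry weight, texture granularity ∝ node+branch
   counts).
2. **preprocess** — VDVI vegetation segmentation ((2G−R−B)/(2G+R+B),
   threshold 0.057, dark pixels with G < 10 removed), rigid canopy
   alignment + padding to a fixed size, 4× flip augmentation, and z-score
   trait normalisation.
3. **cnn** — three multi-trait CNN regressors (RGB / DSM / early-fusion
   RGB-DSM) with a 30-dimensional bottleneck and a purely linear head
   (estimates = XW + 1bᵀ), trained with Adam + MSE + reduce-on-plateau and
   evaluated by repeated k-fold cross-validation with per-treatment Pearson
   correlations. Implemented on a small seeded numpy backend (im2col
   convolutions, manual backprop) so everything runs deterministic on one
   CPU with no deep-learning framework.
4. **latent** — PCA of the bottleneck features, rotation of the head into PC
   space (W′ = EᵀW, exact), per-PC sign alignment across CV trials, weight
   averaging and a PC↔trait annotation graph.
5. **gblup** — SNP QC (MAF ≥ 0.025, missing < 0.05), modal imputation,
   VanRaden GRM (G = XXᵀ/c, c = 2Σp(1−p)), eigenbasis REML GBLUP, joint-MVN
   prediction of held-out accessions, and accession-wise cross-validated
   accuracy per treatment.
6. **pc_predict** — trait prediction from genomically predicted PC scores
   (Ỹ = S̃W′ + 1bᵀ) with fold-local PCA (leakage-free), swept over the
   number of PCs l = 1..10, plus a direct-GBLUP vs PC-mediated comparison on
   shared fold splits.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (gradient checks,
algebraic identities, leakage audits) and `tests/test_acceptance.py` with one
test per acceptance criterion. The complete run takes a few minutes on one
CPU; the desk-scale CNN training test dominates.

## CLI

Every stage is a subcommand of `lsp`, driven by one YAML config and cached by
config hash (a stage reruns only when its config or its upstream outputs
change):

```bash
lsp run --config config.yaml            # simulate → … → report
lsp run --config config.yaml --dry-run  # print the plan
lsp simulate --config config.yaml       # single stage (add --force to redo)
```

Minimal config:

```yaml
seed: 1
outdir: my_run
simulate: {n_accessions: 40, n_reps: 2, n_snps: 500, image_height: 96, image_width: 128}
train: {variant: rgb_dsm, epochs: 10, batch_size: 64}
gblup: {cv_k: 5, cv_reps: 2}
pc_predict: {l_max: 10}
```

Stage outputs are plain files (PNG / float-TIFF / CSV / VCF / JSON) under
`outdir/<stage>/`, each with a `manifest.json` recording config hash, seed
and wall time.

## Notes and limitations

- The published layer-by-layer CNN table is not available; the default stack
  (5 conv–batchnorm–ReLU–maxpool blocks, two hidden linear layers, linear
  30-unit bottleneck with non-affine batch norm, linear head; 14 weighted
  layers) is a documented reconstruction, overridable via `ModelSpec`.
- Default training protocol (Adam, lr 1e-3,
  batch 128, 100 epochs, reduce-on-plateau factor 0.5 / patience 5 /
  min_lr 1e-6, best-validation checkpoint); desk-scale runs use fewer epochs.
- Augmentation is applied to training folds only by default;
  `augment_before_split=True` replicates whole-dataset augmentation.
- PCs are matched across CV trials by explained-variance rank only; no
  permutation matching is attempted.
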