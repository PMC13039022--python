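# hepaseg

3D liver/tumor CT segmentation toolkit built around three ideas: a
multi-scale context encoder at every U-Net level, a learnable
vector-quantization codebook with a straight-through estimator at the
bottleneck, and a selective state-space (linear recurrence) module for
global context — trained with a hybrid objective that adds an anatomical
containment penalty (predicted tumor probability may not exceed predicted
liver probability). The package also ships a seedable synthetic phantom
generator, the full preprocessing chain, and a spacing-aware metric suite
(Dice, VOE, RVD, ASD, 95HD, tumor-size strata), so everything is testable
end-to-end without external data.

The network runs on a small numpy-based reverse-mode autodiff engine
(`hepaseg.autograd` / `hepaseg.nn`) — no GPU or deep-learning framework
required; everything runs on one CPU.

## Layout

| module                | contents |
|-----------------------|----------|
| `hepaseg.phantoms`    | ellipsoid-liver / sphere-lesion synthetic CT volumes, NIfTI batch writer + CSV manifest |
| `hepaseg.preprocess`  | HU clipping, spline/nearest resampling, liver-slab sampling, min-max normalization |
| `hepaseg.msce`        | three-branch multi-scale context block (3³, dilated 3³ ≙ 5³, global pool) |
| `hepaseg.codebook`    | K×C prototype codebook, nearest-code assignment, straight-through estimator, two-term VQ loss, perplexity |
| `hepaseg.ssm`         | sequence flattening, gated linear scan `h_t = a(x_t)⊙h_{t−1} + W_b x_t`, residual bottleneck module |
| `hepaseg.net`         | full segmentation network with two sigmoid heads (organ region / tumor), ablation switches, checkpoints |
| `hepaseg.losses`      | soft-Dice+BCE segmentation loss, containment penalty, hybrid weighting (α, β, λ) |
| `hepaseg.metrics`     | Dice/VOE/RVD, surface extraction, ASD/95HD in mm, size-stratified lesion Dice |
| `hepaseg.cli`         | training protocol (Adam 1e-4, batch 1), seed replication with mean±sd reporting, CLI verbs |

## CLI

```bash
hepaseg phantoms generate --out data/ --count 3 --seed 0
hepaseg preprocess run --in img.nii.gz --mask lab.nii.gz --out pre/
hepaseg train --manifest data/manifest.csv --seed 42 --out runs/
hepaseg replicate --manifest data/manifest.csv --out runs/
hepaseg evaluate --pred preds/ --gt gts/ --report report.csv
```

Training defaults follow the reference protocol: Adam (lr 1e-4, β1 0.9,
β2 0.999, ε 1e-8, weight decay 1e-5), batch size 1, 160 epochs, seed
replicates (42, 57, 89) aggregated as mean ± sample sd. Loss weights
default to α=0.4, β=0.6, λ=0.25; codebook K=64, C=64; state size n=16 on
d=64 embeddings. All of these are exposed in the YAML config
(`TrainConfig.to_yaml()` / `from_yaml()`).

## Notes

- Arrays are (z, y, x); axial slices index the first axis. NIfTI I/O
  preserves spacing and affine.
- Labels: 0 background, 1 liver, 2 tumor (tumor voxels are carved out of
  the liver label; the "whole organ" region is labels 1∪2).
- The liver head predicts the whole organ region so that the containment
  penalty `mean(max(0, T − L))` is exactly zero for anatomically valid
  predictions.
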