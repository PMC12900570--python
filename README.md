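# gfssnet

Graph-guided, frequency-enhanced state-space network for 3D dual-modality
(T1/T2) lumbar-spine MRI segmentation, implemented in pure NumPy on a small
tape-based autograd engine so the whole pipeline — synthetic data, model,
training, evaluation — runs offline on a single CPU.

## Components

| Module | What it does |
| --- | --- |
| `gfssnet.phantom_io` | NIfTI I/O, preprocessing (48×256×256 resampling, z-scoring), seeded augmentation, and a deterministic dual-contrast spine phantom generator (5 superellipsoidal vertebrae + 4 disc slabs, Rician noise, smooth bias field) |
| `gfssnet.fdconv` | Frequency dynamic convolution: depthwise sigmoid-gated modulation, per-sample softmax attention over N parallel kernels, fused convolution |
| `gfssnet.td_mamba` | Three-directional state-space block: literal recurrence oracle, O(T) selective scan, axis flatten/unflatten, per-axis branches with concat + pointwise fusion |
| `gfssnet.see_encoder` | Four-stage dual-path (conv + scan) encoder with residuals and strided downsampling; one instance per modality |
| `gfssnet.paaf` | Bottleneck fusion: per-modality scan enhancement with channel gating, channel-pairwise cross-modal compression, position attention from axis-pooled descriptors |
| `gfssnet.spine_graph` | 10-node anatomical graph (background, L1–L5, four discs), symmetric-normalised adjacency, feature↔graph projections, 3-layer GCN, residual back-projection |
| `gfssnet.dapu_decoder` | Depth-aware progressive upsampling: slice attention, multi-scale dilated boundary branch, ×2 trilinear upsampling, skip fusion |
| `gfssnet.losses` | Hybrid frequency-domain-aware Tversky loss family (class-weighted Tversky, gradient-magnitude matching, vertebra-focused and hybrid blends) |
| `gfssnet.metrics` | DSC/IoU with +1 smoothing, HD95 and ASSD in mm over 6-connected surfaces |
| `gfssnet.network` | Full model assembly, Adam training loop with stepped LR / deep-supervision schedules and early stopping, prediction, evaluation tables |
| `gfssnet.nn` | Minimal reverse-mode autograd (conv3d, trilinear interpolation, linear scan, usual elementwise/reduction ops) |

## CLI

```bash
gfssnet generate-phantom --shape 48,64,64 --seed 1 --out-dir data/case0
gfssnet train --data-dir data --test-profile --epochs 50 --out ckpt.npz
gfssnet predict --checkpoint ckpt.npz --t1 data/case0/t1.nii.gz \
    --t2 data/case0/t2.nii.gz --out pred.nii.gz
gfssnet evaluate --pred-dir preds --gt-dir gts --out metrics.csv
```

Volumes are NIfTI-1; metrics come out as CSV with per-case rows plus
mean/std aggregates; training logs are JSON-lines.

## Notes

- Arrays are (depth, height, width) with depth as the sagittal slice axis;
  network inputs are (batch, channels, D, H, W) and all three spatial dims
  must be divisible by 16.
- Training defaults follow the published protocol: Adam at 1e-3 with the
  rate ×0.8 every 30 epochs, deep-supervision weight 0.4 on the same decay,
  early stopping on mean validation Dice of vertebra + disc.
- `gfssnet.network.TEST_PROFILE` is a reduced-width configuration
  (channels 8/16/32/64, state size 4) used by CI so training runs fit a
  single-CPU budget.
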