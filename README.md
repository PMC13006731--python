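# rst2g

Residual-guided spatiotemporal transformer with graph fusion enhancement for
breast-tumour segmentation in dynamic contrast-enhanced MRI (DCE-MRI).

## The problem

DCE-MRI acquires a pre-contrast volume and one or more post-contrast volumes
after gadolinium injection. Tumours enhance preferentially, so the residual
image — the voxel-wise difference `post − pre` — carries most of the
diagnostic signal, but tumour appearance is heterogeneous and the contrast
dynamics couple information across slices and acquisition phases. This
package implements a segmentation model built around that structure, for
researchers who want a fully testable, CPU-runnable reference implementation
of the architecture together with a synthetic phantom cohort generator so
that every stage (training included) runs without downloading any imaging
collection.

## The model

Each study contributes three co-registered branches: pre-contrast `X_pre`,
post-contrast `X_post`, and residual `X_res = X_post − X_pre` (phases are
min–max normalised to [0, 1] first, so the residual lies in [−1, 1]). A
batch is a window of B consecutive slices of one study; the batch axis
doubles as the slice axis.

1. **Shared hybrid encoder.** One parameter set encodes all three branches:
   a pyramid of DownBlocks (2×2 max pooling, 3×3 convolution + batch norm +
   ReLU with a projected residual shortcut), topped at the bottleneck by
   pre-norm transformer blocks (default 6 layers, 4 heads) over the
   flattened token sequence, `softmax(QKᵀ/√d_k)V` per head.
2. **Multi-scale refinement (MSR).** At every stage the three modality maps
   pass modality-specific 3×3 transforms, are concatenated, fused by a
   channel-wise MLP, and recalibrated by a spatial sigmoid gate:
   `F_out = F_fused ⊙ σ(Conv1×1(F_fused))`.
3. **Spatiotemporal graph enhancement (STGE).** Per modality, every
   bottleneck position is a node of a dense graph; a graph-attention layer
   computes `α_ij = softmax_j LeakyReLU(aᵀ[Wh_i ‖ Wh_j])` and aggregates
   `h_i = ELU(Σ_j α_ij W h_j)` (inter-slice attention, with a batch-slice
   recalibration that reads the batch axis as adjacent slices), then the
   three modality maps are fused channel-wise with a sigmoid spatial gate
   (inter-temporal attention).
4. **Decoder.** U-Net-style: bilinear 2× upsampling, skip concatenation
   with the refined stage maps, two conv blocks per stage, and a 1×1 logit
   head; sigmoid + 0.5 threshold gives the binary mask.

Training minimises `L = L_Dice + λ·L_BCE + β·L_Boundary` with λ = 0.5,
β = 0.2; the boundary term is an L1 distance between Sobel responses of
prediction and target. Optimisation is Adam (lr 10⁻³, weight decay 10⁻⁴,
batch size 4). Evaluation reports DSC, Jaccard index and relative volume
difference with patient-level stratified splits (30% hold-out + stratified
k-fold, k = 5, stratum = tumour-volume half).

The compute backend is a compact numpy reverse-mode autograd engine
(`rst2g.nn`) providing exactly the layers the model needs, so the full
pipeline — training included — runs on a single CPU.

## Worked example

```python
import rst2g

# a 10-patient synthetic cohort: enhancing ellipsoidal tumours, Gaussian noise
cohort = rst2g.generate_cohort(10, shape=(16, 32, 32), seed=7)
split = rst2g.split_patients(cohort, k=5, test_frac=0.3, seed=7)
by_id = {s.patient_id: s for s in cohort}

model = rst2g.RST2G(rst2g.RST2GConfig.tiny((32, 32), seed=7))
model, history = rst2g.train(model, [by_id[p] for p in split.train_ids],
                             rst2g.TrainConfig(epochs=8, seed=7))
table = rst2g.evaluate_model(model, [by_id[p] for p in split.test_ids])
print(table.to_string(index=False))
```

prints (abridged):

```
 patient_id      dsc       ji      rvd
phantom-004 0.925620 0.861538 0.160714
phantom-001 0.925968 0.862142 0.159902
phantom-000 0.945385 0.896426 0.113821
phantom-002 0.928198 0.866016 0.154713
       mean 0.931293 0.871531 0.147288
         sd 0.008196 0.014476 0.019458
```

i.e. on held-out phantom patients the model recovers the tumour with mean
DSC ≈ 0.93: the overlap between predicted and true masks is near-perfect,
and the positive RVD says the predictions are slightly over-inclusive.

The same workflow is available from the shell:

```bash
rst2g phantom --n-patients 10 --shape 16 32 32 --seed 7 --out cohort/
rst2g train --manifest cohort/manifest.csv --seed 7 --checkpoint model.ckpt
rst2g evaluate --checkpoint model.ckpt --manifest cohort/manifest.csv --out metrics.csv
rst2g gradcam --checkpoint model.ckpt --pre cohort/phantom-000_pre.nii.gz \
      --post cohort/phantom-000_post0.nii.gz --mask cohort/phantom-000_mask.nii.gz \
      --out overlays/
```

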