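# gbsd — grid-based structural and dimensional explainable lesion classification

`gbsd` is an end-to-end, CPU-only pipeline for binary skin-lesion
classification (benign vs. malignant) on dermoscopy-style images, built so
that every decision it makes can be inspected visually.  It is aimed at
researchers studying explainable texture-based lesion classification who
want a fully reproducible, dependency-light reference implementation that
runs without GPUs, downloads, or clinical data.

## What it computes

1. **ROI preprocessing** — morphological hair removal (multi-orientation
   black-hat + median inpainting), Gaussian smoothing, and per-pixel
   adaptive thresholding (`I < mean_w(I) − offset`) to localize the lesion,
   which is cropped and resized to 128×128.
2. **Grid-based descriptors** — four families of per-pixel feature maps,
   concatenated channel-wise:
   - *grid structural pattern*: a local-binary-pattern variant where every
     pixel of a 3×3 cell acts as an LBP center
     (`code = Σ_d U(I_d − I_c)·2^d`) and the cell value is the mean of the
     nine codes;
   - *grid directional pattern*: Kirsch-mask LDP, setting the bits of the
     m = 3 strongest of the 8 compass responses;
   - windowed mean / median / mode maps;
   - deep maps from a deterministic conv filter bank (optional VGG-16 from
     local weights).
3. **Explainable classifier** — a 3-block CNN trained in a two-pass scheme:
   pass 1 classifies the feature stack; its Grad-CAM++ map
   `H = relu(Σ_l w_l^q A^l)` and FullGrad map
   `P = |x⊙∂Y/∂x| + Σ |b·∂Y/∂b|` are fused as `OH = (H+P)/2`, and pass 2
   classifies `OH` — the explanation *is* the classifier input.
4. **AICO** — the Adaptive Intelligent Coney Optimization metaheuristic, a
   bounded population search blending coyote-style predation toward
   best/mean, deviated (foraging) search, random-hiding stashing, and a
   Taylor-series memory update of the best solution; exposed as a generic
   optimizer and as the classifier's hyperparameter tuner
   (fitness = held-out accuracy).
5. **Evaluation** — accuracy, CSI (threat score), FPR, FNR over exact
   confusion counts; stratified training-percentage (TP 80 = 80/20) and
   k-fold protocols; CSV/JSON reports.

A synthetic dermoscopy generator (star-convex lesions with controllable
border irregularity and texture heterogeneity, hair strokes, sensor noise)
makes the whole pipeline testable offline; see `docs/methods.md` for the
model details and its limitations.

## Worked example

```bash
gbsd generate   --out run/raw  --n-per-class 20 --seed 1
gbsd preprocess --in run/raw/manifest.csv  --out run/pre
gbsd features   --in run/pre/manifest.csv  --out run/feat
gbsd train      --features run/feat/manifest.csv --out run/model.ckpt --epochs 20 --seed 1
gbsd explain    --model run/model.ckpt --in run/feat/benign_00000.npz --out run/sal
```

prints (abridged):

```
wrote 40 images under run/raw
wrote ROIs for 40 images under run/pre
wrote 40 feature stacks under run/feat
final validation accuracy: 1.000
predicted class index 0; maps under run/sal
```

`run/model.ckpt.report.csv` holds the per-epoch loss/accuracy trace;
`run/sal/` contains `gradcampp.png`, `fullgrad.png` and `fused.png` — the
fused map is the single-channel image the classifier's second pass
actually consumed, with bright pixels marking the regions that drove the
prediction (on synthetic data, the lesion).  The same steps are available
as library calls (`gbsd.generate_dataset`, `gbsd.preprocess_image`,
`gbsd.extract_features`, `gbsd.train`, `gbsd.saliency_bundle`), and
`gbsd evaluate` / `gbsd tune` run the split protocols and the AICO
hyperparameter search.

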