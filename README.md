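# groomdet

Automated detection of mouse grooming from top-view video, distinguishing
**facial grooming** (class 1) from **body grooming** (class 2) and
**not grooming** (class 0).

The pipeline:

1. **preprocess** — absolute difference of consecutive frames, cropped around
   the animal's centroid, resized, grayscaled, and binarized into a stack of
   binary differential images; windows of `2w+1` consecutive diff frames
   ("grouped images") form the classifier inputs.
2. **models** — a 3D-CNN (C3D-style, five Conv3D/MaxPool3D blocks and three
   fully-connected layers) or a CRNN (per-frame 2D conv features, two LSTM
   layers, five fully-connected layers), trained with class-balanced sampling
   with replacement, rotation/flip augmentation, categorical cross-entropy,
   and the AMSGrad optimizer. The networks are implemented in pure numpy
   (forward and backward passes, finite-difference-verified gradients) so the
   package runs on a bare scientific Python stack.
3. **postfilter** — three serial rule-based filters remove implausible
   predictions: sporadic grooming runs (≤ 4 frames flanked by not-grooming),
   short interruptions inside bouts (≤ 6 frames), and short transitions
   adjacent to the other grooming class (≤ 4 frames).
4. **evaluate** — confusion matrices (body/face/not order), per-class
   sensitivity and positive predictive rate, accuracy, three-class macro F1,
   per-video bout-count Pearson correlation, and the boundary /
   oversight / false-detection error taxonomy.
5. **synthetic** — a scripted renderer (bright ellipse "mouse" on a dark
   arena, with class-distinct oscillating appendage/flank motion) generates
   videos plus ground-truth tracks obeying the annotation contract
   (bouts ≥ 5 frames, inter-bout gaps ≥ 6 frames), and a corruption operator
   injects exactly the patterns the posterior filters reverse.

## CLI

All stages are subcommands of `groomdet`; every stage writes its artifact
plus a `<artifact>.manifest.json` with the config snapshot, input hashes,
seed and timing. Configuration is a YAML file with per-stage sections
(`simulate`, `preprocess`, `model`, `train`, `filter`); command-line flags
override config values. Defaults follow the published setup (`w=40`, filter
thresholds 4/6/4, epoch plan 1000/200/400, batch size 8, dropout 0.5/0.2,
learning rates 3e-5/1e-4).

```sh
groomdet simulate --out work/ --n-videos 2 --n-bouts 4 --seed 1
groomdet preprocess work/video_00.npy --out work/video_00.stack.npz
groomdet train --stacks work/ --out work/model.npz --epochs 300 --seed 0
groomdet predict work/model.npz work/video_00.stack.npz --out work/pred.csv
groomdet filter work/pred.csv --out work/filtered.csv
groomdet evaluate work/video_00_truth.csv work/filtered.csv --raw-truth --out work/report.json
```

Video inputs can be a `.npy` frame stack `(T, H, W[, 3])`, a multi-page
TIFF, or a directory of image files. Label CSVs are `frame,label` with
0-based contiguous frame indices; prediction CSVs are
`frame,p0,p1,p2,label_raw` where `frame` indexes the diff stack (raw frame
index minus one — pass `--raw-truth` to `evaluate` when comparing against a
per-raw-frame truth CSV).

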