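# pigpen

Static-camera pig-pen detection toolkit: background-suppressed image
generation, depth-based facility masking, a dual-stream early-fusion
detector stem, a synthetic pen-scene simulator, detection metrics
(IoU / AP50 / F1) and a convolution FLOPs accountant.

## The problem

Pig detectors trained in one pen degrade badly in an *unseen* pen: the
floor texture, lighting and — critically — the feeders and pipes that
occlude the animals all change. A **static camera**, however, affords
one-time, per-environment knowledge: a background plate `f_bg` (the scene
without animals) and a depth map of that plate (higher = closer). This
package implements the preprocessing and fusion pipeline that exploits it:

* **Background suppression** — per frame `f`, compute
  `d = max_c |f − f_bg|`, threshold it with Otsu's method (foreground
  `d > t`), and keep original pixels only where the mask is set. The
  result preserves animal texture on a black background and is largely
  environment-invariant.
* **Facility masking** — Otsu on the depth map segments infrastructure
  closer than the floor; those pixels are painted white (255) in *both*
  network inputs, equalizing facility appearance across environments.
* **Dual-stream stem** — both views enter a detector stem: per-view
  stride-2 convs (3 → C), a SiLU + channel-SoftMax attention map from the
  suppressed branch scaled by a multiplier λ (default 2), element-wise
  modulation of the input branch, stacking along a new depth axis, a 3D
  convolution with spatial stride 2, and a depth max-pool — producing
  `B×C×H/4×W/4`. Because downstream layers see a quarter of the pixels,
  and conv FLOPs `2·H_out·W_out·C_out·(C_in/g)·K_h·K_w` are linear in
  `H_out·W_out`, the downstream cost drops by exactly 4×.

A seeded simulator generates static-camera pen scenes (textured floor,
occluding feeder/pipes, elliptical animals, paired background/depth
plates, visibility-filtered labels: only animals with more than 20% of
their pixels visible are labeled), and a minimal CPU-scale dense detector
lets the whole train-on-seen / test-on-unseen loop run at desk scale.

## Worked example

```python
import numpy as np
import pigpen as pp

# a seen-environment scene from the simulator
cfg = pp.seen_config(noise_std=0.0)
scene = pp.generate_scene(cfg, seed=3)

# one-time preprocessing for this environment
model = pp.build_background_model(scene.background_plate, scene.depth_plate, "seen")
print("facility coverage:", round(float((model.facility_mask > 0).mean()), 3))

# per-frame dual input
pair = pp.fuse_inputs(scene.frame, model, use_fig=True)
sup = pair.suppressed_view
print("suppressed view: non-zero fraction",
      round(float((sup.max(axis=2) > 0).mean()), 3),
      "— white at every facility pixel:",
      bool((sup[model.facility_mask > 0] == 255).all()))

# stem cost audit at 640x640
from pigpen.complexity import baseline_stem_layers, reference_downstream
audit = pp.stem_comparison(
    baseline_stem_layers(8, (640, 640)),
    pp.stem_replace_descriptor(pp.BSIConfig(channels=8)),
    reference_downstream(), (640, 640))
print("GFLOPs baseline %.2f vs dual-stem %.2f (ratio %.3f)"
      % (audit["baseline_gflops"], audit["bsi_gflops"], audit["ratio"]))
```

prints

```
facility coverage: 0.236
suppressed view: non-zero fraction 0.308 — white at every facility pixel: True
GFLOPs baseline 5.82 vs dual-stem 1.71 (ratio 0.294)
```

i.e. ~24% of the pen is occluding infrastructure, the fused suppressed
view keeps only animals plus the white-equalized facility regions, and
replacing the baseline stem cuts the audit backbone's conv cost to under
a third.

The end-to-end comparison (train on the seen pen, evaluate on the unseen
one) is one call:

```python
rows = pp.run_experiment(pp.seen_config(), pp.unseen_config(),
                         variants=["baseline", "big_fig"], seeds=[0, 1, 2],
                         work_dir="scratch/exp")
```

Each row carries `ap50_seen`, `ap50_unseen`, `f1_unseen` per (variant,
seed); on the default conditions the full pipeline's median unseen AP50 is
roughly ten times the raw-frame baseline's (≈ 0.2 vs ≈ 0.02).

## Command line

```bash
pigpen synth --out data/seen --n 24 --env seen --seed 1
pigpen preprocess --background data/seen/background.png --depth data/seen/depth.png --out model/
pigpen big --input frame.png --background data/seen/background.png --out suppressed.png
pigpen fuse --input frame.png --model model/ --mode suppressed --fig --out-dir fused/
pigpen stem-describe
pigpen flops --config layers.yaml
pigpen train --data data/seen --variant big_fig --seed 0
pigpen experiment --variants baseline,big_fig --seeds 3 --work-dir scratch/exp --out results.csv
pigpen eval --pred preds.json --labels data/seen/labels --out report.yaml
```

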