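# skelfuse

Merging multiple inaccurate skeleton streams from a ring of RGB-D sensors
into one accurate, tracked skeleton.

A single depth sensor tracking a person suffers from self-occlusion: joints
hidden behind the body come back late, displaced, or mislabeled. Surrounding
the subject with several sensors fixes the coverage problem but creates a
fusion problem — per-sensor skeletons disagree, occasionally swap left/right
labels, and carry large occlusion outliers. `skelfuse` implements a complete
pipeline for this setting, aimed at motion-analysis and HRI researchers who
capture markerless skeletons with multi-sensor rigs:

- **Extrinsic calibration** — per-sensor rigid transforms `(R, T)` from
  sphere-centroid correspondence trajectories via the Kabsch/SVD
  least-squares fit (`R = V diag(1,1,det(VUᵀ)) Uᵀ`,
  `T = ĉ_M − R ĉ_p`), RANSAC known-radius sphere fitting for the
  centroids, and a four-marker plate defining the global frame.
- **Misorientation correction** — per mirrored pair, a confidence-weighted
  cross-sensor reference `P^Rr`; a sensor's pair is swapped when
  `‖P^Rr − P^Tr‖ > ‖P^Rr − P^Tl‖`.
- **DBSCAN merging** — joint candidates cluster with searching area ε
  (default 10 cm) and `N_c = 1`; the largest cluster wins and the merged
  joint is the centroid of its sensor candidates, with the reference and
  the previous merged position participating as auxiliary candidates only.
- **Kalman tracking** — per-joint constant-position filter
  (`A = H = I`, `Q = 0.01·I`, `R = 1.0·I`) smoothing residual tremble.
- **Synthetic benchmark** — a seeded six-gesture simulator (kinematic
  templates with exact bone-length constancy) plus an occlusion/outlier/
  swap/dropout corruption model, so the whole pipeline is testable without
  hardware.
- **Evaluation** — per-region (torso / upper limb / lower limb) AE, STD
  and RMSE in millimeters, with sweeps over pipeline variants (A1–A5),
  ε, and all same-size sensor subsets.

## Worked example

```python
import numpy as np
from skelfuse import FusionConfig, fuse_sequence, joint_errors
from skelfuse.simulator import default_benchmark

streams, truth = default_benchmark(seed=1, gesture="squat", n_frames=400)
merged = fuse_sequence(streams, FusionConfig(variant="A4", eps_mm=100.0))
print(joint_errors(merged, truth).region_summary.round(2).to_string(index=False))
```

```
    region  ae_mm  std_mm  rmse_mm    n
     torso   4.34    3.48     5.56 3200
upper_limb   4.44    6.41     7.80 1600
lower_limb   4.64    4.99     6.81 1600
       all   4.44    4.75     6.50 6400
```

Four simulated sensors watch a squatting subject; every joint is jittered
(σ = 5 mm), back-facing joints carry 300 mm occlusion outliers at rate
0.15, and 1% of joints drop out. After arrangement and DBSCAN merging the
fused skeleton sits ~4–5 mm from ground truth per region — the outliers,
which would shift a plain average by tens of millimeters (run
`variant="A1"` for comparison: ~25 mm), are rejected by the clustering.
The same comparison over sensor counts shows the error falling
monotonically as sensors are added (1 → 4 sensors: ~30 → ~4.5 mm), the
core claim of multi-sensor fusion.

The same stages are available from the shell:

```sh
skelfuse simulate --gesture squat --frames 400 --seed 1 --out-dir bench/
skelfuse fuse bench/stream_cam*.csv --variant A4 --eps 10cm --out merged.csv
skelfuse evaluate --merged merged.csv --truth bench/truth.csv --out report.csv
```

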