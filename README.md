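# spineret

Content-based retrieval of spine vertebra radiographs with anterior
osteophyte (AO) irregularity.

Anterior osteophytes — bony spurs on the anterior vertebral border —
are a common, frequently under-diagnosed finding on lateral spine
x-rays. A content-based image retrieval system lets a clinician query a
case archive with a vertebra image and get back previously diagnosed
cases of the same irregularity class, supporting visual comparison and
screening. `spineret` implements such a system end to end:

* **Shape modelling.** A vertebra boundary is represented either by the
  nine-anatomical-point scheme (9-APR: four body corners, lower/upper
  edge midpoints, an anterior midpoint, and two osteophyte marker
  points) or by a closed third-order B-spline through 27 points equally
  spaced along the 9-APR polygon (B-SR). Segmentation in a new image
  uses an active shape model: a PCA point-distribution model
  `x = x̄ + Φb`, |bᵢ| ≤ 3√λᵢ, coupled with per-landmark gray-profile
  models searched along the boundary normals ("whiskers").
* **Fracture characterization.** Region-based descriptors computed from
  the Euclidean distance transform (EDT) of the segmented body — Gabor
  wavelet bank responses (GW), six Haralick co-occurrence statistics
  (GLCM), 180 Radon projection averages of the watershed skeleton (RT),
  an 18-bin gradient orientation histogram (OH) — and contour-based
  descriptors: a global shape profile (GSP) and similarity-invariant
  Fourier descriptors of the central-distance and complex-coordinate
  shape signatures (FD-CD, FD-CC).
* **Classifier-gated retrieval.** A one-hidden-layer perceptron trained
  under stratified 5-fold cross validation (the "gating classifier")
  pre-classifies the query; candidates are then ranked by a weighted
  city-block distance `d(f_q, f_i) = Σ_k w_k |f_qk − f_ik|`,
  `w_k = 1/(σ_k + ε)`, either over the whole archive (standard
  architecture, SA) or only within the predicted class (gated
  architecture, PA). Quality is summarized by
  `Pr@M = 100 · N_R / M` for M ∈ {5, 10, 15, 20} and by the average
  group score `A_GS = mean(Pr@5, Pr@10, Pr@15, Pr@20)`.
* **Synthetic vertebrae.** A seeded generator renders labelled
  quadrilateral vertebral bodies with claw / traction / claw-traction
  osteophytes at three severity grades (cervical, 10 classes) or
  lower/upper/both anterior-corner osteophytes (lumbar, 4 classes) into
  noisy grayscale images, so the whole pipeline runs without clinical
  data.

## Worked example

Run the full experiment grid on a synthetic lumbar benchmark — 22
images per class, annotated landmarks as segmentation, orientation
histogram and central-distance Fourier descriptors as features:

```python
from spineret.workbench import ExperimentConfig, run_experiment

cfg = ExperimentConfig(region="lumbar", per_class=22,
                       algorithms=("OH", "FD-CD"),
                       segmentation="ground-truth", seed=7)
res = run_experiment(cfg)
print(res.table.to_string())
```

```
           SA_Pr@5  SA_Pr@10  SA_Pr@15  SA_Pr@20  SA_A_GS  PA_Pr@5  PA_Pr@10  PA_Pr@15  PA_Pr@20  PA_A_GS
algorithm
OH           67.05     55.11     47.27     42.10    52.88   100.00    100.00    100.00    100.00   100.00
FD-CD        65.45     62.84     57.58     51.88    59.44    95.68     95.34     95.45     95.45    95.48
Mean         66.25     58.98     52.42     46.99    56.16    97.84     97.67     97.72     97.72    97.74
```

Each row is one feature algorithm; every archived image served once as
a leave-one-out query. Under the standard architecture the OH features
place on average 42% same-class images among the top 20; gating the
archive by the cross-validated classifier (held-out AUC 0.98 for OH)
lifts every precision to 100% because only same-class candidates remain
rankable. The `Mean` row is the per-architecture average — the headline
comparison between the two architectures.

The same pipeline is scriptable from the shell:

```sh
spineret synth --region cervical --per-class 5 --seed 7 -o data/
spineret index --dataset data/ --algorithm GLCM -o archive/
spineret train --archive archive/ -o model.json
spineret evaluate --archive archive/ --architecture PA --model model.json
```

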