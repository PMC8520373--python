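# osemeat

Ordered-subset expectation-maximization (OSEM) reconstruction for
low-dose CT, coupled to the cardiac analyses that motivate it:
epicardial adipose tissue (EAT) volumetry by Hounsfield-unit
thresholding, Gensini coronary-severity scoring, and cohort-level
risk-factor statistics on synthetic patient data.

## The problem and the method

Low-dose CT trades radiation exposure for noise, so iterative
reconstruction replaces filtered backprojection.  The maximum-likelihood
EM algorithm (MLEM) iterates the multiplicative update

    g_j^(k+1) = g_j^(k) · ( Σ_i q_ij · y_i / ŷ_i ) / ( Σ_i q_ij ),
    ŷ = A g^(k),

where `y_i` is the measured projection on ray `i`, `q_ij` the
intersection length of ray `i` with pixel `j` (the system matrix `A`),
and the update monotonically increases the Poisson data likelihood.
MLEM uses every ray in every update and converges slowly.

OSEM partitions the view angles into `L` equal subsets `S_1 … S_L` and
applies the same update once per subset, so each full iteration refines
the image `L` times — an approximately `L`-fold speed-up.  Two rules
govern the partition here: each subset's angles are spread uniformly
over the angular range (a stride-`L` interleave, keeping subsets
balanced), and subsets are processed in a greedy farthest-first order
that maximizes the angular distance between consecutively processed
subsets, decorrelating successive updates.

Downstream, the package measures EAT volume on a CT volume as the voxel
volume of everything inside the fat window (−150 to −50 HU) between
anatomical slice bounds; scores coronary lesions with the Gensini
system (severity points 1/2/4/8/16/32 per stenosis bracket × segment
coefficient, left main = 5); and analyzes an EAT–coronary-disease
cohort with logistic regression, Spearman correlation, ROC/Youden
analysis and two-group tests.  Because no clinical data ship with the
package, a calibrated synthetic-cohort generator (control EAT
124.50 ± 26.72 mL, diseased 159.41 ± 38.51 mL, copula-linked Gensini
and vessel counts) stands in for the patients.

## Worked example

```python
from osemeat import (
    generate_shepp_logan, make_geometry, default_detector_count,
    build_system_matrix, forward_project,
    partition_subsets, osem_reconstruct, mlem_reconstruct, ReconConfig,
)

truth = generate_shepp_logan(256)
geom = make_geometry(1.0, 180.0, default_detector_count(256))  # 180 views
A = build_system_matrix(geom, truth)
y = forward_project(A, truth)

part = partition_subsets(180, 6, "optimized")        # 30 subsets of 6 views
osem = osem_reconstruct(y, A, part, ReconConfig(n_iterations=20), truth=truth)
mlem = mlem_reconstruct(y, A, ReconConfig(n_iterations=40), truth=truth)

print(f"OSEM after 1 iteration : {osem.error_history[0]:.4f}")
print(f"OSEM minimum (20 iters): {min(osem.error_history):.4f}")
print(f"MLEM after 26 iterations: {mlem.error_history[25]:.4f}")
```

Output:

```
OSEM after 1 iteration : 0.2045
OSEM minimum (20 iters): 0.0455
MLEM after 26 iterations: 0.2248
```

The error metric is the relative RMSE against the ground-truth phantom,
`‖g − g_true‖₂ / ‖g_true‖₂`.  One OSEM iteration with 30 subsets reaches
an error of 0.2045 that MLEM needs 26 full iterations to match (within
10%) — the subset-count-fold acceleration — and 20 OSEM iterations drive
the error down to 0.0455 on the noiseless 256×256 phantom.

The same pipeline is scriptable from the shell (`osemeat phantom`,
`osemeat project`, `osemeat reconstruct`, `osemeat eat`,
`osemeat gensini`, `osemeat cohort`, `osemeat stats`); every subcommand
is a thin wrapper over the functions above.

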