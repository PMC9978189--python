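# modnet

Module-structured functional brain network estimation and classification.

Functional brain networks (FBNs) estimated from resting-state fMRI ROI time
series are a standard substrate for computer-aided diagnosis of neurological
disorders such as mild cognitive impairment (MCI). The plain Pearson
correlation network is dense; ℓ1-sparsified and sparse+low-rank variants are
sparser but still give only an *approximate* modular structure. `modnet`
implements the **accurate-module** estimator (AM-PC): a sparse, nonnegative
network whose graph Laplacian rank is constrained so that the estimated
network has an **exact, pre-specified number of modules** (connected
components), together with the conventional baselines and the full
network-based classification protocol.

## The model

Let `X ∈ ℝ^{m×n}` be one scan's ROI signals, column-standardized so that
`A = XᵀX` is the sample Pearson correlation matrix. The accurate-module
estimator solves

```
min_{W ≥ 0}   ‖W − A‖²_F + λ Σ_ij W_ij     s.t.   rank(L_W) = n − k,
```

where `L_W` is the (normalized) graph Laplacian of `W` and `k` is the target
module count. Because the multiplicity of the zero eigenvalue of a Laplacian
equals the number of connected components, the rank constraint forces
exactly `k` modules. The constraint is relaxed through the Ky Fan theorem
(`Σ_{i≤k} σ_i(L_W) = min_{FᵀF=I} Tr(Fᵀ L_W F)`) into

```
min_{W ≥ 0, FᵀF = I}   ‖W − A‖²_F + α Tr(Fᵀ L_W F) + λ Σ_ij W_ij,
```

solved by alternating a spectral F-step (the `k` smallest-eigenvalue
eigenvectors of `L_W`) with a closed-form W-step
(`W_ij = max(0, a_ij − α f_ij/4 − λ/2)` where `f_ij = ‖f_i − f_j‖²`), while
α is doubled whenever the Laplacian has fewer than `k` zero eigenvalues and
halved whenever it has more.

Also included: the Pearson network (`pc`), its nonnegative variant (`pc+`),
ℓ1-regularized estimation `min ‖X − XW‖²_F + λ‖W‖₁` (`sparse-pc`, `+`),
sparse+trace-norm estimation (`m-pc`, `+`), upper-triangle feature
extraction, two-sample t-test feature selection at a fixed p threshold,
linear SVM (C = 1) classification under repeated 5-fold **subject-level**
nested cross-validation, and a synthetic modular-cohort generator with
exact ground truth.

## Worked example

```bash
cat > spec.yaml <<'EOF'
n_rois: 30
k_true: 5
n_subjects_per_class: [10, 12]
scans_per_subject: 2
n_discriminative_edges: 6
EOF
modnet simulate --spec spec.yaml --out cohort --seed 1
modnet estimate --method am-pc --k 5 --lam 0.0625 \
    --input cohort/NC001_s1.tsv --output net.tsv
modnet classify --manifest cohort/manifest.csv --method am-pc --k 5 \
    --grid "2^-6..2^-3" --folds 5 --repeats 5 --seed 0 --report report.json
```

prints

```
44 scans, 22 subjects
wrote net.tsv
ACC: 1.0000 ± 0.0000
SEN: 1.0000 ± 0.0000
SPE: 1.0000 ± 0.0000
AUC: 1.0000 ± 0.0000
```

`net.tsv.json` (the sidecar of the estimated network) records
`k_observed: 5, converged: true, alpha_final: 12.8, n_iterations: 10` —
the solver reached a network with exactly the 5 requested modules. The
classification metrics are mean ± sd over 5 repeats of 5-fold subject-level
CV; on this high-signal synthetic cohort (6 within-module connections
weakened by 0.3 in the patient class) the two classes are perfectly
separable, so all four metrics are 1. With permuted labels the same
pipeline drops to chance accuracy (see the acceptance script below).

The same operations are available as a library:

```python
from modnet import ModularCohortSpec, generate_scan, ampc_estimate, AmpcConfig
import numpy as np

ts, truth = generate_scan(ModularCohortSpec(seed=1), 0, np.random.default_rng(1))
res = ampc_estimate(ts, AmpcConfig(k=8, lam=2**-4))
res.k_observed      # 8 — exactly the requested module count
```

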