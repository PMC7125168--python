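# connectoml

A machine-learning discovery framework for classifying clinical groups from
MEG functional connectomes — built for studies of the kind that compare
PTSD patients with trauma-exposed controls using resting-state neural
synchrony, and for anyone who wants a leakage-disciplined, fully seeded
reference implementation of that workflow on their own edge-feature data.

## The problem and the method

Each participant contributes, per frequency band (Theta 4–7, Alpha 8–14,
Beta 15–30, low gamma 30–80, high gamma 80–150 Hz), a functional connectome:
the weighted phase lag index (wPLI)

    wPLI = | Σ_k Im S_xy,k | / Σ_k |Im S_xy,k|

between every pair of the 90 AAL atlas regions — 4005 edges with values in
[0, 1], insensitive to zero-lag (volume-conduction) coupling. The package
takes these subjects × edges matrices with binary labels through:

1. per-edge Welch t-tests with significance on the raw p at α = 0.01;
2. unsupervised structure checks (two-way Ward clustering, PCA) at the
   all-edges / significant-edges / selected-edges stages;
3. a stratified 80/20 participant split, then **CV-SVM-rRF-FS**: recursive
   random-forest feature elimination (drop the worst 20% per round, keep
   the minimal-OOB-error set) nested inside each of 10 stratified CV folds,
   with a consensus edge list from the edges selected in ≥ 5 of 10 folds;
4. a final RBF-SVM on the consensus edges with internal 10-fold CV accuracy,
   a B = 99 label-permutation test (add-one p, floor exactly 0.01), and
   external ROC/AUC (Mann–Whitney, ties ½) on the held-out 20%;
5. two-component PLS-DA with VIP scores (threshold 0.8) as an
   SVM-independent verification of the selected edges.

Because studies of this kind rarely deposit raw patient data, the package
ships a first-class synthetic-data module that emulates the design
(23 + 21 subjects, 4005 edges, five bands, a few dozen planted
discriminative edges of mixed direction) at two levels: direct edge weights
with exact effect-size control, and coupled oscillatory time series reduced
through the package's own wPLI estimator. Ground truth is available to
tests, never to the pipeline.

## Worked example

```bash
$ echo '{"n_regions": 30}' > spec.json
$ connectoml simulate --seed 11 --n-planted 12 --effect-size 1.5 \
      --spec spec.json --out sim
wrote 5 band tables to sim
$ connectoml run --input sim/edges_Alpha.csv --seed 11 --out run/Alpha
band=Alpha consensus_edges=7 cv=1.000±0.000 perm_p=0.01 auc=1.000
$ connectoml report --runs run
 band  n_consensus_edges  cv_mean  cv_sd  n_support_vectors  svm_C  svm_gamma  permutation_p  auc  plsda_cv_accuracy  no_signal
Alpha                  7      1.0    0.0                 19    1.0        0.1           0.01  1.0              0.975      False
```

Reading the numbers: of the 12 edges planted at effect size d = 1.5 (among
435), the fold-consensus kept a minimal signature of 7; the final SVM
separates the training subjects perfectly in internal 10-fold CV
(1.000 ± 0.000), beats all 99 label permutations (p = 0.01, the add-one
floor), and classifies the held-out subjects perfectly (external AUC 1.0);
the independent PLS-DA classifier agrees (CV accuracy 0.975). Every stage
output (univariate table, consensus edge list as region pairs, ROC points,
VIP scores, PCA scores, checksummed manifest) is written under `run/Alpha/`.

The same objects are available as a library:

```python
from connectoml import study_spec, generate_edge_dataset, run_band

spec = study_spec(seed=11, n_planted=40, effect_size=1.2)   # 23+21, 4005 edges
ds = generate_edge_dataset(spec, "Alpha")
report = run_band(ds, seed=11)
report.model.cv_mean, report.permutation.p_value, report.evaluation.auc
```

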