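# sparsecmtf

Sparse coupled matrix–tensor factorization for longitudinal clinical
cohorts, with built-in permutation and split-half validation.

## The problem

Prospective cohorts of newly diagnosed type 1 diabetes patients collect
three very different kinds of data on the same children: repeated
paraclinical biomarkers (stimulated C-peptide, HbA1c, autoantibody
titers, incretins, …) at fixed visits after diagnosis; baseline
characteristics at onset (age, symptom duration, ketoacidosis, HLA-DQB1
risk group, …); and genotypes of diabetes-associated SNPs. Analysing
each variable separately multiplies tests and misses the point — the
scientific questions are about *patterns*: which trajectory of
biomarkers travels together, and which onset characteristics and
genetic backgrounds travel with it.

`sparsecmtf` answers this with a multi-block latent factor model. The
biomarker data form a three-way tensor (subjects × biomarkers × visit
months) that is factorized in CP/PARAFAC form jointly with the baseline
and genotype matrices, all three blocks sharing the subject-score
matrix *A*:

```
X ≈ Σ_r a_r ∘ b_r ∘ c_r        Y ≈ A Dᵀ        Z ≈ A Eᵀ
```

Fitting minimizes a block-weighted, observed-entry least-squares loss
with an L1 penalty on the variable modes, so small loadings are set to
exactly zero and each component reads as a short list of biomarkers,
baseline variables and SNPs with signed weights, plus a time profile.
Because the latent components concentrate the evidence, the approach
controls the multiplicity problem by dimension reduction rather than by
per-variable correction.

The package provides:

* `synthetic` — a coupled-cohort generator with known ground truth
  (129 × 20 × 4 tensor, 10 baseline variables, 51 SNPs by default,
  missing entries, tertile-discretized genotypes);
* `clinical` — the deterministic clinical codings (IDAA1c and partial
  remission, DKA from bicarbonate, HLA-DQB1 risk groups, autoantibody
  cutoffs, additive SNP coding);
* `preprocess` — long-table → tensor assembly, log transforms,
  column standardization, equal-contribution block weighting;
* `cmtf` — masked CP-ALS, the sparse coupled fit, component alignment,
  explained variation, stability-based penalty selection;
* `validation` — pattern-to-pattern permutation tests (calibrated by a
  leave-the-tested-block-out anchor), split-half consistency with
  matched-component congruence, gene-selection homogeneity;
* `pipeline` / a `sparsecmtf` CLI — end-to-end runs producing tidy CSV
  reports.

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

```python
from sparsecmtf import (generate_cohort, prepare, cmtf_fit,
                        align_components, explained_variation)
from sparsecmtf.validation import permutation_association_test

ds, truth = generate_cohort(seed=42)          # synthetic 129-subject cohort
dsp = prepare(ds)                              # standardize + weight blocks
model = align_components(cmtf_fit(dsp, rank=2, lam=0.01,
                                  n_starts=8, seed=0), dsp)

print(f"tensor explained variation: "
      f"{explained_variation(model, dsp, 'tensor'):.1f}%")
for r in range(2):
    for pair in (("tensor", "baseline"), ("tensor", "gene")):
        res = permutation_association_test(dsp, model, pair,
                                           component=r, n_perm=999, seed=1)
        print(f"component {r+1} {pair[0]}-{pair[1]}: "
              f"|r| = {res.statistic:.3f}, p = {res.p_value:.3f}")
```

prints

```
tensor explained variation: 12.7%
component 1 tensor-baseline: |r| = 0.887, p = 0.001
component 1 tensor-gene: |r| = 0.868, p = 0.001
component 2 tensor-baseline: |r| = 0.870, p = 0.001
component 2 tensor-gene: |r| = 0.887, p = 0.001
```

The two-component model captures ~13% of the biomarker-tensor variation
(the generator's default noise level makes the tensor ≈ 78% noise per
entry, so this is the expected order), and each component's biomarker
pattern is significantly associated with both the baseline and the
genotype block — p = 0.001 is the smallest value attainable with 999
permutations. With `lam=0.01` the top component's gene loading vector
keeps 15 of 51 SNPs; the rest are exactly zero.

From the shell, the same analysis end to end:

```bash
sparsecmtf simulate --seed 42 --out cohort/
sparsecmtf run-all --data cohort/ --out run/ --lam 0.01 \
    --nperm 999 --nsplits 10 --seed 0
```

which writes `loadings.csv`, per-component pattern tables (zero
loadings omitted), `explained_variation.csv`, `permutation_tests.csv`,
`split_half.csv` and `model.json` into `run/`.

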