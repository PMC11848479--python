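# grnkit

Inference toolkit for small gene regulatory networks from single-cell
transcript-count data, built around a three-gene case study (`elt-1`,
`egl-18`, `ceh-16` across wild-type and mutant genotypes):

* **data_core** — validated long-format count tables
  (`gene,genotype,timepoint,animal_id,cell_id,count`), bootstrap summary
  statistics (mean, SE of the mean, Fano factor, CV, paired-cell
  correlation), and genotype→protein-activity resolution for hypomorphic
  and null alleles.
* **synthetic_data** — mixed-Poisson generators (shared per-animal
  log-normal extrinsic factor × Poisson) with known ground-truth networks;
  shipped presets `final-L1`, `literature`, `basal-only`.
* **mra** — hypomorph-adapted Modular Response Analysis: central fractional
  differences, local response coefficients
  `r = -(diag(diag(Rp^-1)))^-1 · Rp^-1` (diagonal normalized to −1), cell
  bootstrap with percentile confidence intervals and weak-link flags.
* **grn_ode** — Hill-function ODE family over a signed topology with
  AND/OR co-regulation logic; enumeration of all logic variants (20 for the
  late-L1 topology), genotype activity fractions inside every Hill term,
  steady states by forward integration (numba-accelerated when available).
* **sparse_abc** — likelihood-free fitting with sparsity-inducing
  spike-and-slab priors: pseudo-likelihood `exp(-d/delta_abc)` on the
  normalized Euclidean distance, per-parameter slab scales with collapsed
  (marginalized) removal/reinstatement proposals, delta readjustment by the
  burn-in threshold rule, sign-relaxed (a/r) mode, and a no-sparsity naive
  literature-model baseline.
* **network_analysis** — presence percentages per parameter and per link
  (with AND/OR logic context), double-mutant prediction and the `d ≤ 2.5`
  validation filter, final-network assembly by the ≥90 % deletion rule,
  cross-timepoint z-score checks, and CSV/JSON report bundles.

## CLI

```sh
# simulate a synthetic dataset with archived ground truth
grnkit simulate --preset final-L1 --n-animals 200 --seed 1 --out data.csv

# bootstrap MRA (10000 iterations by default)
grnkit mra --data data.csv --timepoint late-L1 --n-iter 10000 --seed 1 \
    --gamma egl-18=0.01 --out results/mra

# fit AND/OR logic variants with the sparse sampler
grnkit fit --data data.csv --variants 1,20 --delta 0.0125 --chains 3 \
    --sweeps 2000 --seed 1 --out results/fits

# double-mutant summary for validation, and report bundling
grnkit predict-double --data data.csv --out results/dm.csv
grnkit report --mra-edges results/mra_edges.csv --out results/report
```

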