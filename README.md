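# ffproteo

Statistical pipeline for two-group follicular-fluid proteome cohorts with a
nested repeated-measures design (patient → fluid → technical repeat):

- **`ffproteo.cohort`** — synthetic cohort simulator: three-level lognormal
  intensity model, injected log2 fold-change effects, an optional positively
  correlated protein block with one anti-correlated protein, and per-protein
  technical noise. Includes a default 20-protein effect table (one
  down-regulated, nineteen up-regulated, magnitudes 0.07–0.61).
- **`ffproteo.forest`** — class-weighted, capacity-limited random forests
  (50 trees, depth ≤ 3, ≥ 30 samples per leaf, weights inversely proportional
  to class size), patient-grouped k-fold cross-validation, recursive feature
  elimination with per-cycle **persistence scores** (elimination rounds
  survived, averaged over the per-fold elimination paths), accumulation over
  many cycles, outlier-based protein selection (score > median + 1.5·IQR)
  and balanced-accuracy evaluation. The elimination step is configurable:
  an absolute count, a fraction per round, or `"auto"` (drop all
  zero-importance features); `fine_from` switches to one-per-round
  elimination once the candidate set is small.
- **`ffproteo.effects`** — pseudoreplication-safe effect estimation: repeats
  are collapsed to fluid-level medians of log2 intensities, then percentile
  bootstrap CIs (default 10,000 resamples) for the difference of group
  medians.
- **`ffproteo.correlation`** — winsorisation-based robust correlation
  matrices (default γ = 0.2).
- **`ffproteo.pipeline` / `ffproteo.cli`** — end-to-end orchestration with a
  JSON run manifest (seeds, versions, artifact checksums) for byte-identical
  reruns.

## CLI

```bash
# synthetic cohort (study-like defaults: 34+40 patients, 484 proteins)
ffproteo simulate --seed 1 --out-dir run/

# persistence scores over grouped RFECV cycles
ffproteo score --matrix run/matrix.tsv --metadata run/metadata.tsv \
    --folds 20 --cycles 30 --step 0.25 --seed 1 --out run/scores.tsv

# bootstrap log2 fold changes
ffproteo effects --matrix run/matrix.tsv --metadata run/metadata.tsv \
    --boot 10000 --seed 1 --out run/effects.tsv

# winsorised correlation
ffproteo correlate --matrix run/matrix.tsv --metadata run/metadata.tsv \
    --proteins PROT0011,PROT0035 --gamma 0.2 --out run/corr.tsv

# full pipeline from a YAML config (see below)
ffproteo all --config config.yaml --seed 1 --out-dir run/
```

Example `config.yaml`:

```yaml
simulate:
  n_pcos_patients: 34
  n_control_patients: 40
  n_proteins: 484
  seed: 1
forest:
  n_trees: 50
  max_depth: 3
  min_samples_leaf: 30
n_folds: 20
n_cycles: 30
step: 0.25        # fraction of features eliminated per round
n_boot: 10000
gamma: 0.2
seed: 1
out_dir: run
```

Instead of a `simulate` section you may point `matrix` / `metadata` at TSV
files: the matrix has a `row_id` column followed by one column per protein
(strictly positive intensities); the metadata has
`row_id, patient_id, group, fluid_id, repeat_index` with `group` in
`{pcos, control}`.

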