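# scpquant

Quantification pipeline for single-cell TMT (isobaric-label) proteomics:
from search-engine PSM tables to differentially expressed proteins.

The pipeline addresses the two problems that dominate single-cell proteomics
quantification — batch effects across multiplexed sets and pervasive
left-censored missing values — with five stages:

1. **Identification cleanup** (`scpquant.io_tables`) — drop reverse /
   contaminant / site-only protein groups and their PSMs. Reporter
   intensities of 0 are treated as *missing* (non-detection), never as true
   zeros.
2. **PSM-level weighted-ratio normalization** (`scpquant.normalization`) —
   per protein and channel, PSM reporter intensities are divided by the
   batch's reference-channel intensity (or a channel/PSM sum when no
   reference exists), weighted by
   `(precursor_intensity × fill_time) ** 0.75` (normalized to sum to 1), and
   collapsed to one protein value by the **weighted median** (lower median
   on ties). Values are then log2-transformed.
3. **Quantification QC** (`scpquant.qc`) — valid-value filtering within each
   cell (default ≥ 70%) and then across samples per protein (default ≥ 50%),
   a full threshold grid with per-cell-type median protein variances, a
   per-sample missingness profile, and exclusion of proteins with fewer than
   2 PSMs before differential expression.
4. **Down-shift imputation** (`scpquant.imputation`) — missing entries drawn
   from `Normal(μ − d·σ, (w·σ)²)` per column (defaults d = 1.0, w = 0.3);
   a distribution report flags when large down-shifts plant a separate
   imputed mode into the value distribution.
5. **Moderated-t differential expression** (`scpquant.de_stats`) —
   empirical-Bayes variance shrinkage (moment-matched inverse-chi-square
   prior), two-sided p-values, Benjamini–Hochberg q-values, volcano table.

`scpquant.evaluation` provides PCA embeddings and k-means grouping accuracy
for judging pipeline settings, and `scpquant.synthetic` generates complete
synthetic experiments (carrier/reference/control channels, MNAR
missingness, planted fold-changes, low-quality cells) so every stage is
testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: weighted-median
oracle equivalence, weight-formula exactness, QC-grid reconciliation,
imputation distribution and bimodality-flag behavior, DE calibration /
FDR control, and end-to-end planted-effect recovery.

## CLI

```bash
# generate a synthetic experiment
scpquant synth --n-batches 8 --n-proteins 1000 --seed 7 --out data/

# run everything (stage outputs + summary in run/)
scpquant run-all --psm data/batch01.evidence.tsv ... \
    --annotation data/annotation.tsv --protein-groups data/proteinGroups.tsv \
    --out run/ --seed 1

# or stage by stage
scpquant normalize --psm data/batch01.evidence.tsv --annotation data/annotation.tsv \
    --protein-groups data/proteinGroups.tsv --out matrix.tsv
scpquant qc-grid --matrix matrix.tsv --annotation data/annotation.tsv \
    --cell-thresholds 0,10,30,50,70,90 --protein-thresholds 0,10,30,50,70,90 --out grid.tsv
scpquant impute --matrix filtered.tsv --down-shift 1.0 --width 0.3 --seed 1 --out imputed.tsv
scpquant de --matrix imputed.tsv --annotation data/annotation.tsv --out de.tsv
scpquant evaluate --matrix imputed.tsv --annotation data/annotation.tsv --out pca.tsv
```

`run-all` also accepts a YAML config (`--config pipeline.yaml`) with keys
`psm_paths`, `annotation_path`, `protein_groups_path`, `out_dir`,
`ratio_mode`, `thresholds: {min_valid_within_cell, min_valid_across_samples,
min_psm_count}`, `imputation: {down_shift, width, scope}`, `q_cutoff`,
`seed`.

## Input formats

- **PSM tables**: tab-delimited, one row per PSM. The default column
  dialect matches MaxQuant `evidence.txt` (`Reporter intensity corrected N`,
  `Intensity`, `Ion injection time`, `Leading razor protein`, `Raw file`,
  `Reverse`, `Potential contaminant`); other engines can be mapped with a
  custom `Dialect`.
- **Protein groups**: `proteinGroups.txt` dialect (`Protein IDs`, flag
  columns, `MS/MS count`).
- **Channel annotation**: TSV/CSV with `batch`, `channel`, `role`
  (carrier / reference / control / unused / empty / single_cell) and
  `cell_type` columns.
- **Matrices**: TSV, proteins × samples, `NA` for missing, scale recorded
  in a `# scale=` header comment.

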