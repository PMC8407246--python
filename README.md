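# pulsedyn

Pulse-SILAC proteome-dynamics analysis: from protein-groups quantification
tables (MaxQuant `proteinGroups.txt` dialect) to label-incorporation
kinetics, protein turnover rates and half-lives, temporal binning and
within-bin ranking, incorporation-profile clustering with
time-to-50%-labeling, heavy-channel iBAQ absolute quantification, and
Fisher-exact functional enrichment. A ground-truth simulator emulating slow
(persistence-like) and fast, saturating (resuscitation-like) labeling
regimes makes every stage testable offline.

## What it computes

* **Quality filtering** — removes contaminant / reverse / only-by-site rows;
  masks ratio cells with fewer than 2 peptide ratio counts (cell-level, the
  row survives if any cell does). Zero intensities are treated as missing.
* **Replicate union** — per protein and time point, values measured in 1, 2
  or 3 replicates are kept / averaged and tagged confidence class I / II /
  III; time points are pooled into configurable bins by the median and
  proteins ranked into quartile categories within each bin.
* **Turnover kinetics** — incorporation fraction `r/(1+r)`; closed-form
  through-origin rate `k = Σ ln(r_i+1)·t_i / Σ t_i²`; half-life
  `T1/2 = ln2/k`; uncentered `R²`; reliability filter (≥ 5 time points,
  `R² > 0.70`). Optional labeled-pool-purity estimator from two-lysine
  missed-cleavage peptide label states (`p̂ = 2HH/(2HH+HL)`, corrected rate
  `k/p̂`).
* **Profile clustering** — complete-case incorporation matrix, Ward
  hierarchical clustering on Euclidean distances cut at K (default 8)
  groups; per-cluster loess-smoothed conditional mean (tricube weights,
  nearest-neighbor span, default degree 2) and the earliest 50% crossing.
* **Enrichment** — two-sided Fisher exact test per category with
  Benjamini–Hochberg FDR within each annotation source.
* **iBAQ (heavy channel)** — in-silico Lys-C digest (cleaves after K,
  including K-P; ≤ 2 missed cleavages; observable window 7–30 aa) and
  heavy intensity divided by the observable peptide count, median over
  replicates.
* **Simulation** — per-protein trajectories
  `I(t) = plateau · pool_purity · (1 − e^{−kt})` with lognormal channel
  noise, logistic intensity-dependent dropout and low-ratio-count cells,
  serialized in the same dialect the reader consumes, with ground truth.

## CLI

```bash
# simulate a persistence-like experiment (500 proteins, 3 replicates)
pulsedyn --seed 1 --out-dir work simulate --n-proteins 500

# run the full pipeline from a YAML config
cat > config.yaml <<EOF
input_table: work/simulated_protein_groups.tsv
out_dir: work
condition: persistence
seed: 1
EOF
pulsedyn --config config.yaml run-all
```

Subcommands: `simulate`, `filter`, `merge`, `bin`, `turnover`, `cluster`,
`enrich`, `ibaq`, `run-all`; global flags `--config`, `--seed`, `--out-dir`,
`--log-level`. Stages read their upstream artifacts from the output
directory, so they can be run one at a time. Every artifact is a TSV with a
JSON provenance sidecar (config hash, seed, version); `manifest.json`
summarizes each run. The `enrich` and `ibaq` stages need `annotations`
(GMT-like TSV) and `fasta` paths in the config and are skipped by `run-all`
when unset.

Config keys and defaults: `min_ratio_count: 2`, `min_points: 5`,
`min_r2: 0.70`, `k_clusters: 8`, `span: 0.5`, `fdr: 0.1`,
`min_category_size: 3`, `min_pep_len: 7`, `max_pep_len: 30`,
`max_missed: 2`, plus the experiment design (`condition`, `replicates`,
`time_points_h`, optional `bin_scheme`).

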