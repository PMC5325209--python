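# silacswap

Design-aware analysis of triplex-SILAC experiments with a double label
swap. In this design each protein carries six oriented log2 ratios: four
"treated" ratios (exposed vs sham, two per reciprocal labeling
experiment over the H–L and H–M channel pairs) and two "control" ratios
(same-state channel pairs that measure technical variation only). The
package exploits that structure end to end:

- **Ingest & QC** (`silacswap.io`): MaxQuant-style `proteinGroups`
  tables with configurable column maps, reciprocal reorientation of
  replicate-2 ratios, decoy/contaminant/peptide-count filtering,
  median-centering normalization, quantitation summaries.
- **Synthetic data** (`silacswap.simulate`): a generator with known
  ground truth — per-protein label bias (stronger for H–L than H–M),
  intensity-dependent noise, a small regulated fraction, missingness,
  decoys — plus a term-annotation generator for the set-analysis stage.
- **Swap diagnostics** (`silacswap.swap`): reciprocal-ratio Pearson
  correlations with Fisher-z CIs (negative when label bias dominates
  treatment), quadrant classification, and a paired t-test comparing the
  two swap types.
- **Design filters** (`silacswap.filters`): sign-consistency and
  composite (treated-dominates-control) Boolean filters with MAD-based
  signal-to-noise reporting.
- **Detector ensemble** (`silacswap.detect`): fold change, Z-score,
  robust M-score, intensity-binned significance-B, rank product with a
  permutation/exact null, an FCROS-style rank statistic, and an
  empirical-Bayes moderated fold-change-threshold test; BH adjustment
  and a union ensemble with per-method provenance and stringency tiers.
- **Set comparison** (`silacswap.sets`): Jaccard/overlap scores and
  proteome coverage summaries.
- **Protein-set analysis** (`silacswap.gsa`): Bayesian on/off term
  activation model (false-positive rate α, false-negative rate β, prior
  p on discrete grids) with exact enumeration for small models and a
  Metropolis sampler with multi-run SDs; network export (TSV/GraphML).
- **Pipeline & CLI** (`silacswap.pipeline`, `silacswap.cli`): a
  config-driven end-to-end driver emitting table-shaped TSV reports and
  a deterministic metrics JSON.

`silacswap.studydata` packages the published study's printed summary
tables (identification counts, set comparisons, quantitation counts and
regulated-protein calls) used by report rendering and the acceptance
checks.

## CLI

```sh
silacswap simulate --seed 17 --out sim/            # synthetic dataset + truth
silacswap ingest sim/proteinGroups.tsv --out canonical.tsv
silacswap swap-diagnostics sim/proteinGroups.tsv --out swap.tsv
silacswap filter sim/proteinGroups.tsv --out-prefix filt
silacswap detect sim/proteinGroups.tsv --out-prefix det --seed 1
silacswap compare-sets a.txt b.txt
silacswap gsa --annotations anno.tsv --universe ids.txt --study hits.txt \
    --runs 20 --steps 1e6 --seed 1 --out-prefix gsa
silacswap run --config pipeline.yaml --seed 1 --out out/   # full pipeline
```

A pipeline config is a single YAML file; any section may be omitted:

```yaml
seed: 1
simulation: {n_proteins: 3000, frac_regulated: 0.01}
detection: {methods: [fc, z, m, sigb, rankprod, fcros, treat],
            fc_tier: 1.2, p_tier: 0.05, mode: filter_first}
gsa: {n_terms: 8, n_runs: 4, n_steps: 20000}
```

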