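# persevo

Simulation and analysis toolkit for the evolution of antibiotic persistence
under serial-transfer population bottlenecks.

A *persister* is a phenotypically tolerant cell that survives a bactericidal
treatment without a resistance mutation. Under a daily cycle of high-dose
treatment, dilution into fresh medium (the bottleneck, ratio `D`), and
regrowth to stationary phase, mutations that raise the persister fraction are
strongly selected. This package provides:

- **`sim_core`** — a stochastic serial-transfer simulator: per-genotype
  binomial survival of treatment (endpoint or biphasic kill), binomial
  dilution bottlenecks, multinomial regrowth with fitness-weighted odds,
  Poisson mutation with a configurable persistence/growth-trade-off DFE, and
  a barcoded knockout-library selection mode emitting read-count tables
  (partial edit fractions, inert control designs, replicate populations,
  growth-only control arm).
- **`trajectories`** — persister-fraction estimation from CFU counts and
  sigmoidal adaptation-trajectory fits
  `p(t) = L + (U−L)/(1 + e^(−S(t−λ)))` (free asymptotes, or the strict
  normalized two-parameter form via `fix_asymptotes=(0, 1)`), with grid-seeded
  least squares, bootstrap CIs, and per-bottleneck summaries.
- **`competition`** — growth-curve AUC, the competition coefficient solving
  `AUC_mixed = c·AUC_mono + (1−c)·AUC_anc`, odds-ratio relative fitness from
  head-to-head frequencies, and the deterministic mutant-spread recurrence
  with the serial-dilution correction factor `D(lnD)²` applied to the
  selection coefficient.
- **`barcode_analysis`** — control-design median-of-ratios normalization,
  per-design enrichment/depletion calls (one-sample t on replicate log2
  fold-changes, BH-adjusted) with growth-confound filtering, retained-design
  fractions (lost-mutant threshold: < 3 raw reads), frequency distributions,
  pairwise Pearson replicate correlations, and top-hit tallies.
- **`smallstats`** — Spearman rank correlation with *exact* permutation
  p-values for n ≤ 8 (full n! enumeration), Welch t-tests, a variance F-test,
  and Benjamini–Hochberg adjustment.
- **`io_cli`** — validated TSV schemas (cfu, od, frequency, counts, variants,
  cycles), deterministic fixture generation, run manifests, and the CLI.

## CLI

All subcommands share `--seed`, `--config` (flat key/value YAML),
`--out-dir`, and `--log-level`; every run writes a `manifest.json` with the
config snapshot, seed, version, and SHA-256 digests of inputs/outputs.

```sh
persevo --seed 1 --out-dir run simulate-evolution --d-values 0.002,0.01,0.1 --replicates 10
persevo --out-dir run fit-trajectory run/cfu.tsv --per-population
persevo --seed 1 --out-dir lib simulate-library --d 0.1 --random-effects 0.05
persevo --out-dir lib library-analyze lib/counts.tsv --alpha 0.05
persevo --out-dir lib diversity lib/counts.tsv
persevo --out-dir lib heterogeneity lib/counts.tsv
persevo --out-dir out mutant-spread --w 1.5 --d 0.01 --p0 1e-8 --rounds 100
persevo --out-dir out competition-coef od.tsv
persevo --out-dir out relative-fitness frequency.tsv
persevo correlate table.tsv --x-col bottleneck --y-col S
persevo --seed 7 --out-dir fixtures make-fixtures --kind od
```

All tables are plain TSV with a header row; cycle and timepoint indices are
0-based.

## Notes

- Randomness flows through `numpy.random.Generator`; one top-level seed is
  expanded into per-population child streams, so identical (config, seed)
  pairs give bit-identical outputs.
- The simulator realizes regrowth as a single fitness-weighted multinomial
  redraw at stationary size (correct expectations, desk-scale speed) and uses
  `N_stat − N_seed` as the division count for the mutation supply.
- Monte-Carlo test suites run at a scaled stationary size of 10⁶ cells.
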