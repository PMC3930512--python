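# hybridqtl

Expression-QTL mapping and epistatic-network analysis for F2 intercrosses
between diverged inbred lines — the study design used to dissect hybrid
male sterility in house-mouse subspecies crosses, where disrupted testis
gene expression, *trans*-eQTL hotspots, and Dobzhansky–Muller
incompatibilities are the objects of interest.

## Who this is for

Quantitative geneticists analysing an F2 cross (hundreds of genotyped
males, a sparse SNP map of 19 autosomes + X, a genome-wide expression
matrix with parental and reciprocal-F1 controls, and sterility
phenotypes), and anyone who wants a fully simulated test bed with known
architecture for such an analysis.

## What it computes

- **Genotype probabilities.** A hidden Markov model over true genotypes
  on a marker + pseudomarker grid (default 2 cM). The F2 autosome chain
  is the tensor product of two gamete chains over {AA, AB, BB}; the
  hemizygous male X has two states. Haldane, Kosambi and
  Carter–Falconer map functions; symmetric genotyping-error emissions
  (default 0.001).
- **Single-QTL genome scans.** Haley–Knott regression on expected class
  probabilities and EM interval mapping (normal mixture, common SD), with
  `LOD = (n/2)·log10(RSS₀/RSS₁)`. Expression traits are normal-quantile
  transformed, `x ↦ Φ⁻¹((rank−½)/n)`, so one permutation null serves all
  transcripts.
- **Permutation significance.** Single-transcript and dataset-wide
  (column-permutation) thresholds, with the X as its own stratum: the
  genome-wide α is split by map length and the X permutation count is
  scaled up by the autosome/X length ratio. Permutation P values and
  Storey q-values (smoother π₀).
- **Misexpression.** A transcript is misexpressed when it falls outside
  both parental means by more than 0.5 (log2) *and* the relevant
  significance guard (Welch t + q ≤ 0.05 for F1 groups; 2 parental SEs
  for single F2s). Per-individual counts (over/under × autosome/X) become
  √-transformed phenotypes and are QTL-mapped.
- **eQTL catalog.** Per-trait, per-chromosome peaks above threshold;
  *cis* (< 5 cM from the probe), *trans* (different chromosome), or
  excluded; dominance classes (additive / dominant / over- /
  underdominant) from genotype-class means in 2-SE units; effect size =
  difference between extreme class means; hypergeometric enrichment with
  Bonferroni correction; sterile-allele inference from concordance with
  the sterile-F1 misexpression pattern.
- ***Trans* hotspots.** 4 cM sliding windows on the grid; a permutation
  null that reassigns each trans eQTL to a random grid position on
  another chromosome; size-stratified 95th-percentile count thresholds;
  merging of adjacent significant windows; a permutation co-localization
  test against sterility-QTL support intervals (hotspot positions
  re-drawn, sterility intervals fixed).
- **Conditional (epistasis) mapping.** For a genotype covariate, additive
  and full (covariate × QTL) models scanned with the *same* permutation
  shuffles, giving paired LOD_f / LOD_a / LOD_i nulls; interaction eQTL
  require both LOD_f and LOD_i above threshold; interaction hotspots and
  a covariate → peak network whose nodes merge regions closer than
  12.8 Mb, with reciprocal-edge flags and per-covariate summaries.
- **Simulator.** F2 crosses from a no-interference crossover process,
  expression with cis effects, trans master regulators of configurable
  dominance, purely epistatic pairs with exactly zero marginal effects,
  parental/F1 groups, and Gaussian sterility phenotypes (including
  two-locus incompatibility effects) — all pure functions of a seed.

## Worked example

```bash
hybridqtl simulate --seed 3 --out study/
hybridqtl analyze study/ --seed 3
```

The first command writes `cross.csv`, `expression.tsv`, `probes.tsv`,
`phenotypes.csv`, `map.tsv`, and `ground_truth.json` for the default
study: 300 F2 males, a ~200-marker map, 40 cis-regulated, 60
master-regulated, 20 epistatic and 60 null probes. The second runs every
stage and prints

```
111 eQTL, 1 hotspots; outputs: scan_peaks.tsv, thresholds.tsv, ...
```

meaning 111 per-chromosome eQTL records cleared the single-transcript
permutation thresholds (3.39 autosomal, 2.85 X LOD for this seed, from
200 and 4,275 permutations) and one trans-eQTL hotspot was called:
chromosome 1 at 46–52 cM with 57 member eQTL — the simulated
underdominant master regulator sits at 48 cM — and inferred sterile
allele `het` in `study/results/hotspots.tsv`, as expected when
heterozygotes carry the misexpression. `eqtl_strata.tsv` holds the
cis/trans × autosome/X table (41 cis, 68 trans here),
`colocalization.tsv` the hotspot ↔ sterility-QTL overlap test, and
`interaction_eqtl.tsv` / `network_edges.tsv` the conditional-mapping
results.

The same pipeline is available as library calls (`simulate_to_dir`,
`analyze`, `fertile_subset_run` in `hybridqtl.pipeline`).

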