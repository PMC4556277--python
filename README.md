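# domhier

Dominance-hierarchy analysis of dyadic animal interaction data, built for
studies of formal dominance in small social groups (the motivating case is
a kennel group of domestic dogs, but nothing is dog-specific beyond the
ethogram module).

Behavioural observers code dyadic interactions — who did what to whom,
with which body postures — into event logs. `domhier` turns such logs (or
pre-tabulated actor × recipient count matrices) into the standard
quantitative description of a dominance hierarchy:

- **Event coding.** A postural ethogram (7 postures ordered by height,
  two of them lying variants) and a 24-element behavioural ethogram with
  aggressive and fear/submission/avoidance categories. The key derived
  event is *Lowering of Posture* (LoP): a dog lowering its display into
  half-low / low / low-on-back / on-back during an interaction, scored in
  spontaneous, agonistic or competitive context.
- **Sociomatrices.** Directed count matrices per behavioural variable,
  with windowing, roster restriction, combination and transposition (for
  submission variables, so that rows always mean dominance).
- **Linearity.** Landau's index on the 0.5-filled dominance relation,
  h = 12/(n³−n) · Σᵢ (Vᵢ − (n−1)/2)², and the improved index
  h′ = h + 6u/(n³−n), where u counts unknown-or-tied dyads; significance
  by a seeded randomization test.
- **Directional consistency.** DCI = Σ(H−L) / Σ(H+L) over dyads, 0 for
  fully symmetric exchange, 1 for fully one-way exchange, plus the
  unknown / 1-way / 2-way / tied dyad census.
- **Ranking.** Dyadic win proportions Pij = s/n (or the chance-corrected
  Dij = P − (P−½)/(n+1)), David's scores DS = w + w₂ − l − l₂, normalized
  David's scores NormDS = (DS + n(n−1)/2)/n, and the I&SI rank order
  minimising (inconsistencies, summed strength) lexicographically —
  certified by exhaustive search for groups of ≤ 8, by an iterative
  swap-and-insertion heuristic with restarts above that.
- **Steepness.** The absolute OLS slope of NormDS against ordinal rank,
  with a randomization test that keeps every dyad's interaction total and
  re-draws wins Binomial(n, ½) (20,000 replicates by default).
- **Covariation.** Pearson correlations between per-individual NormDS
  profiles of the selected variables (significant h′, < 25% unknown
  dyads), average-linkage clustering on d = 1 − r with heights rescaled
  to [0, 25] (Newick export), and one-tailed Spearman correlations of
  rank with covariates such as age and weight (exact permutation null for
  groups of ≤ 10).
- **Synthetic data.** A seeded generator with a latent linear hierarchy,
  Poisson dyad totals, zero-inflation (unknown dyads) and a logistic
  win-probability slope, plus an interaction-log writer whose records the
  event coder classifies back into an exact target LoP matrix.

## Worked example

Simulate a 10-individual group in the default regime (~13.5 interactions
per active dyad, 8.9% silent dyads, strong directionality) and analyse
it:

```
$ domhier simulate --seed 7 --matrix-out lop.csv --log-out log.csv
wrote lop.csv (total events: 528; latent order: I > P > V > Z > S > K > W > T > U > B)
wrote log.csv (581 records)

$ domhier matstats lop.csv --n-rand 10000 --seed 7
N = 528
h = 0.75  h' = 0.79  (p = 0.0001, 10000 randomizations)
DCI = 1.00
unknown 7 (15.6%)  1-way 37 (82.2%)  2-way 1 (2.2%)  tied 0 (0.0%)

$ domhier steepness lop.csv --seed 7
steepness = 0.72 (variant pij)
null mean = 0.11, right-tailed p = 0.0000 (20000 randomizations)

$ domhier rank lop.csv | tail -3
U  0.944   0.052  7.056  17.441 -23.500   2.150     9
B  0.056   0.052  7.944  25.664 -33.500   1.150    10
I&SI order: I > P > V > Z > S > K > W > T > U > B (I=0, SI=0, certified=False)
```

Reading the numbers: h′ = 0.79 with p = 0.0001 says the dominance
relations are far more consistent with a single linear order than random
direction assignment would produce (the seven silent dyads keep h′ below
the ≥ 0.9 "strong" convention); DCI = 1.00 says every exchanged dyad was
one-way; steepness 0.72 against a null expectation of 0.11 indicates
large score differences between adjacent ranks (a steep, despotic-side
gradient rather than a shallow, egalitarian one); and the I&SI order
recovers the latent order the generator embedded, with zero
inconsistencies. The interaction log round-trips: coding `log.csv` with
`domhier lop-extract` reproduces `lop.csv` cell for cell.

For a full multi-variable run (per-variable property table, variable
selection, profile correlations, dendrogram, covariate tests) use
`domhier report --config cfg.yaml --outdir out/`; the config file is flat
YAML naming matrix CSVs, the variables to transpose, the status variable,
seeds and replicate counts. Everything is also callable as a library —
see `domhier.run_pipeline` and the module functions.

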