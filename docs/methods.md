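# Methods

This note documents the statistical model behind `domhier`, the
conventions and defaults it fixes, what the synthetic generator does and
does not emulate, and the design choices made where the methodology left
room.

## Event coding

Postures are ordered by display height: high (5), half-high (4), neutral
(3), half-low (2), low (1), with two lying variants that keep their
standing height — back (3) and low-on-back (1). "On-back" is treated as
an alias of "back": the results-level terminology uses both names for the
lying-at-neutral posture, and keeping one entity avoids a phantom eighth
posture.

A *Lowering of Posture* (LoP) is credited to a participant X of a dyadic
interaction, directed at the other participant, when X's display ends in
a target posture (half-low, low, low-on-back, back) and either dropped in
height or moved from standing into lying. The neutral→back transition is
height-neutral but counts as a lowering because the target list names
on-back explicitly; such events carry a `lying_transition` audit flag.
Context is assigned with precedence **agonistic > competitive >
spontaneous**: "spontaneous" is *defined* by the absence of partner
aggression, so any aggressive behaviour by the partner must dominate, and
the competitive context requires the explicit resource flag. In the
agonistic context a dog that is already low qualifies by starting to
signal fear/submission/avoidance instead of lowering further. Both
participants are evaluated symmetrically and each can contribute at most
one event per record.

Two behaviour labels used by the context rules — *chase* and *high pitch
vocalisations* — are not among the 24 catalogued behaviour elements; they
are accepted as valid labels carrying the aggressive and fear flag
respectively, so that rule evaluation matches the context definitions
exactly. *lick mouth* is an alias of *mouth lick*.

Accumulation treats every variable as a point event: for a posture
variable a participant is counted once per record if it displays the
posture at the start or the end of the interaction; for a behaviour
variable once per record if its behaviour set contains the label; for
LoP, one count per detected event. Windows are half-open `[start, end)`
over opaque ordinal timestamps — no calendar logic. Records with a
missing end posture inherit the start posture; missing behaviour sets are
empty.

The competitive-context clause "or the dog controlling the resource
showed a neutral or higher posture" is grammatically ambiguous about
which dog lowers; since both readings require the focal dog to lower,
the implementation requires `resource_context` plus a lowering and
retains the controller posture only for audit.

## Linearity and directional consistency

For each unordered dyad the dominance score is s = 1 / 0 / 0.5 (winner /
loser / unknown-or-tied, by comparing the two directed counts). With
V_i = Σ_j s_ij,

    h  = 12/(n³−n) · Σ_i (V_i − (n−1)/2)²
    h′ = h + 6u/(n³−n),   u = #unknown-or-tied dyads.

h′ is exactly the expectation of plain h when every unknown-or-tied dyad
is resolved by a fair coin: each such dyad adds variance ¼ to the two
scores involved, and 12/(n³−n) · 2u/4 = 6u/(n³−n). The test suite checks
this against a fill oracle that enumerates all 2^u resolutions exactly
when 2^u ≤ 4096 and Monte-Carlo averages (3-SE band) otherwise.

The randomization test redirects every *known* dyad with a fair coin,
keeps unknown dyads unknown, recomputes h′ per replicate, and reports
the right-tailed p = (1 + #{h′_rep ≥ h′_obs}) / (N + 1). The add-one
estimator is standard permutation-test practice and avoids reporting
zero. Ties in the observed matrix count toward the observed u but are
resolved to a direction in replicates (they are known dyads). A
`rerandomize_all_dyads` flag switches to the unconditional null in which
silent dyads are also directed; the default conditions on the observed
coverage. Both conventions are exposed because published analyses of
this design report p-values under more than one convention; neither is
labelled the correct one.

DCI = Σ(H−L)/Σ(H+L) over dyads, with H/L the larger/smaller directed
count; silent dyads contribute to neither sum, and an entirely silent
matrix has no DCI (returned as missing with a warning rather than 0).
The dyad census classifies each pair as unknown (0:0), one-way, two-way,
and additionally tied (equal nonzero); percentages are reported to one
decimal, indices to two, matching the conventional table format.

## Dyadic proportions, David's scores, steepness

Pij = s_ij/n_ij with both directions 0 for silent dyads; the
chance-corrected Dij = Pij − (Pij − ½)/(n_ij + 1) shrinks sparse dyads
toward ½, and silent dyads sit exactly at ½ (the correction's limit as
information vanishes; configurable). David's scores use the standard
w/w₂/l/l₂ decomposition; NormDS = (DS + n(n−1)/2)/n lies in [0, n−1] and
sums to n(n−1)/2 — both conservation laws are asserted property-wide.
Ordinal ranks sort by decreasing NormDS with ties broken by matrix label
order, so equal scores still receive distinct ranks deterministically.

Steepness is the absolute slope of the OLS fit of NormDS on ranks 1..n
(plain least squares, no robust variant). Its null keeps each dyad's
total n_ij and draws wins Binomial(n_ij, ½); 20,000 replicates by
default, vectorised over replicates so the full-size test runs in
seconds. p is again the add-one right tail, and the null mean is
reported alongside.

## I&SI ordering

I counts dyads in which a lower-ranked individual dominates a
higher-ranked one; SI sums their rank distances. Dyads with equal
(including zero) counts carry no direction and contribute no
inconsistency under any order — the tie convention is not settled in the
literature for this method, so the neutral choice is made and flagged
here rather than guessed as intent. Groups of ≤ 8 are solved exhaustively
(the optimum is certified; ties between optimal orders resolve to the
first in lexicographic permutation order). Larger groups use local search
from the decreasing-NormDS start with a neighbourhood of all pairwise
swaps and all single-element relocations, iterated to a fixed point, plus
20 seeded random restarts; on seeded tournaments of 5–6 individuals the
heuristic attains the exhaustive optimum in 100/100 acceptance trials.

## Covariation

Variables qualify for the covariation analysis when their linearity p is
≤ α (default 0.05; the boundary convention is a flag) and their unknown
fraction is strictly below 25%. Profiles are per-individual NormDS
vectors; similarity is Pearson r; clustering is average linkage on
d = 1 − r, so perfect anti-correlation is maximally distant (d = 1 − |r|
is available as an option). Merge heights are linearly rescaled so the
final merge sits at 25 — a pure rescaling preserves merge order and
height ratios; the verbal description of the 0–25 device in the source
material ("ratios identical to the ratios of the original correlations")
is internally inconsistent as stated, so plain linear height rescaling is
implemented and documented as such. Dendrograms serialize to Newick
(branch lengths = height differences) and to a merge-table CSV.

The rank–covariate association uses Spearman's r with average ranks for
ties and a right-tailed p (higher score paired with larger covariate is
the positive direction). For n ≤ 10 the p-value is exact, by enumerating
all n! pairings vectorised through the monotone dot-product statistic;
beyond that the t approximation on n − 2 degrees of freedom is used.

The pooled LoP variable can equivalently be analysed as its three
context-specific variables (spontaneous/agonistic/competitive); both
representations are supported since the covariation analysis is
well-defined for either set.

## Synthetic generator

The generator is the package's test bed and defines the study conditions:
n = 10 individuals, dyad totals Poisson(λ = 13.5) (≈ 550 events per
matrix), silent-dyad probability 0.089 (4 of 45 dyads unknown in
expectation), and win probability logistic in latent rank difference with
slope β = 5 — the regime in which linearity and directional consistency
both exceed 0.9 and roughly 90% of dyads are covered, i.e. the regime the
analysis is designed to describe. A logistic in rank *difference* (not
ratio) was chosen so that a single parameter sweeps cleanly from the
exchangeable null (β = 0, every interaction a fair coin) to a
deterministic hierarchy (β → ∞). A `min_interactions` clamp (default 1)
supports designs that require a minimum dyad sample. Covariates for the
ten default individuals are the published core-group ages and weights,
embedded verbatim as a fixture; other labels draw uniformly from the
observed ranges.

The log writer emits, per matrix cell (i, j), exactly counts[i, j]
records that the event coder classifies as one LoP event i → j, with
contexts drawn from a configurable mix, plus ~10% distractor records
(approaches, posture rises, friendly exchanges) that the coder must map
to nothing — asserted at generation time and re-checked in tests. Equal
seeds give bitwise-identical logs.

What the generator does *not* emulate: temporal dynamics (rank changes,
play bouts, time-of-day structure), triadic/polyadic interactions,
observer effects, or any behavioural covariance beyond the shared latent
order. Passing tests therefore demonstrate the correctness and
calibration of the *statistics* under the assumed data-generating
process, not the ethological validity of the coding scheme on real
observation data.

## Numerical and scale choices

- Randomization p-values use (1 + k)/(N + 1); comparisons use a 1e-12
  tolerance on ≥ so exact ties count.
- The linearity and steepness nulls are vectorised; default replicate
  counts (10,000 / 20,000) run in seconds on one core at n = 10.
- Calibration checks (p-value uniformity under the null) use 200
  simulated matrices with 300–400 replicates each and a
  Kolmogorov–Smirnov test at α = 0.01; tournament size 10 for linearity
  and Poisson-total groups of 8 for steepness keep the discrete support
  of the statistic fine enough for the KS comparison to be meaningful.
- The unknown-fill oracle enumerates exactly up to 2^12 resolutions,
  else Monte-Carlo with a 3-SE acceptance band (2,000 fills in the
  50-matrix acceptance sweep; a 20,000-fill spot check in the unit
  tests).
- Degenerate inputs: all-zero matrices yield missing DCI, h′ = 6u/(n³−n),
  all-equal NormDS (ranks broken by label order) and steepness 0; groups
  below 3 are rejected for h/h′/steepness; empty rosters are errors while
  windows that exclude all records produce a zero matrix with a logged
  warning.

## Known limitations

- The I&SI heuristic above n = 8 is a local search: optimality is not
  certified (`optimal_certified=False`), though restarts make failures
  rare at the group sizes this package targets.
- Exact Spearman enumeration at n = 10 materialises 10! pairings
  (~36 MB); for larger groups the t approximation is used rather than a
  Monte-Carlo permutation option.
- The pipeline treats matrices as the canonical interchange; log
  processing is a front stage rather than a streaming component, which is
  appropriate for observation studies of this size (hundreds of events)
  but not for very large logs.
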