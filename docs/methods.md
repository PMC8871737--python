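# Methods

## Population model

Three inbred founders B, E, K are crossed pairwise; each cross is advanced
by single-seed descent (one selfed seed per line per generation) to a
configurable generation (default F13) or to complete fixation. A line's
genome is represented continuously per chromosome as a pair of
piecewise-constant founder-origin functions on the genetic scale
(breakpoints in cM plus an origin label per segment); markers are imposed
only at read-out, so marker density and the crossover process are
independent choices.

Each meiosis draws a per-chromosome crossover count and places crossover
positions uniformly on [0, L] cM — Haldane's model, no interference. Two
count models are available:

- **plain Poisson** (`obligate_chiasma=False`): gamete count ~ Poisson(λ)
  with λ = L/100. The nominal genetic length is then exactly the realized
  expectation.
- **obligate chiasma** (`obligate_chiasma=True`, default): the bivalent
  draws a zero-truncated Poisson with mean 2λ and each crossover is
  transmitted to the gamete with probability ½, so every bivalent carries
  at least one chiasma (proper disjunction). This inflates the effective
  per-gamete rate to λ/(1 − e^(−2λ)), i.e. the realized genetic length
  exceeds the nominal cM by ~5–12% for λ around 1–1.5. Validations that
  compare estimates against nominal simulated truth therefore use the
  plain-Poisson setting.

The two gametes of a selfing come from independent meioses. Fixation is
detected exactly (the two origin functions of every chromosome identical);
because inherited breakpoints are bit-identical floats this is a cheap
canonical comparison, and homozygous chromosomes are skipped in later
meioses (recombining identical haplotypes cannot change the origin
function).

### Founders and markers

Markers are placed near-uniformly in bp with jitter; the bp→cM map is
piecewise linear with a recombination-poor pericentromeric core (defaults:
central 40% of the physical length carries 10% of the genetic length),
which produces the sigmoid cM-vs-Mb curve typical of assembled plant
chromosomes. Outside IBD blocks each marker's differing founder is drawn
from configurable proportions (default ¼ B, ¼ E, ½ K, one founder more
distinct, as is typical when two cultivars share recent ancestry); every
polymorphic marker separates exactly one founder from the other two.
Inside a pairwise IBD block the sharing founders are identical, so the
differing founder is forced to the third; tri-shared blocks are monomorphic
and hence unmappable. Overlapping blocks with different sharing sets are
contradictory and rejected.

Residual heterozygosity at finite generations is emitted as missing
('-'), since the parent-of-origin code set has no heterozygote symbol;
uniform missingness is applied on top. Raw nucleotide calls (the allele of
the origin parent) can be written instead of codes to exercise the
encoding path.

### Phenotypes

trait = Σᵢ effectᵢ·sᵢ + N(0, σ), with signed genotype sᵢ = +1 when the
line carries the minor allele at QTL i (the allele of that marker's
differing founder), −1 otherwise, 0 for a residual heterozygote. Genotypes
come from the true origin functions, so a QTL contributes in every
population including those where the marker itself does not segregate —
only linked markers can detect it there, as with real data.

## Estimators

**Map expansion.** For selfed RILs at fixation the observable recombinant
fraction between two loci is R = 2r/(1+2r); the package inverts this as
r = R/(2(1−R)) and converts to distance with Haldane's d = −50 ln(1−2r)
(Kosambi optional). Both directions are validated against an exact
absorption Markov chain of two-locus selfing (tests reproduce the identity
to 1e-9 across r ∈ [0, 0.49]).

**Interval estimation.** Adjacent-interval R pools informative lines
(non-missing at both markers) across the populations in which both markers
segregate. Intervals with fewer than 20 informative lines inherit the
nearest well-estimated R on the same linkage group (flagged); adjacent
markers sharing no scored population fall back to a line-wise bridging
rule, counting recombination between each line's own nearest informative
flanks. Cumulative cM starts at 0 at the first placed marker per LG.
Markers scored in no population are unmappable and reported unplaced.

**Ordering.** The initial order is physical (bp, ties lexicographic by
marker id; per-LG orientation table optional). Colormapping refinement
minimises the count of short interior genotype runs (window 1 = singleton
runs, i.e. apparent close double recombinants): groups of ≤7 markers are
solved exactly by exhaustive permutation; larger groups use greedy
first-improvement search over adjacent transpositions and segment
inversions (≤ `move_window`), which never increases the objective and is
idempotent at convergence.

**IBD gaps.** Adjacent-marker intervals with d above the threshold
(default 10 cM) are presumptive tri-shared IBD segments — between adjacent
integrated-map markers no population has a marker, so the region is
unpolymorphic in all three crosses; the gap length is the flank-R distance.
Pairwise IBD does not create integrated gaps; it is reported separately as
per-population spans of the map devoid of that population's markers (a
span without BE-segregating markers implies B = E over the span).

**Crossover statistics.** Junctions are code changes along a line's
informative marker sequence, positioned at the midpoint of the bracketing
interval; lines with fewer than two informative markers on an LG are
excluded and counted. The spacing of junctions is summarised by binning
inter-junction distances (2 cM bins, end segments excluded by default as
censored) and fitting log relative frequency on bin midpoint by
count-weighted least squares — weights ∝ count because the sampling
variance of a log proportion is ≈ 1/count; unweighted fitting is visibly
flattened by single-count tail bins. Natural logarithms are used in the
runs-theory law log F_L = 2 log ε + L log(1−ε) − ε log(1−ε), so the slope
identifies ε as 1 − e^slope; a second estimate, interval count divided by
total interval length, is reported alongside since the two differ under
model misfit.

**Trait scan.** Traits are z-scored within population (sample SD). Each
marker yields per-population Student's t (pooled variance) between the two
parent-of-origin classes, sign = alphabetically earlier class minus later,
plus a pooled series: the two populations sharing a marker both contain
its differing founder, whose lines form one class, while the two sharing
founders' lines carry the same allele and are pooled into the other.
Classes under 5 lines leave the statistic omitted and flagged — extremes
driven by missing data are artifacts. No multiple-testing correction is
applied to the reported extrema (an optional Bonferroni column is
available); cosegregating marker blocks can be collapsed to one
representative t.

**Gene-set enrichment in gaps.** Genes get map positions by linear
interpolation between flanking anchored markers on the same
pseudomolecule; genes on scaffolds are excluded from the denominator. The
observed in-gap count is tested against n·(gap cM)/(total cM) by a
two-cell goodness-of-fit χ², Yates-corrected by default (both statistics
reported; the corrected one is never larger).

## Default parameters

| parameter | default | rationale |
|---|---|---|
| chromosomes | 7 × (110, 126, 151, 132, 126, 138, 145) cM | pea-like genome totalling 928 cM |
| physical lengths | (342, 384, 463, 357, 438, 298, 393) Mb | pea-like pseudomolecules |
| markers/chromosome | 650 | ~4.5k genome-wide, Infinium-array scale |
| generations | 13 | advanced RILs by SSD |
| missing rate | 0.02 | array-typical no-call rate |
| gap threshold | 10 cM | IBD-gap definition |
| n_min informative | 20 | below it, interval R is unstable |
| scan class n_min | 5 | guards missing-data artifacts |
| runs bin width | 2 cM | resolves the spacing decay without empty-bin noise |
| cM/Mb span | 10 intervals | smooths local rate estimates |

Test and validation runs scale these down (2–3 chromosomes, 100–220
markers per chromosome, 40–200 lines per population) so the whole suite
runs in a few minutes; the estimators are n-consistent, so the scaled runs
probe the same statistical behaviour at wider tolerances.

## Numerical and design notes

- Single `numpy` Generator per run, explicit seed; draw order is founders →
  populations in the fixed order BE, BK, EK (per line: generations in
  sequence; per chromosome: count, positions, starting strand; then the
  missingness mask) → phenotypes. Same seed ⇒ byte-identical outputs.
- Breakpoints are never recomputed, only inherited, so fixation and
  homozygosity tests are exact float comparisons.
- `interval_R` clips R just below 1 and r just below 0.5 before the
  logarithm; R = 0 maps to d = 0 exactly.
- Tie-breaks are deterministic everywhere (bp ties lexicographic;
  equal-R placement resolves to the earlier map marker).
- χ² proportionality tests take the distinct-marker LG totals as the
  expectation base when provided; summing per-population columns would
  count every marker twice.

## Known limitations

- **No crossover interference.** Junction counts per chromosome in fixed
  RILs are consequently mildly *overdispersed* (variance/mean ≈ 1.2–1.3 at
  dense marker resolution; the exact multi-locus selfing chain in the test
  suite confirms the simulator's moments). Real RIL data typically show
  variance/mean below 1, the signature of interference in plant meiosis —
  so passing dispersion tests here says nothing about interference in real
  data. At coarse marker resolution (few informative loci) observable
  junction counts become underdispersed (bounded counts), which the same
  chain oracle predicts.
- Obligate chiasma is a count-truncation device, not a chiasma placement
  model; it reproduces the positive map-length intercept per chromosome
  but not positional interference.
- Genotyping error beyond uniform missingness, segregation distortion and
  selection during inbreeding are not modelled.
- Finite-generation RILs are treated with fixation-limit formulas (the
  exact chain shows per-locus heterozygosity ~2^(1−g) is negligible at
  F13).
- Centromere positions for arm analyses are inputs, never inferred.
- The simulator's population offsets for phenotypes exercise the
  normalisation path but are not a model of genotype-by-environment
  structure.
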