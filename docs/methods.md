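# Methods

`germxqtl` implements an extreme-QTL (X-QTL) bulk-segregant analysis of seed
germination speed under salt stress, together with the forward simulator
that generates the study design it analyses. This note records the models,
the defaults and why they were chosen, and what the simulation-based checks
do and do not demonstrate.

## Forward simulator

**Populations.** The mapping population is an F3 from a biparental cross
(Bs-2 x Col-0 style): two F1 gametes form each F2, and one generation of
selfing (two further meioses over the F2's haplotypes) forms the F3, with no
selection between generations. Meiosis uses the Haldane map function
`r = (1 - e^(-2d/100))/2` with no crossover interference, so recombination
events in disjoint marker intervals are independent Bernoulli draws — the
property the vectorised gamete sampler exploits. Genetic positions come
from a constant per-chromosome recombination rate (default 4 cM/Mbp, giving
~120 cM per 30-Mbp chromosome, in the range of the *A. thaliana* map).
Expected F3 Col-0 allele frequency is 0.5 and heterozygosity 0.25 (F2
heterozygosity halved by one selfing); both are checked to four binomial
standard errors at n = 2000.

**Panel.** Desk-scale default: 5 chromosomes x 30 Mbp, 3000 evenly spaced
SNPs (the published platform had ~30,389 SNPs over the 5 A. thaliana
chromosomes; 600 SNPs/chromosome keeps marker spacing, ~50 kb, well inside
the F3 LD scale of roughly a centimorgan, so density is not limiting).
Full publication-scale panels and populations are accepted but not default.

**Germination-time model.** For individual *i* with Col-0 dosage `d_q` at
each QTL *q*,

    t_i = baseline + sum_q e_q(env) * (d_q - 1 + dom_q * 1[d_q = 1]) + eps_i

where `e_q(env)` is the additive effect in hours per Col-0 allele in the
given environment (a locus with an effect only under salt is a cryptic
variant), `dom_q` in [-1, 1] shifts the heterozygote, and individuals with
`t_i` beyond the environment's censoring time never germinate within the
scoring window. Multi-locus genotypes with mixed-sign effects produce
transgressive segregation automatically.

**Noise is right-skewed, not Gaussian — and this matters.** `eps_i` is a
zero-mean gamma deviate (shape `k`, SD `sigma`). A sharp onset followed by
a long tail is the shape of real stressed germination-time distributions
(a declining hazard: the germination-competent fraction goes quickly, the
rest trickle out over weeks), and it is a *requirement* for the observed
cohort phenomenology, not a cosmetic choice. For any additive biallelic
locus at frequency 0.5 whose residual is iid, symmetric and unimodal on
*any* monotone transform of the time axis, the slow-homozygote density
exceeds the fast-homozygote density only past the midpoint of the
homozygote means — a point the cumulative distribution reaches at >= 37.5%
— so with only ~23% of seeds germinating, a late 20th–23rd percentile
cohort could never be enriched for the slow allele. The opposite early/late
allele-frequency bias that motivates time-cohort X-QTL therefore cannot
occur under Gaussian noise at this censoring level. With a sharply
right-skewed residual the late window catches the slow genotype's onset
burst while the fast genotype is already deep in its thin tail, and the
bias flips sign. Numerically (salt defaults below, one -12 h/allele
locus): early-cohort Col-0 frequency ~1.0, late-cohort ~0.32.

**Environment defaults** (frozen from a design study before any
pipeline-level testing):

| environment | baseline (h) | noise SD (h) | gamma shape | censor (h) |
|---|---|---|---|---|
| `salt_250mM` | 300 | 100 | 0.7 | 232 |
| `no_salt` | 40 | 8 | 4.0 | 120 |

The salt censor time is the 23% germination quantile of the default
single-QTL scenario, mirroring the ~23% harvest fraction of a 15-day salt
selection; the no-salt environment germinates essentially completely
(shape 4 is mildly skewed — benign media produce more symmetric schedules).
Setting noise SD to zero makes the phenotype model exactly deterministic.

**Cohorts.** Germinants are ranked by time (ties broken by individual
index) and assigned by rank/total-seeds to half-open percentile bands of
*total seeds*: early [0, 0.05), medium [0.05, 0.20), late [0.20, 0.23).
With 100 seeds and 23 germinants this yields cohort sizes 5/15/3. The
all-germinant pool is the n-weighted mixture of the three cohorts.

**Array model.** Each SNP has two allele probes with lognormal
probe-specific affinities (SD 0.3 on the log scale). A hybridization
produces, per replicate and dye orientation,

    signal_col = a_col * f * g * (1 + eps),   signal_bs = a_bs * (1-f) * g' * (1 + eps')

with multiplicative Gaussian noise of CV 0.05 and the two dye gains
(1.0, 1.3) exchanged between the forward and swapped orientations. Pool
frequencies are floored at 1e-4 from the boundaries (cross-hybridization:
a fixed pool still yields faint signal on the other probe, and a genuinely
zero intensity would be un-normalisable).

## Allele-frequency estimation

Per SNP and replicate, the col/bs channel ratio is geometric-mean averaged
over the dye-swap pair (dye gains cancel exactly), divided by the matching
reference-pool ratio (probe affinities cancel exactly), and the corrected
odds — relative to the random-F2 reference frequency of 0.5 — converted to
a frequency. A pool identical to the reference lands at 0.5, which is how
reference normalisation absorbs segregation distortion. Estimates are
clamped to [0, 1] with the clamp count logged; SNP/replicate pairs missing
a dye-swap partner are dropped, not imputed.

## Scan statistic and significance

**Windowed nested ANOVA.** For each focal SNP the window is the `w`
consecutive panel SNPs centred on it (default `w = 9`), truncated at
chromosome ends and never spanning chromosomes. The response is the
per-SNP, per-replicate-pool frequency estimate in the window; factors are
selection condition (fixed, selected vs control), replicate pool nested in
condition, and SNP-in-window as the residual stratum. The reported F tests
condition against replicate-within-condition and carries the sign of the
window mean-frequency difference (positive = Col-0 bias). Because both
mean squares average over the window, this F is computed from per-replicate
window means (a one-way ANOVA on them); a brute-force sums-of-squares
decomposition over the full window table is kept as a test oracle and
agrees to 1e-10. The nesting structure is this package's explicit reading
of a "three-way nested" scan model; it is a design decision, documented as
such.

**Replication and exchangeability.** Each replicate pool is an independent
selection experiment (its own simulated F3 population). Two desk-scale
constraints set the default of 10 replicate pools per condition, both fixed
before the validation runs: (i) a genome-wide permutation test at
alpha = 0.05 over replicate labels needs at least 40 distinct label
assignments, i.e. R >= 4; (ii) an analytic (noncentral-F) power analysis of
the weakest contrast the simulator must support — the late-cohort scan,
|Delta f| ~ 0.18 with ~50-seed pools — against a per-run power target of
0.97. Control pools are subsampled to the expected early-cohort size
(~100): at desk scale pool-composition noise dominates array noise, and
equal pool sizes are what make replicate labels exchangeable under the
null; with full-size (~2000-germinant) control pools the permutation
threshold is badly anticonservative. At publication scale (10^5 seeds)
array noise dominates instead and this subtlety vanishes.

**Permutation threshold.** Replicate-pool labels are permuted across the
two conditions (dye-swap pairs stay intact inside a replicate); each
permutation's genome-wide max |F| forms the null distribution, and the
threshold is its empirical (1 - alpha) quantile taken as the next-higher
order statistic (the standard, slightly conservative permutation
convention). Default 200 permutations, alpha 0.05, deterministic given the
seed. Window-size selection runs this per candidate window and takes the
smallest window whose threshold is within 5% of the next larger one.

**Interval calling.** Runs of consecutive SNPs with |F| >= threshold
(boundary SNPs count as significant) and a shared direction become
intervals spanning first-to-last SNP position. Adjacent same-direction runs
on a chromosome closer than 1 Mbp are merged transitively; opposite
directions never merge, and an interleaved opposite-direction run blocks
merging across it (the literal "merge everything same-direction" rule could
create overlapping opposite-direction intervals). Coordinates are 1-based
closed internally; BED output converts to 0-based half-open.

## Germination kinetics

Cumulative curves are interval counts accumulated and divided by total
seeds. The four-parameter Hill function `g(t) = y0 + a t^b / (c^b + t^b)`
is fitted by bounded least squares (a, b, c > 0; 0 <= y0 <= 1) with at most
100 function evaluations and an objective tolerance of 1e-8; initialisation
is y0 from the curve minimum, a from the observed rise, c from the earliest
half-rise crossing, b = 2. Hitting the iteration cap clears the converged
flag rather than raising; an all-flat curve is returned as degenerate. For
positive (a, b, c) the fitted curve is analytically non-decreasing. t50 is
reported in two modes — relative (time to half the fitted rise, identically
`c`) and absolute (g = 0.5 of total seeds, undefined when the fitted
asymptote stays below 50%) — because either convention is found in the
germination literature; relative is the default.

Stage-schedule comparisons use the pooled-variance two-sample t-test from
summary statistics (df = n1 + n2 - 2); this is the variant that reproduces
published founder stage-timing p-values from triplicate means/SDs. One
published row (cotyledon greening under salt, printed 0.0177) is not
reproduced by any summary-statistic pooled test (it gives 0.0244) and one
row (testa rupture without salt, printed 0.6211) lands at 0.6209 from the
printed, rounded inputs — both are input-precision artefacts, noted here
rather than chased. The genotype x environment analysis is a fixed-effects
two-way ANOVA with interaction on a balanced 2x2 design of replicate t50
values (statsmodels OLS/anova_lm; in the balanced case all
sums-of-squares types coincide, and a by-hand decomposition is kept as a
test oracle).

## What the simulations show — and what they do not

The validation harness demonstrates, at desk scale (3000 SNPs, 2000 seeds
per replicate pool, 20 seeded runs each, ~2-3 s per run):

* family-wise false-positive calibration of the called QTL under a global
  null (200 runs, bound alpha + 3 Monte-Carlo SE);
* recovery of a single cryptic -12 h locus by the early-cohort salt scan,
  and its silence in an equally powered no-salt scan;
* opposite called directions for the same locus in early vs late cohorts.

The generator reproduces the *mechanisms* (truncation selection, cryptic
G x E effects, dye-swap array structure, reference normalisation), not the
full complexity of real data: no linked multi-QTL architectures beyond
what the user configures, no epistasis, no probe outliers or spatial array
artefacts, no segregation distortion (the reference-normalisation path is
exercised algebraically, not by simulated distortion), and pool-composition
noise plays a far larger role at desk scale than it did at publication
scale. Passing these checks validates the statistical machinery, not any
claim about a particular real locus.

## Numerical and degenerate-input conventions

Zero condition difference gives F = 0 (not 0/0); identical replicates
within both conditions with a nonzero difference give +inf, which the
threshold handles naturally. Frequency clamps and dropped dye-swap
partners are counted and logged. Cohort assignment is reproducible under
ties (stable sort by time then individual index). All randomness in a run
flows from a single integer seed; identical configurations are
byte-identical.
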