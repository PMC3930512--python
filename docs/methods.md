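# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical choices at the edges. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Cross model and coordinates

Genetic positions are chromosome-local centimorgans with the origin at
the first marker; intervals are closed on cM. Physical Mb positions are
used only for reporting and are obtained by linear interpolation
between flanking markers (`cm_to_mb`); positions outside the marker
range are clamped with a warning. The male X is hemizygous: two
genotype classes (A, B), never AB — an AB code on the X is a hard input
error, while codes outside the known vocabulary are demoted to missing
with a logged count.

The fertile-subset selector standardizes the four sterility traits,
takes the first principal component of the complete cases (individuals
missing any trait are dropped from this computation only), orients it
so the first listed trait — conventionally testis weight — loads
positively (higher score = more fertile), and keeps individuals
strictly above the requested percentile (default 20th). If every trait
is constant the PCA is degenerate; the full set is returned with a
warning rather than an error, since downstream stages remain well
defined.

## Genotype probabilities

True genotypes along a chromosome form a Markov chain: the F2 autosome
chain is the tensor product of two independent gamete chains, giving
the standard intercross transition matrix over {AA, AB, BB} with
interval recombination fractions from the configured map function; the
male X is a single gamete chain. Emissions are symmetric errors:
P(observed = true) = 1 − e, with e split evenly over the wrong classes
(default e = 0.001); missing observations emit uniformly. Posterior
probabilities come from scaled forward–backward smoothing.

The grid holds every typed marker plus pseudomarkers at
first-marker + k·step (default 2 cM), truncated at the last marker;
pseudomarkers landing within 1e-9 cM of a marker are merged so each
marker appears exactly once. Correctness is pinned by an exhaustive
enumeration oracle on chains of up to four positions (both chromosome
models, with and without error, agreement ≤ 1e-9).

Map functions: Haldane and Kosambi invert in closed form;
Carter–Falconer (which models crossover interference and is the
default for analysis) is inverted by bracketed Brent root-finding on
the forward function to 1e-12. The simulator defaults to Haldane so
that its no-interference crossover process matches the HMM transition
model exactly; analysis/test pairings use matched functions.

## Genome scans

Haley–Knott: the trait is regressed on expected genotype-class
probabilities — columns (p_AB, p_BB) on autosomes (a 2-df model), (p_B)
on the X — and LOD = (n/2)·log10(RSS_null/RSS_model). EM interval
mapping fits the normal mixture with class means and a common SD,
priors being the HMM probabilities, iterated to a relative
log-likelihood change < 1e-6 (cap 1000 iterations); at a fully typed
marker the mixture collapses and EM equals HK, which the tests assert
to 0.01. EM is implemented for covariate-free scans; conditional scans
use HK, where the additive design is nested in the full design by
construction so LOD_i ≥ 0 holds exactly rather than approximately.

Positions where the model fits perfectly (residual sum of squares below
1e-12) are flagged `degenerate` and the RSS is floored there; this
keeps LODs finite for pathological traits (e.g. a trait equal to the
genotype dosage).

Covariate genotypes are taken as the most probable class at the typed
covariate marker; exact ties are treated as missing and those
individuals are dropped (error if more than 20% would be lost). The
full model adds covariate-class-indicator × genotype-dosage products
(two terms for an autosomal covariate, one when the covariate is on
the X).

Expression traits are normal-quantile transformed,
x ↦ Φ⁻¹((rank − ½)/n) with average ranks for ties; the (rank − ½)/n
plotting position is one of several conventional choices and is fixed
here. After this transform all traits share one distribution, which is
what justifies a single-transcript permutation threshold.

## Permutation significance

The X chromosome is a separate stratum: the genome-wide α (default
0.05) is split between autosomes and X in proportion to map length,
and the X permutation count is scaled up by the autosome/X length
ratio so the much smaller α_X quantile is estimable. Thresholds are
upper (1 − α_stratum) sample quantiles (type "higher", so α = 1
degrades to the null minimum). Dataset-wide thresholds permute the
individual ↔ expression-column assignment once per replicate —
preserving inter-transcript correlation — and take maxima over all
transcripts, with a single permutation count for both strata.

Permutation P values use the add-one tail rule
P = (1 + #{null ≥ obs})/(n_perm + 1). q-values follow the Storey
procedure with π₀ estimated on the λ grid 0.05…0.95 by a cubic
polynomial smoother evaluated at the largest λ, clamped to (0, 1];
q_i = min over p_j ≥ p_i of π₀·n·p_j/rank(p_j).

LOD support intervals take the outermost grid positions within `drop`
(default 1.5) of the peak and extend one grid position outward where
available; a secondary peak within the drop extends the interval across
the intervening valley (documented behaviour of the outermost-position
rule), and a flat profile yields the whole chromosome with a warning.

## Misexpression

F1 rule (replicated groups): mean outside both parental means, both
Welch tests significant at q ≤ 0.05, and both mean differences > 0.5
log2. F2 rule (a single value per individual): value outside both
parental means with the distance to the nearer parental mean exceeding
both 0.5 and 2 standard errors of that parental group mean — the F2
contributes one observation, so the only available SE is parental.
Counts per individual (over/under × autosome/X) are square-root
transformed exactly once and mapped as phenotypes. Classification is
antisymmetric under negation of all values (over ↔ under), which the
suite asserts exactly.

## eQTL catalog

Per trait and chromosome at most one record: the left-most maximum-LOD
grid position if it clears the stratum threshold. cis means same
chromosome and |peak − probe| < 5 cM; trans means a different
chromosome; same-chromosome distal peaks are excluded from both
classes. Dominance is read from genotype-class means at the peak's
nearest typed marker (pseudomarkers have no observed classes), using
most-probable class assignment and requiring ≥ 3 individuals per
class; "two standard errors" is interpreted as the combined SE of the
two compared class means, √(se₁² + se₂²). Effect size is the absolute
difference between extreme homozygote (or hemizygote) class means.

Sterile-allele inference at a hotspot: each member transcript with a
sterile-F1 misexpression call votes for a genotype class — its
low-expression class if F1-underexpressed, its high class if
F1-overexpressed. The majority class wins at ≥ 60% concordance among
≥ 20 members; "het" is eligible only when ≥ 50% of members are over-
or underdominant. The 60%/20 gates are package choices (configurable);
the qualitative procedure they implement is inherently judgement-based.

## Trans hotspots and co-localization

Windows of 4 cM anchored at every grid position, half-open [lo, lo+4),
truncated (and size-recorded) at chromosome ends; the terminal grid
position is closed into end windows so no peak is lost. The null
reassigns each trans eQTL independently to a uniform grid position on
a chromosome other than its probe's chromosome — preserving the
per-probe eQTL count and the trans definition; the alternative reading
("other than the observed eQTL's chromosome") is available behind
`exclude="eqtl"`. Thresholds are per-window-size 95th-percentile
maxima; windows strictly above threshold are merged when overlapping
or adjacent, and merged hotspots inherit member-window significance.
Null calibration (uniformly reassigned records, thresholds recomputed
per replicate) runs in the suite at 200 replicates.

Co-localization keeps sterility intervals fixed and re-places the
observed hotspot sizes, largest first, uniformly at grid anchors where
they fit within a chromosome, rejecting overlaps (error after 10,000
attempts per interval). Three statistics are recorded — hotspots
overlapping any sterility QTL, overlapping grid positions, total cM of
overlap — each with its own add-one permutation P.

## Conditional mapping and the network

Per covariate, each permutation's shuffled trait is scanned under both
the additive and the full model, so the LOD_i null is a paired
difference within a permutation, never mixed across permutations.
Positions within 5 cM of the covariate marker are masked
(self-interaction guard). An interaction eQTL is the maximum-LOD_f
position among positions where both LOD_f and LOD_i clear their
stratum thresholds; interaction hotspots reuse the sliding-window
machinery on those peaks. Network nodes single-linkage-merge
same-chromosome regions whose gap is < 12.8 Mb (order-independent, the
suite checks); edges run covariate → hotspot with summed eQTL counts
and a reciprocal flag when the reversed edge exists. The per-covariate
summary reports the fractions of interaction eQTL with an original
(no-covariate) eQTL within 5 cM of the covariate and of the peak, and
with a significant reversed-configuration interaction.

## Simulator: what it emulates, what it does not

Emulated: an intersubspecific F2 sibling-mating design (n = 300 males
by default; 19 autosomes + X with ~200 evenly spaced markers, Mb =
2 × cM), cis effects (additive + dominance deviation), trans master
regulators in five dominance modes, purely epistatic pairs whose
product-pattern deltas (±e on the four double-homozygote classes) have
exactly zero marginal means for unlinked loci, two-locus
(Dobzhansky–Muller) effects on phenotypes confined to one genotype
class, parental/F1 control groups (8/8 parents, 6 DxM + 4 MxD F1
males, the study-typical sizes), F1-male X following the maternal
lineage, and i.i.d. Gaussian noise. Over- and underdominant modes both
shift heterozygotes only; the effect's sign carries the direction
(negative = heterozygotes below the homozygotes). Everything is a pure
function of (inputs, seed).

Not emulated: crossover interference (the no-interference process
matches the HMM exactly, which is the point of a matched
generator/analysis pairing; Carter–Falconer remains available for
analysing real data), spatial array artifacts, probe-specific noise,
batch effects, Y-linked markers, and non-male F2s. Passing tests
therefore demonstrate correctness of the inference machinery under its
own assumptions, not robustness to real microarray pathology.

One property of correlated trait panels deserves emphasis: when many
transcripts share one strong genetic component, the chance correlation
of that component with an unlinked marker elevates *all* of them
together, producing coherent clusters of false trans eQTL ("ghost"
hotspots) under a permissive single-transcript threshold — the reason
dataset-wide thresholds exist. The recovery simulations size the shared
effect at a homozygote difference of ~1.3 noise SD, where the causal
hotspot is recovered with high LOD and tight localization while ghost
clusters stay below the window thresholds; at a 4× stronger shared
component the ghosts become real enough to call, which is behaviour,
not bug.

## Problem sizes

Chosen so the whole suite and the acceptance script each complete in a
few minutes on one CPU: threshold calibration uses 500 null replicates
at 200 autosomal permutations (X scaled) on a 5-autosome + X genome at
n = 300; hotspot-null calibration 200 replicate datasets of 5,000
records with 200-permutation thresholds each on the full 20-chromosome
map; recovery and fertile-contrast simulations 20 seeded runs each at
n = 300; paper-scale permutation counts (10,000/158,550 single
transcript, 360 dataset-wide, 10,000 hotspot and co-localization) are
reachable through `AnalysisConfig`.

## Known limitations

- Extended Haley–Knott is not implemented; non-normal phenotypes are
  mapped with standard HK (affects heavy-tailed sterility traits).
- EM with covariates is not implemented; conditional scans are HK.
- Rank-deficient scan designs (a genotype class entirely absent at
  zero error rate) are not re-parameterized; the default error rate of
  0.001 keeps designs full-rank in practice.
- The q-value smoother is a cubic polynomial, not a smoothing spline;
  π₀ estimates on small p-value sets are noisy either way.
- Multiple-QTL models, composite interval mapping, and full two-locus
  pair scans are out of scope.
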