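# Methods

This note documents the models, statistical procedures and design
choices behind `denitscape`, in the order the pipeline runs.

## Genome typing

A genome's denitrification repertoire is reduced to booleans for
*nirK*, *nirS*, *nor* (any heme-copper NO-reductase subtype — subtypes
are treated equivalently), *nosZ*, a *nosZ* clade (I, II or both), and
two exclusion flags. Classification:

* complete — (*nirK* or *nirS*) and *nor* and *nosZ*
* initiator — *nir* without *nosZ* (with or without *nor*)
* terminator — *nosZ* without *nir* (with or without *nor*)
* initiator-terminator — *nir* and *nosZ* without *nor*
* non-denitrifier — neither *nir* nor *nosZ* (including *nor*-only
  genomes, whose Nor likely detoxifies rather than respires), and any
  anammox or archaeal-nitrifier genome regardless of gene content,
  because their nitrite reductases are not respiratory denitrification
  enzymes. Exclusion flags override gene content.

Quality filtering is strict at the boundaries: genomes *below* 80 %
completeness or *above* 5 % contamination are removed, so values
exactly at the thresholds are retained; GUNC failures are removed when
required. Genomes with missing growth predictions or fewer than 10
annotated ribosomal proteins are dropped from growth analyses only,
never from classification.

Growth rates are binned fast/slow at 0.2 h⁻¹; a rate exactly at the
cutoff is "fast" (the source framing assigns "faster than" to fast and
"lower than" to slow, leaving the boundary open; we close it upward).
Codon-bias growth predictions saturate below the cutoff, which is why
ranked comparisons support a *tie floor*: all values below the floor
are replaced by it before ranking, collapsing them to one shared rank.

In clade-conditional summaries a genome carrying both *nosZ* clades is
counted as clade I — conservative toward the known clade I /
complete-pathway association — and the count of such genomes is
reported alongside.

## Rank statistics

`compare_groups_ranked` runs the tie-corrected Kruskal–Wallis test
(scipy) followed by Dunn pairwise z-tests on pooled mid-ranks with the
tie-corrected standard error, Benjamini–Hochberg adjustment across the
pairs of one call only, and a compact letter display built with the
insert-and-absorb algorithm at α = 0.05 (deterministic group order, so
letters are reproducible). If every value is tied the statistic is 0
and p = 1 by convention. The one-sided two-sample KS test reports
D⁻ = max(F_b − F_a) over the pooled support — the hypothesis that
sample b is stochastically smaller — with the one-sided asymptotic
p-value exp(−2mnD²/(m+n)).

## Community delta statistics

Reads surviving the placement filter require (a) at least 95 % of
their placement mass accumulated on one clade, (b) zero outgroup mass,
and (c) a clade outside the exclusion set (non-denitrifying anammox
NirS clade 1h, archaeal-nitrifier NirK clades 2 and 4, eukaryotic NirK
clades 1b and 1e, and *nosZ* clade III, the reference-tree outgroup).
Mass accumulation is evaluated at the clade level (per-clade mass
sums), which matters for users supplying raw jplace files where a read
may hit several edges of one clade.

The deltas divide the count difference by total sequenced bases,
`read_length × reads`, scaled to copies per Gbp. Read length is a
per-sample column defaulting to 150 nt (reads longer than that are
truncated upstream of this package). Samples where one or both gene
groups are undetected are retained — the delta is defined there, which
is the reason the statistic is a difference rather than a ratio.
Metatranscriptomes use the identical formulas with mRNA reads as the
denominator. Marine zone assignment uses absolute latitude with the
inclusive-lower convention: polar > 60°, westerlies [30°, 60°],
trades [0°, 30°).

## Placement validation

Reference sequences are cut into non-overlapping read-length windows
from position 0; a final window anchored at the sequence end is added
when the leftover tail is at least one third of a fragment (the tail
window overlaps its neighbour). The built-in placer scores each
fragment against every reference by the best ungapped alignment
identity over offsets seeded by shared 8-mers, gives mass 1.0 to the
top-scoring clade and splits it equally on exact ties; outgroup
references compete on equal footing, and sub-50 %-identity best hits
are flagged. This stand-in placer exists because the validation
statistics are placer-agnostic: sensitivity (ingroup fragments placed
in the ingroup) and specificity (one minus outgroup leakage into the
ingroup) accept externally produced placements, so full phylogenetic
placement output can be dropped in. For multi-clade families the
outgroup-leakage denominator is shared across clades. Validation of
simulated references is leave-one-parent-out — each sequence's
fragments are placed against all *other* references — since
self-matches would trivially saturate both statistics.

## Environmental responses

Relative abundances are standardized by dividing each MAG's row by its
maximum across samples (all-zero MAGs are returned as zeros and
flagged). Each MAG's standardized abundance is regressed on NO3− and
chlorophyll in one joint OLS model (each slope adjusts for the other)
plus a separate model on ln(chlorophyll / NO3−), zeros offset by half
the smallest positive value before the ratio. Per-type responses are
inverse-variance weighted means of the per-MAG slopes. The default CI
is the Knapp–Hartung interval (t quantile on k−1 df with the
weighted-spread variance): with 2–14 MAGs per type, the plain normal
interval on 1/√Σw is measurably anticonservative (~94.3 % coverage in
a 1000-replicate calibration check) because the weights themselves are
estimated, while Knapp–Hartung stays at nominal coverage; the normal
interval remains available via `ci_method="normal"`. A single MAG
falls back to mean ± 1.96·SE. Types are declared different when their
95 % CIs do not overlap.

Predictor screening keeps, within each connected component of the
|Spearman ρ| > 0.7 graph, only the highest-priority predictor, then
iteratively drops the highest-VIF predictor (lowest priority breaking
ties) until all VIF ≤ 4, with VIF computed by auxiliary regression.
Stability selection emulates repeated forest-based variable selection:
each of 100 runs appends a shuffled decoy copy of every predictor,
fits a random forest, computes permutation importance, and keeps real
predictors beating the best decoy; predictors retained in ≥ 95 runs
survive. This decoy protocol is a stand-in for the original VSURF
procedure — it follows the same 100-run / ≥95 retention protocol but
its internal thresholding differs, so identical retained sets are not
claimed; externally produced selections can be supplied instead.
Forest tuning grid-searches mtry / nodesize / sampsize by out-of-bag
RMSE at 500 trees (sklearn `RandomForestRegressor`; OOB predictions).

First-order ALE curves use quantile bins (reduced with a warning when
the feature has fewer distinct values); within each bin the prediction
difference between the bin edges is averaged over that bin's observed
rows, differences are accumulated, and the curve is centered so the
bin-count-weighted mean effect is zero. Effects are reported at right
bin edges. For a linear model the curve is exactly linear regardless
of binning.

## Meta-analysis

Hedges g uses the bias correction J = 1 − 3/(4(n₁+n₂−2)−1) and the
standard large-sample variance (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)).
Pooling is fixed-effect inverse-variance by default — the analysis
these tools mirror does not state the model — with a
DerSimonian–Laird random-effects switch; Q and I² are always reported.
Correlation pooling first averages effects that share a study but
differ in filter fraction (one study, one vote), then takes the
sample-size-weighted mean of study-level r with a normal-approximation
CI from the weighted spread of study effects (large-sample variance of
r for a single study). Fisher-z pooling was deliberately not used, to
match the bare-bones weighted-mean convention of the upstream
approach.

## Synthetic data

The generators define the study conditions for all tests; they are
pure functions of their configuration (seed included; per-generator
substreams are derived with CRC-32 keys so runs are reproducible
across processes).

* **Genomes** — type counts follow the configured mixture (defaults:
  18 % denitrifiers; complete 23 %, initiators 49 %, terminators 24 %,
  initiator-terminators 4 % of denitrifiers) by largest-remainder
  quota, then types are assigned to genomes in random order: the
  configured mixture is the ground truth rather than a multinomial
  draw. Gene presence is drawn consistently with each type (*nirK*
  -dominant nitrite reductase choice; clade I for 74 % of complete
  denitrifiers, clade II for 80 % of terminators); non-denitrifiers
  include *nor*-only and rare anammox-with-*nir* genomes. Genome sizes
  are lognormal (median 4 Mbp, σ = 0.35), growth rates lognormal with
  per-type medians 0.46/0.28/0.23/0.20 h⁻¹ (0.25 for
  non-denitrifiers), and ~10 % of genomes receive quality metrics that
  fail the filter. Trait counts (transporters, transcription factors,
  substrates, redox couples) are Poisson around per-type densities
  with complete denitrifiers the most generalist.
* **Metagenome counts** — Poisson counts at fixed depth, with per-gene
  per-Gbp rates solved from the configured biome offsets so the
  expected deltas equal them exactly: nir total = base rate (400 per
  Gbp, 60 % *nirK*), nos total = base + δnos-nir, clades split by
  δnosZI-nosZII. Infeasible (negative-rate) configurations are
  rejected. Default biome offsets make *nir* dominate everywhere and
  clade II dominate except in engineered communities.
* **Reference sequences** — clade ancestors evolve from a common root
  at the between-clade divergence (outgroup at a higher divergence),
  descendants at the within-clade divergence, by i.i.d. uniform
  substitution over the three alternative bases (Jukes–Cantor-like).
  Adequate for placement separation tests; no indels, rate variation
  or tree structure below the clade ancestors.
* **MAG survey** — standardized abundances follow per-type linear
  responses to the gradients plus Gaussian noise (σ = 0.05). Because
  the downstream pipeline re-standardizes by each MAG's *observed*
  maximum, the generator pins the scale-defining observation: each
  gradient includes one sample at either extreme (interior samples
  drawn from the central 40–100 % of the range) so a responsive MAG's
  optimum sits at an isolated design point, and that observation is
  set to the exact noise-free peak. This is not a loss of generality —
  the standardized scale is *defined* relative to the observed
  maximum, so noise on the scale-defining observation is
  unidentifiable from rescaled noise on all the others — and without
  it the empirical-maximum division multiplicatively shrinks every
  recovered slope. Unresponsive MAGs stay flat at mid-range, where the
  noisy maximum only rescales a zero slope. Abundances are then scaled
  to a configurable maximum relative abundance (2 %).

What passing tests show, and what they do not: the generators contain
no phylogenetic autocorrelation, no compositional coupling between
MAGs, no overdispersion beyond Poisson, and no spatial or temporal
structure in the environmental gradients. Recovery results therefore
validate the estimators' correctness under their stated assumptions,
not robustness to the full messiness of field data.

## Numerical conventions and degenerate inputs

Missing values are "NA" or empty on input, "NA" on output; floats are
written with 17 significant digits so tables round-trip exactly.
Placement masses may exceed 1 per read by at most 1e-6. All-tied rank
inputs yield statistic 0 / p 1. ALE requires ≥ 2 distinct feature
values. The weighted-response coverage guarantee is a statistical one:
a 95 % CI covers the truth in ~95 of 100 replicates, so a ≥ 93/100
acceptance on any fixed 100-replicate battery can fail by binomial
noise alone (~1 time in 8 per type) even though 1000-replicate
calibration shows nominal coverage; the test suite keeps the strict
per-type assertion and documents this behaviour rather than widening
it.

## Known limitations

The nearest-reference placer is a deliberately simple identity
classifier, not a phylogenetic placement method; its
sensitivity/specificity numbers characterize the synthetic separation
scenario, not any real reference database. Tweedie mixed models for
substrate counts, phylogenetic signal testing, and ecoregion-based
biome assignment are out of scope; their outputs are consumed as
table columns where needed.
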