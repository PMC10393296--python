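# Methods

This note records the modelling choices behind `ciliareg`: what each
procedure assumes, which defaults matter and why, what the synthetic
generator does and does not emulate, and the numerical conventions used
throughout. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates and sequence conventions

All intervals are 0-based, half-open. GFF3 input is converted on read.
For a minus-strand gene model the stored TSS/translation-start coordinate is
the half-open boundary just 5′ of the first transcribed/coding base in
genome coordinates, so the upstream interval is always `[a, a+L)` on the
minus strand and `[a−L, a)` on the plus strand — one formula per strand, no
off-by-one cases downstream. Promoters default to 700 bp upstream of the
translational start: nematode 5′UTRs are short and trans-splicing makes
transcription starts unreliable, so the translation start is the more stable
anchor for regulatory sequence.

## PWM scanning

A PWM stores per-position log2 odds against a background distribution:
`log_odds[i,b] = log2(p_ib / bg_b)` with
`p_ib = (counts[i,b] + pc·bg_b) / Σ_b'(counts[i,b'] + pc·bg_b')`.
The default pseudocount 0.01 keeps all cells finite while leaving informative
positions essentially unchanged; an explicit zero-pseudocount mode scores
impossible bases as −10⁹ rather than −∞ so window sums stay finite and
comparable. The default match threshold is 0.8 × the maximum attainable
score — a scale-free choice, configurable per call, since no absolute
threshold transfers across matrices of different widths and information
content. Windows containing N never match. Reverse-strand matches are scored
against the reverse-complemented matrix and reported in forward coordinates,
which makes strand symmetry an exact invariant (tested against an exhaustive
per-window oracle and against Biopython's PSSM scoring).

The shipped X-box matrix is a **synthetic** RFX-like matrix built by
concentrating 85% of each column's mass on the canonical *C. elegans* X-box
consensus `GTTGCCATGGCAAC` (a perfect palindrome; real X-boxes are imperfect
palindromes, so this is an idealization adequate for planted-motif recovery,
not a database PWM). The Forkhead-like matrix is built the same way from
`GTAAACA`.

## K-mer over-representation

An order-0 stand-in for de novo word discovery: every window contributes one
canonical k-mer (lexicographic min of k-mer and reverse complement;
palindromes counted once), the null occurrence probability is the i.i.d.
product under the chosen background (estimated from the input, supplied
explicitly, or taken from a background sequence set), the p-value is the
binomial upper tail over all N windows, and Benjamini–Hochberg control is
applied over all canonical k-mers. Markov backgrounds above order 0 and
assembly of significant words into matrices are out of scope.

## Peak annotation

Each peak is reduced to a point anchor — the summit when the caller reported
one, else the midpoint. A point anchor makes tie-breaking and distance
semantics exact and testable, at the cost of diverging from annotators that
use full-interval overlap; the feature hierarchy is likewise collapsed to
four classes (promoter > genic > downstream(≤3 kb) > intergenic) because the
downstream analyses only consume the promoter assignment and the
gene-to-peak map. Promoter means the anchor falls in the strand-aware
window `[TSS−2000, TSS+1000)` in transcript orientation. The assigned gene is
the nearest-TSS gene among those whose window contains the anchor (otherwise
the nearest TSS overall); ties break to the lexicographically smaller gene
id, deterministically. Consequently the reported promoter fraction is not
bit-compatible with seven-class annotators, and `battery_binding` by default
counts a battery gene as bound only via promoter-window assignments —
binding to the regulatory region, which is the quantity the prioritization
uses. Counting any assignment is available via the `features` argument.

## TF prioritization

Across TFs, battery genes bound is regressed on total peaks (OLS). A TF
whose externally studentized residual exceeds the two-sided t critical value
at the Bonferroni-adjusted 0.05 level is flagged: it binds the battery in
excess of what its overall peak count predicts. With exactly three TFs the
externally studentized residual has no residual degrees of freedom, so the
procedure falls back to internal studentization with a normal reference.
The calibration of this test assumes roughly constant-variance scatter
around the shared line; count noise whose variance grows with peak number is
anti-conservative, which is a property of that noise model rather than of
the procedure.

## Central motif enrichment

Fixed-length windows (2 × 210 bp, matching the average ChIP-seq peak length
the analysis was designed around) are cut around peak centres; windows
overhanging a chromosome edge are excluded and counted. Per window only the
single best-scoring site over both strands is kept — the "best site" mode of
the tool this re-implements — because it makes the positional null exact:
under no positional preference the best site's centre is uniform over the
`L − m + 1` possible positions, so the count inside a central region of
width `w` is binomial with success probability `w/(L−m+1)`. The reported
p-value is the minimum binomial upper tail over the width grid
{20, 40, …, 200}, multiplied by the grid size (Bonferroni) — explicitly
conservative, hence super-uniform under the null, which the test suite
checks over 200 replicates. The comparative multi-motif mode and
log-adjusted p-value refinements of the original tool are not reproduced.

## Distances and dual signatures

X-box–to–peak distances are measured from motif midpoint to the **centre**
of the nearest peak. Motif instances on chromosomes with no peaks get an
infinite distance and by default count in the denominator as "not within";
`exclude_unmatched=True` switches the denominator, since either convention
is defensible and the choice shifts the reported fraction. The dual
signature is pure set algebra over the battery; ids outside the battery are
ignored with a logged count, and the four classes always partition the
battery exactly.

## Single-cell screen and correlation

Counts are normalized per cell to counts-per-10k (no log) before any
statistic: correlation and fold on raw counts conflate sequencing depth with
biology. The enrichment fold is the ratio of class means, target over pooled
non-target cells (an alternative `max` mode compares against the strongest
other class — a specificity screen); the pooled-other mean is floored at a
small epsilon so silent backgrounds give large finite folds that remain
monotone in the target mean. Because the upstream screen's statistic is
undocumented, significance uses a one-sided Wilcoxon rank-sum test on the
per-cell normalized values — robust to the zero-inflation and skew of
single-cell counts — with BH control over the candidate list; a hit needs
fold ≥ 5 **and** q ≤ 0.001. A fold-only mode exists. Detection in a class
means nonzero expression in ≥ 5% of its cells. Correlation profiles are
Pearson R over a cell subset with an NaN sentinel for constant vectors, and
are exactly invariant under per-cell depth rescaling.

## Reporter statistics and the multiplicative model

Pairwise genotype comparisons use a two-tailed two-sample t with an F-test
variance pretest at 0.05 selecting pooled vs Welch variance (mirroring the
spreadsheet F.TEST/T.TEST workflow such data is typically analysed with),
Bonferroni-corrected over all pairs. Regional comparisons use one-tailed
(mutant < control) t tests with BH control over regions.

Fold changes divide per-animal counts by the reference genotype's mean; the
expected combined-mutant fold change under independence is the product of
the two double-mutant means, with first-order error propagation by
**relative-error addition**, `sd_E = E·(s₁/m₁ + s₂/m₂)` — the standard
first-order product rule, with per-animal fold-change SD (not SEM) as the
input spread; a quadrature mode (`√` of summed squared relative errors) and
an SEM-based variant are available via flags. The synergy test is a
one-sample, by default two-sided, t of the triple mutant's per-animal fold
changes against E treated as a **fixed** null value; E's own sampling
uncertainty is reported (`sd_expected`) but deliberately not folded into the
test, matching how the expectation is used as a derived constant. The
`conservative` flag widens the denominator to `√(sem² + sd_E²)` for a
sensitivity check. Type-I calibration therefore holds against the true
expectation (verified at 500 Poisson replicates); against an estimated E the
fixed-E test is anti-conservative by construction, which is exactly what the
conservative mode is for. Zero-variance groups fall back to exact
comparison (p = 1 on equality, a `degenerate` verdict otherwise).

Rescue experiments use the two-sided Fisher exact test on on/off tables
(verified against full hypergeometric enumeration). Behavioral indexes are
the literal assay formulas — response index, quadrant and two-halves
chemotaxis indexes, sector and drop avoidance indexes, dauer fraction and
fold induction — with their range invariants (signed indexes in [−1, 1],
ratio indexes in [0, 1]) property-tested; normality pretests delegate to
the Shapiro–Wilk implementation in scipy.

## The synthetic generator

The generator's defaults encode the emulated study conditions; it exists so
every stage has inputs with machine-readable ground truth.

* **Genome & genes** — six chromosomes at nematode-like lengths (~100 Mb
  total), i.i.d. sequence at GC 0.355, 20,000 non-overlapping gene models on
  a jittered grid (≈5 kb spacing, so TSS windows overlap as they do in a
  compact genome), among them a 163-gene battery split 73/68/13/9. X-box
  consensus instances are written into battery promoters with per-category
  probabilities {core 0.83, subtype 0.27, broad/male 0.58} — chosen so that,
  combined with the binding probabilities below, the dual-signature
  fractions land at the study's reported values under independence.
* **Peaks** — the regulator gets 5035 peaks; each battery gene is bound with
  probability {core 0.75, subtype 0.22, broad/male 0.46} (≈49% overall).
  Designated anchors are re-drawn until the annotation rule assigns them to
  the designated gene, and the regulator's remaining peaks are uniform but
  rejected out of all battery TSS windows — so the truth table of bound
  genes is exact, not approximate. Half of the bound X-box genes get their
  peak centred on the X-box (σ = 200 bp); 20% of non-battery regulator
  peaks get an X-box planted near their centre (σ = 60 bp), giving the
  genome-wide central co-occurrence signal. Background TFs (20, with
  500–4000 peaks each) place peaks uniformly.
* **Single cell** — negative-binomial counts (var = μ + 0.5·μ², a typical
  overdispersion; Poisson mode available) over classes
  {ciliated 1000, other neurons 2000, non-neuronal 2000} — a scaled-down
  stand-in for the tens of thousands of cells in real atlases — with
  lognormal per-cell depth. Planted effects are defined on the normalized
  scale: per-class expected totals over the non-regulator genes are
  rebalanced before the regulator's fold is applied, so a planted fold
  survives counts-per-10k normalization instead of being diluted by the
  compositional shift of the other class-biased genes. The default planted
  fold is 8 — comfortably inside the f ≥ 5 regime the screen targets; a
  fold planted exactly at the threshold sits on a knife edge where sampling
  noise alone decides the fold gate. A gamma latent factor couples the
  regulator and the core gene set within the target class (strength 0.8) to
  give correlation profiling planted positives.
* **Reporter counts** — Poisson (or NB) counts around reference mean 60
  (a whole-animal reporter-positive neuron scale) × genotype multiplier,
  10 animals per group; the triple-mutant multiplier is the product of the
  double-mutant multipliers (0.5 and 0.15) times an interaction coefficient
  — 1 encodes the multiplicative null, values below 1 a synergistic loss.

All randomness flows from the config seed through fixed per-stage child
streams (`default_rng([seed, stage])`), so regeneration is byte-identical
across runs and platforms.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: real genomes are not i.i.d. (repeats,
composition bias inflate chance motif matches); real gene structure has
isoforms, operons and nested genes; real ChIP-seq peaks have width/signal
structure and correlated binding between TFs; real single-cell data has
ambient contamination, doublets and richer cell-type structure; real X-box
matrices are imperfect palindromes with position interdependence. The tests
demonstrate that the *procedures* are correct and calibrated under their
stated models, not that the biological conclusions transfer.

## Problem sizes

The default test suite runs the generator at desk scale (two 3-Mb
chromosomes, 500 genes, 44-gene battery, 200 regulator peaks, ~1,000-cell
matrices); the acceptance script and the end-to-end acceptance tests use the
full study-scale emulation above. Simulation-based calibration checks use
200–500 replicates — enough to bound a 0.05 rejection rate within ±3
binomial standard errors.

## Known limitations

* The X-box merge rule that produced the original coordinate set from four
  overlapping matrices is not reproduced; externally supplied X-box
  coordinate/gene sets are accepted instead, and the built-in scan uses the
  single synthetic consensus matrix.
* Whether the distance-profile denominator includes motif instances on
  peak-free chromosomes is a reporting convention; both modes are provided
  and the default counts them as not-within.
* The one-sample synergy t test's sidedness is configurable (default
  two-sided); with small groups the verdict near p ≈ 0.05 can flip between
  conventions.
* `prioritize_tfs` assumes homoscedastic scatter around the binding line;
  heavy-tailed or count-proportional noise inflates its flag rate.
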