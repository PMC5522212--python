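# Methods

`lncarray` implements the analysis workflow of a two-condition, three-time-point
microarray radioresistance screen: a radioresistant (case) cell line and its
parental (control) line, profiled in triplicate at 0, 2 and 48 h after
irradiation, on an array carrying both lncRNA and mRNA probes. This note
records the models, conventions and numerical choices the package makes, and
what its synthetic-data tests do and do not demonstrate.

## Scale convention

One convention is used everywhere: quantile normalization runs on the linear
intensity scale; fold changes are ratios of linear normalized group means;
t-tests, Pearson correlations and clustering use log2-transformed normalized
values. Linear values are floored at 1.0 intensity unit before the log2
transform so zeros stay finite. Whether the original screen ran its t-test on
linear or log2 values is not knowable; log2 is the default here (the standard
choice for approximately log-normal intensities) with `DEConfig.test_scale`
switching to linear.

## Quantile normalization

Every sample column is replaced rank-wise by the reference distribution — the
vector of row means of the column-sorted matrix. Tied values within a column
receive the mean of the reference quantiles they span; this tie policy is
deterministic and rank-preserving, but when ties exist the output columns are
no longer exactly permutation-identical (a property shared by all standard
implementations of this tie rule). On tie-free data — which continuous
intensities are, almost surely — the sorted vector of every output column is
exactly the reference, and renormalizing reproduces the output up to one
floating-point rounding of the row mean (≈1 ulp; averaging n bitwise-identical
values rounds once).

## Differential expression

Per probe and time point: fold change = mean case intensity / mean control
intensity (linear normalized, means floored at 1.0), folded to
`fc_abs = max(ratio, 1/ratio)` with regulation "up" iff ratio > 1; p-value
from the pooled-variance two-sample Student's t-test (df = n1 + n2 − 2) on
log2 values; a probe is significant iff `fc_abs >= 2` and `p < 0.05`
(`DEConfig`). No multiple-testing correction is applied by default — the
screen this reproduces filtered on raw p — but `bh_adjust=True` switches the
significance call to BH-adjusted p. Degenerate policy: zero pooled variance
with equal means gives p = 1; with unequal means, the smallest positive
float (`MIN_P`), which is also the floor applied before −log10 in the volcano
table. Top-N tables rank by `fc_abs` descending with ties broken by smaller p
then lexicographic probe id, so the output is deterministic.

## Cross-time-point logic and clustering

The three per-time-point significant sets (per RNA type and direction)
intersect exactly; the "common percentage" reported with each Venn is
100 × |triple intersection| / |union of the three sets|. The union
denominator is an inferred convention — raw counts are always emitted
alongside so any other denominator can be recomputed.

Hierarchical clustering uses 1 − Pearson (default) or Euclidean distance and
average (default) or complete linkage via scipy; both linkages are monotone,
so merge heights never decrease. Zero-variance items are dropped with a
warning under the correlation distance. Merge order for tied distances is
deterministic for a fixed input order; dendrograms are exported as Newick
with branch lengths taken from merge-height differences.

## Correlation pairing

Candidate pairs are (significant lncRNA probe) × (significant mRNA probe) at
one time point (`require_de=False` lifts the restriction). The Pearson
coefficient is computed over the n = 6 samples of that time point (3 case +
3 control, log2 normalized) and a pair is retained iff |r| > 0.99 and
p < 0.05, where p is the two-sided tail of t = r·sqrt((n−2)/(1−r²)) on n−2
df. n = 6 is an inferred constant: at df = 4 the closed form
p = 1 − (|r|/2)(3 − r²) reproduces, to printed precision, every (r, p) cell
of the published pair tables, which is strong evidence the original
correlations were computed within a time point; `n` remains configurable.
Zero-variance probes are skipped with a log entry. Direction strings
("up-down" etc.) come from the members' DE regulation calls.

## Target prediction

**cis.** One positional class per pair by precedence: same-strand exonic
overlap → Sense; opposite-strand span overlap → Antisense; lncRNA span
contained in one gene intron without exonic overlap → Intronic; no overlap,
head-to-head orientation (facing ends are both 5' ends) with gap ≤ 1 kb →
Bidirectional, ≤ 5 kb → Divergent; any remaining configuration with an
interval gap ≤ 10 kb → Intergenic (10 k); else none. Distance is 0 for
overlapping loci, otherwise the gap between transcript spans. All intervals
are 0-based half-open; GTF input is shifted on read. The 10 kb window is the
one documented constant of this step; the Bidirectional/Divergent gaps
(1 kb / 5 kb) and the precedence order are package conventions, exposed in
`TargetPredConfig`.

**trans.** Smith–Waterman local alignment of the lncRNA sequence against the
mRNA 3'UTR with +1 match, −1 mismatch, −2 linear gap ('N' scores as
mismatch), implemented in-package with a deterministic traceback: the best
cell is the highest score at the lowest row then lowest column, and diagonal
moves are preferred over up over left. A pair is called
"miRNA sequestration" when the alignment contains a contiguous core segment
with score ≥ 16 and identity ≥ 0.85 (identity = matches / aligned columns,
gap columns included). The gates are evaluated over contiguous windows of the
optimal alignment path rather than its full extent for a structural reason:
under this scoring any positive-score alignment has identity > 1/2, and the
optimum greedily absorbs any extension that raises the score even marginally,
so a perfect shared element flanked by low-identity extension would otherwise
be rejected by its own flanks. The default thresholds are sized to a ~22 nt
miRNA-response-element: a perfect 22-mer scores 22 at identity 1.0, while an
element with 4 scattered mismatches scores 14 and fails the score gate.
Pairs with neither cis nor trans evidence are dropped from the target table
and counted.

## Enrichment

Over-representation of DE mRNA gene lists: hypergeometric upper tail
P(X ≥ k) with the universe equal to all annotated mRNA genes on the array
(not the genome), BH correction across sets, and a top-30 report sorted by
adjusted then raw p then set name. Gene sets load from standard GMT; sets
with no universe member after intersection are omitted.

## Assay arithmetic

Plating efficiency PE = colonies/seeded in the unirradiated control (default
seeding 300/600/900/1200 cells at 0/2/4/6 Gy; colonies of > 50 cells count).
Survival fraction SF = (colonies/seeded)/PE. The optional linear-quadratic
fit solves min ‖ln SF + αD + βD²‖² with α, β ≥ 0 by non-negative least
squares; SF ≤ 0 records are excluded from the log-scale fit with a warning,
and the fit is refused with fewer than two distinct positive doses. Total
apoptosis = Annexin V+/PI− (early) + Annexin V+/PI+ (late) quadrant
fractions; a record whose four quadrants sum beyond 1 (tolerance 1e−6) is
invalid. qRT-PCR relative expression = 2^−ΔCT with ΔCT = mean CT(target) −
mean CT(reference), reference β-actin. Group comparisons reuse the same
Student's t machinery as the expression screen.

## Synthetic-study generator

No accession was deposited for the original arrays, so the generator is the
test bed. It emulates the design exactly — 2 conditions × 3 time points ×
3 replicates — with a log-normal intensity model: log2 intensity = per-probe
baseline ~ Uniform(4, 16) (a realistic array intensity span) + condition
effects + Normal(0, σ = 0.25) probe noise, exported linear. Planted DE
probes receive ±δ (default 2 log2) in case samples at their time point.

**Co-expressed pairs.** A pair construction must satisfy three competing
demands at n = 6: pass |r| > 0.99, have both members clear the FC ≥ 2 &
p < 0.05 screen, and use the fixed probe noise σ = 0.25. A pure shared
latent factor large enough for the r filter (latent/noise ≳ 20) destroys the
members' own DE detectability, because the latent inflates within-group
variance. The generator therefore gives pair members a strong condition
shift (±6 log2 per member, i.e. FC 64 — within the top-table fold-change
range such screens report) plus a modest shared per-sample latent term
(sd 1.5, sign-flipped for anti-correlated pairs) on one shared baseline.
Measured on this construction: ~90% of planted pairs pass the filter on the
generated data and ~96% of members are called DE. The pass rate grows
monotonically with the latent/noise ratio.

**What normalization does to planted correlations.** Quantile normalization
is a rank-based per-column transform; at the knife-edge |r| > 0.99 threshold
it injects warping and rank-quantization noise of the same order as the
probe noise, so roughly half of the planted pairs survive the
post-normalization filter (the run report shows the realized counts). This
is a genuine property of pushing near-perfect correlations through rank
normalization, not a defect of either stage; the generator's pass-rate
contract is therefore stated on the data it emits.

**Geometry and sequences.** mRNA genes sit in tandem on one chromosome
(50 kb spacing, three exons, a 300 bp terminal 3'UTR); default lncRNAs sit
isolated on a second chromosome, > 10 kb from any neighbour. Each cis pair's
lncRNA is placed to realize its intended class by construction (exon copy,
antisense overlap, intron interior, head-to-head at 0.5/3 kb, same-strand
8 kb gap). Trans pairs share an exact random 22-mer copied into both the
lncRNA sequence and the partner 3'UTR; sequences are otherwise i.i.d.
uniform nucleotides. Sequence content is independent of genomic coordinates
— a deliberate simplification. Assay records draw colonies binomially from
SF × PE × seeded, apoptosis quadrants from a Dirichlet around the true
means, CT values from Normals; `noise=0` returns exact expectations.

All randomness flows from one seed through named `SeedSequence` streams;
identical seeds give byte-identical study files. A missing seed is an error.

**What passing these tests shows — and does not.** Recovery of planted
signals shows the statistics and predictors are implemented correctly at the
stated effect sizes and noise; it does not validate the biological premises
(that r > 0.99 co-expression implies regulation, that a shared 22-mer
implies miRNA sequestration), does not model probe-level artifacts (dye
bias, spatial effects, saturation), and cannot reproduce the published
study-level counts, which would require the undeposited raw arrays.

## Problem sizes

The default test and acceptance runs use studies of 200–2000 probes
(5 seeds for the DE recovery experiment at 2000 probes), 10⁴ random
geometries for the cis oracle sweep, 200 random sequence pairs (length
≤ 50 nt) for the alignment oracle plus 60 planted-element draws at realistic
lengths (400/300 nt), and 10⁴ probe pairs for the correlation null — sizes
at which every stochastic check is stable across seeds while the whole suite
runs in well under a minute.

## Known limitations

- The normalization variant of the original GUI software is unknowable;
  plain quantile normalization is what is claimed and implemented.
- Bidirectional/Divergent definitions, trans alignment scoring and cutoffs,
  the Venn percentage denominator, and the correlation sample size are
  package conventions (flagged above), not published constants.
- The enrichment module supplies the statistic only; pathway content
  (KEGG/Reactome/...) must be provided by the user as GMT.
- Probe→gene mapping is allowed to be many-to-one; set logic operates on
  probe ids, gene-level collapsing happens only at enrichment.
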