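# Methods

## Data model

All stages operate on a single container: a sparse cells × genes integer
count matrix with a gene table (symbol, host/viral origin, chromosome,
arm, 0-based start, optional functional and viral temporal class) and a
cell table (sample, infected/control status, optional assigned type and
cluster). Host and viral genes share one matrix, mirroring alignment
against a human reference extended with the viral genome as a separate
contig; viral genes sit on the reserved contig `VV`. Coordinates are
0-based half-open and strand is ignored — counts are gene-level. On disk
the dataset is Matrix-Market coordinate (1-based indices, orientation
declared in a header comment) plus TSV sidecars; infection status is an
explicit column, with the convention that sample names ending in "v"
denote infected samples honoured as a fallback parser. Symbol matching
is case-insensitive exact-string everywhere; no alias resolution.

## Synthetic experiment generator

The generator emulates the statistical structure the analysis assumes,
not the sequencing process. Per cell:

* library size L ~ round(LogNormal(μ=log 5000, σ=0.35)), floored at 1 —
  a typical droplet-era depth;
* cell type drawn from the sample's type-proportion map. The default
  experiment is five cultures (two glioblastoma-derived, one gliosis,
  one normal brain, one immortalized line), each measured as a control
  and an infected sample, with ~8 types (PN, CL, UN, Mgl, Fib, Prc, OC,
  U87) distributed so malignant subtypes appear only in their tumour
  culture;
* for infected samples, a viral fraction v ~ Beta with type-level mean
  (defaults span 0.02–0.30 in the order PN > Mgl > UN > Fib > U87 >
  Prc > OC > CL) and concentration 50 — enough spread to produce
  overlapping violin-shaped distributions without modelling infection
  kinetics; control samples have v = 0 exactly;
* round(v·L) counts are allocated multinomially over viral-gene weights
  (Gamma(1.5, 1) draws, "early"-class genes up-weighted by
  `early_weight`, default 3), and the remaining counts multinomially
  over type/status-specific host gene rates.

Multinomial allocation of a fixed library (rather than independent
Poisson counts) guarantees that the per-cell fraction statistic's
denominator is exact and that v is directly plantable. Host base rates
are Gamma(shape 1.5, scale 1) — right-skewed per-gene abundances
spanning roughly two orders of magnitude. Host genes are laid out in
contiguous blocks of `genes_per_arm` (default 50) cycling through arms
1p…22q, giving the CNV screen positional structure.

Structured gene sets, all drawn without replacement from the upper half
of base rates (curated markers and reported signature genes are
detectably expressed genes; planting signal in near-zero-count genes
would test the depth of the sequencing, not the method):

* **markers** — per type, `markers_per_type` genes up-weighted
  `marker_fold`-fold (default 8) in their own type;
* **planted positive/negative genes** — rates multiplied by
  exp(±`planted_effect`·(μ_type − μ̄)), with μ_type the type's configured
  viral mean and μ̄ the across-type mean. Being a type-level property,
  this coupling is present in control cells too, so it is recoverable
  both post- and pre-infection;
* **infected-only planted genes** — the same multiplier applied only in
  infected cells, producing post-infection-only signature genes;
* **induced genes** — rates × `induced_fold` in infected cells of every
  type, the target of the differential-expression stage;
* **CNV events** — every gene on the named arm in the named type
  multiplied by the event's fold change (default experiment: 0.5× on
  19p/19q/22q in PN and UN, 1.5× on 7p/7q and 0.5× on 15p in CL),
  applied in both statuses since dosage is genomic.

All draws come from one generator stream seeded by a single master seed,
in a documented fixed order with new draws appended last, so adding a
config field never reshuffles earlier draws and identical configs give
byte-identical datasets. MOI (0.1 PFU/cell in the emulated design) is
recorded as metadata only.

What the generator does **not** emulate: read-level noise, UMI
collapsing, ambient RNA, doublets, batch effects, infection
time-courses, or per-cell transcriptional bursting beyond multinomial
sampling. Passing tests therefore demonstrate that the analysis recovers
the statistical structure it targets at realistic depths and sample
sizes — not robustness to the full noise anatomy of real droplet data.

## Normalization

Two denominators are deliberate, not interchangeable:

* **Host-gene analyses against viral load** (correlation signatures,
  differential expression) use log1p of counts-per-10k of **host counts
  only**. With a whole-library denominator, every host gene's share is
  scaled by (1 − v), so all host genes would inherit a spurious −log(1−v)
  coupling to viral load; correlations would then measure composition,
  not regulation, and the null calibration below could not hold.
* **Viral-gene levels and annotation scoring** use the ordinary
  whole-transcriptome counts-per-10k: a viral transcript is treated like
  any other transcript (the alternative — share of viral counts — is not
  the default), and marker scoring follows the standard single-cell
  convention.

## Stage-by-stage notes

**Viral load and ranking.** Fraction = viral counts / total counts per
cell; zero-total cells are dropped with a logged count. Groups are
cell-type × status; groups under 20 cells are flagged low-confidence.
Ranking uses Welch (unequal-variance) two-sample t-tests on raw per-cell
fractions — groups differ strongly in variance, and the fraction scale
keeps the statistic interpretable; a log-scale option exists but is off
by default. All pairwise p-values are Holm–Bonferroni adjusted by the
step-down rule adj_(i) = max_{j≤i} min(1, (m−j+1)p_(j)). The ordering
string joins adjacent groups with `>`, upgraded to `>>` where that
adjacent pair is significant at α (default 0.01) — an operationalization
of the field's informal notation. Control groups are summarized (to
verify they carry no viral reads) but excluded from ranking. Pairs of
zero-variance groups get p = 1 with a warning rather than an undefined
statistic.

**Annotation.** Marker weights are 1/k for a marker claimed by k types'
positive sets (specificity weighting, in the spirit of marker-database
annotators; it is "ScType-like", not a reproduction). Expression is
CP10K + log1p, then z-scored per gene across cells (zero-variance genes
get z = 0); a cell's score for a type is Σ w·z over positive markers
minus Σ w·z over negative markers; assignment is argmax, "unclassified"
if the best score is ≤ 0, ties broken lexicographically with a logged
count. Cluster-level labels sum member-cell scores and require the best
total to reach n/4. Glioblastoma subtyping is the same scorer with a
subtype marker table — no separate code path. Note that removing a type
from the database leaves other types' scores unchanged only when marker
sets are disjoint; shared markers re-weight.

**CNV screen.** Per group, host-gene counts are summed (pseudobulk) and
scaled to CPM; the per-gene statistic is log2((CPM_t + 1)/(CPM_r + 1))
centred by the genome-wide median (so a balanced genome sits at 0 even
when a large event shifts the mean). Within each arm, genes are ordered
by start and smoothed with a centred running median (window 51 genes,
truncated at arm edges; min 10 genes per arm) — medians absorb
single-gene outliers that a mean-filter would smear into a false call.
The arm score is the mean smoothed value; |score| ≥ 0.3 (≈1.23× dosage)
calls a gain/loss, a threshold that detects a clonal single-copy loss
(ideal −1) with wide margin while sitting far above pseudobulk noise at
≥20 cells/group. This is a dosage screen at arm resolution — no per-cell
states, allele frequencies, or sub-arm segmentation — sufficient to
classify groups as carrying/lacking arm events against a non-malignant
reference.

**Correlation signatures.** Correlation is computed across cell-type
group means, not across single cells: the question is which genes track
*type-level* susceptibility, and group means suppress the dominant
within-type single-cell noise. Genes constant across groups are excluded
(not scored 0). Signatures take genes with R > 0.5 (descending, ties by
gene id) and R < −0.5 (ascending), truncated to 300 per direction —
threshold first, then truncation. The pre-infection variant correlates
control-group means against the *matched infected groups'* viral means
via an explicit type-matching map; at least 3 matched pairs are
required. Shared signatures are order-preserving intersections (post-R
order).

Null calibration: for n exchangeable groups the null Pearson tail is
P(|R| > r) = I_{1−r²}((n−2)/2, 1/2); for n = 6 and r = 0.5 this is
0.3125. With no planted coupling and equal viral means across types the
measured selected-gene fraction matches this value within Monte-Carlo
error. The equal-means condition matters: with *unequal* type-level
viral loads, host libraries shrink by (1 − v) in high-load types and the
log1p transform's Jensen bias then induces a small shared trend across
all genes, inflating the tail beyond the independent-gene null. That
shared-background behaviour is visible in the default experiment, where
the negative signature fills with genuinely load-coupled background
(CNV arms, markers of low-susceptibility types) on top of the planted
genes.

**Differential expression.** Per type with ≥20 cells in each arm:
two-sided Wilcoxon rank-sum (infected vs control) on the transformed
host expression, Benjamini–Hochberg within type, log2 fold change from
group means on the transformed scale with a 1e-9 pseudocount. Genes
identical in both arms get p = 1. "Commonly upregulated" ranks genes by
the number of types with q < 0.05 and positive fold change (ties by mean
fold change, then gene id), reporting the top 50. A negative-binomial
count model is out of scope; the rank test is the common single-cell
default and is what the null-calibration guarantee is stated for.

**Viral genes.** Each viral gene's group-mean level (whole-library
CP10K, log1p) is correlated with group mean viral fraction; the
no-negative check asserts no gene falls below R = −0.5 — under
proportional multinomial allocation every viral gene's level rises with
total load, so a negative correlate would indicate annotation or
normalization problems. Temporal tallies count Early / Late / EarlyLate
/ Unknown, with n_known the sum of the first three. The packaged
reference table (20 virus-encoded transcripts, coefficients 0.56–0.68,
9 early and 2 late among 13 with known stage) is integrity-checked by
row count and coefficient checksum; numeric gene identifiers in it are
kept as strings with Unknown class. Whether early-class genes correlate
*more* tightly than late ones depends on the data regime: with sparse
per-gene coverage their 3× abundance advantage reduces sampling noise
and raises their mean R; at high coverage the log transform compresses
abundant genes harder and the ordering can invert. The test suite pins
the sparse regime.

## Pipeline

Stages run in a fixed order (load/generate → annotate → viral load →
ranking → CNV → signatures → differential expression → viral genes);
every stage contributes output or an explicit skip reason. The report is
JSON with per-stage tables as TSVs; the only non-deterministic field is
an isolated timestamp. CLI exit codes: 0 success, 2 configuration error,
3 data format error, 4 stage failure. The synthetic path writes the
generator's true types into the dataset's assigned-type column so every
downstream command runs out of the box.

## Problem sizes used in verification

Recovery and calibration checks run at sizes chosen to make the
statistical claims decisive while staying desk-scale: susceptibility
ranking at 500 cells/type × 8 types × 20 replicates; signature recovery
at 6 single-type groups × 400 cells with 20+20 planted genes; the
correlation null at 6 × 150 cells × 400 host genes × 100 replicates; the
CNV screen at 200+200 cells, 600 genes over 12 arms, 20 alternative and
20 null replicates; annotation at 1,500 cells × 8 types; the DE null at
150+150 cells × 300 genes × 50 replicates. At these sizes every expected
effect is many standard errors wide, so failures indicate defects rather
than noise.

## Known limitations

* Group-level correlation cannot separate genes tracking viral load from
  genes tracking any covariate aligned with the type ordering (e.g., an
  arm loss specific to the most susceptible type) — a real confound the
  default experiment reproduces deliberately.
* The CNV screen reports arm-level dosage only and assumes the reference
  group is genomically balanced.
* The annotation scorer assumes markers are informative at the z-score
  level in the analysed mix; it does not transfer labels from atlases or
  detect novel types (cells fitting nothing are "unclassified").
* Beta parameters of the per-cell viral fraction are calibration knobs,
  not estimates from data; no published per-cell load distributions were
  available to fit them.
* The reference viral-gene table's correlation values cannot be
  reproduced from data here (the underlying dataset is not public); the
  package reproduces its tallies and uses it as a worked example.
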