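# Methods

This note documents the models, defaults and numerical choices behind
`gravirebound`, and what the synthetic validation does and does not
demonstrate about real data.

## Kinetic model and the synthetic study

Per-gene mRNA dynamics follow the standard two-stage model: transcription
at rate α (molecules/min) produces unspliced precursor u, splicing at rate
β (1/min) converts it to spliced mRNA s, which degrades at rate γ (1/min).
The pre-exposure state is the steady state (u = α/β, s = α/γ). At onset,
one rate steps by a fold factor; an optional reversion at a rebound time
(default 5 min) restores it. The solution is piecewise closed-form and
continuous in t; the coefficient `(e^{−βτ} − e^{−γτ})/(γ − β)` is evaluated
through the stable form `τ e^{−βτ} φ((γ−β)τ)` with `φ(x) = (1 − e^{−x})/x`
(series expansion below |x| = 1e−6), so β = γ is the analytic limit rather
than a special-cased division. Accuracy against numeric ODE integration is
better than 1e−6 relative error over a broad parameter grid (measured in
the test suite; observed ~1e−9).

Gene classes map to perturbations:

| class | perturbation | interpretation |
|---|---|---|
| null | none | steady state throughout |
| transcriptional_up | α × 3, sustained | induced transcription |
| post_transcriptional_down | γ × 2, sustained | degradation of mature mRNA only |
| rebound_up_then_down | α × 3, reverts at 5 min | early induction, rebound |
| rebound_down_then_up | α / 3, reverts at 5 min | early repression, rebound |

Default rates: β ~ LogNormal(ln 1.0, 0.2) and γ ~ LogNormal(ln 0.5, 0.2)
per gene. These deliberately describe the fast-turnover transcript pool —
splicing half-life ≈ 0.7 min, mRNA half-life ≈ 1.4 min — because
minute-scale differential expression is only observable for transcripts
with fast kinetics; genes with hour-scale half-lives would contribute
nothing to a 3-minute contrast. Baseline spliced abundance is
LogNormal(ln 200, 1.0) in count units.

Counts are negative binomial around the kinetic means (variance
m + d·m²), dispersion d = 0.05 with per-gene LogNormal(0, 0.3) jitter.
The unspliced mean is multiplied by a polyA capture factor of 0.15:
polyA-enriched libraries deplete intron-bearing precursors, and this single
multiplicative factor reproduces the qualitative consequence that many
genes are quantifiable in the spliced but not the unspliced fraction. The
ambiguous layer is 0.1 of the spliced mean. The design is 3 conditions
(Ctrl = 0 min, 3 min, 15 min of exposure) × 4 replicates, with a 5%
log-normal per-sample depth jitter.

Transcript-level counts (for PCCR) draw a per-condition gene total from
LogNormal(ln 20000, 0.7), floored at 500, split across isoforms at
condition-specific coding fractions (Ctrl fraction uniform in [0.75, 0.95];
shifted genes move ±5 percent points at 3 min and recover at 15 min) with
per-replicate Poisson counting noise. Between-replicate *biological*
isoform-usage variability is deliberately not modelled: the one-percent-
point classification threshold is then meaningful at its counting-noise
floor. Consequently the measured ≥95% sensitivity/specificity says nothing
about datasets where isoform usage itself varies across replicates — there
the threshold would misclassify far more genes.

The SAM fixture writes paired-end records with known splice status by
construction: exact-junction CIGARs (aM nN bM matching an annotated intron
at both edges), reads wholly inside introns shared by all isoforms, and
exonic non-junction reads (ambiguous in multi-isoform genes, spliced by
definition in intron-less genes). Secondary-flagged duplicates are
sprinkled in to verify flag filtering.

What the generator does not emulate: positional read coverage biases,
sequencing errors, multimapping, fragment-length distributions, isoform-
level expression correlation structures, and any genome-scale correlation
between neighbouring genes. Passing recovery tests therefore demonstrates
the correctness and calibration of the statistical machinery on data
matching its assumptions, not robustness to alignment artefacts.

## Read classification

A pair is assigned to the unique gene whose span contains every aligned
block; overlapping genes or unknown chromosomes yield unassigned (counted
in the summary). Classification rules, in order of precedence:

1. **unspliced** — any aligned base of either mate overlaps a position
   intronic in *every* isoform of the gene;
2. **spliced** — any mate's alignment gaps all match introns of one
   isoform exactly at both boundaries, with the mate's blocks inside that
   isoform's exons;
3. **spliced** — the gene has no introns at all (such genes enter the
   spliced pool immediately upon transcription, by definition);
4. **ambiguous** otherwise (including partial-boundary gaps — a
   conservative choice).

Unspliced evidence trumps a spliced mate because a fragment touching a
universally intronic position cannot derive from a mature transcript.
Secondary, supplementary, duplicate and unmapped records are excluded so
each fragment votes once; orphaned mates are classified alone. Strandedness
is ignored (interval logic does not need it). On fixtures the classifier
agrees with truth for 100% of constructed unambiguous pairs.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference,
computed **once from the total layer** (spliced + unspliced + ambiguous)
and reused for every layer, so layer comparisons are not distorted by
layer-specific normalization. A known consequence, measured here: under
strongly asymmetric regulation (a quarter of the transcriptome down ~45%),
the median ratio shifts and absorbs ~10% of the true effect. This is
intrinsic to median-of-ratios, shared by the standard implementations, and
accepted as part of the method.

Per-gene dispersion is method-of-moments on normalized counts (pooled
within-condition residual variance), shrunk 50/50 toward a fitted
a₀ + a₁/mean trend (non-negative least squares), floored at 1e−8. The
blend is **arithmetic**, not geometric: the few-replicate MoM estimator is
heavily right-skewed, and a log-space blend pulls toward its median,
deflating dispersions and inflating the Wald statistic (observed null
type-I ~7%; arithmetic blending restores ~5.5%).

The test is a two-sided Wald contrast of group means of normalized counts:
lfc = log2 q̂_A − log2 q̂_B, z = (ln q̂_A − ln q̂_B)/se with
se² = (1/q̂_A + d)/n_A + (1/q̂_B + d)/n_B from the NB variance model. No
fold-change shrinkage is applied — downstream calls are sign + FDR based.
Working entirely on normalized counts makes two invariants hold bit-exactly
(and tested as such): swapping groups negates lfc and z and preserves p,
and rescaling any sample together with its size factor changes nothing.
Normalized matrices are forced C-contiguous so floating-point reduction
order cannot depend on the data frame's internal layout.

Observability ("adjusted p defined") is decided by independent filtering:
the mean-normalized-count threshold is chosen from a quantile grid (floored
at 5) to maximise discoveries at α = 0.05, per family. This is what leaves
weakly covered genes with an NA adjusted p — most visibly in the
count-poor unspliced layer, where the chosen threshold is routinely 5–6×
higher than in the spliced layer, reproducing the observation that many
genes are quantifiable in only one fraction. BH adjustment is the step-up
procedure with monotonicity enforcement; NaN p-values propagate and do not
count toward m.

Measured calibration and power at the study conditions (4v4, d ≈ 0.05):
null fraction of p < 0.05 ≈ 0.055; sensitivity ≥ 0.8 for a sustained
twofold change on the total layer.

## Rebound analysis

Calls: up ⇔ fdr < 0.05 ∧ lfc > 0; down ⇔ fdr < 0.05 ∧ lfc < 0; ns
otherwise; genes without an fdr are unobserved; lfc exactly 0 ties to ns
(direction undefined). Transition tables partition the genes observable in
both contrasts. The refined 15-min categories distinguish, for a gene down
at 3 min: inner grey (flat between 3 and 15 min, still below control),
outer grey (rising but still below control), continued (still falling),
recovered (ns vs control), overshoot (above control) — with mirrored
categories for genes up at 3 min and late_up/late_down for second-phase
genes. The mapping is total and deterministic; combinations the simple
narrative does not anticipate (e.g. down at 3, down between 3 and 15, yet
ns vs control) resolve by the final state against control.

The rebound correlation is Spearman (average ranks on ties) between the
lfc vectors of adjacent contrasts. The default universe is all genes
observable in both contrasts; a DEG-restricted universe (genes significant
in at least one of the two) is provided and is the better measure of the
rebound *of the responsive pool*: with a 25% responsive mixture the
all-observable ρ has a structural ceiling of about −0.78 regardless of
effect size, because the null majority contributes exactly the −0.5 rank
correlation induced by the shared middle time point, while the DEG
universe reaches ρ ≈ −0.9 under strong rebound. Both are reported.
Cross-dataset coherence restricts to genes detected in all datasets,
counts per-step up/ns/down flows, reports P(same direction at k+1 |
non-ns at k) per step, and extracts the subset differentially expressed in
at least 3 datasets.

## Genomic distribution

Expected DEGs per region = detected genes in the region × global DEG
fraction; expected upregulated = region DEGs × global up fraction among
up+down. Both conservation identities hold exactly by construction. Each
region gets two two-sided Fisher tests — DEG enrichment (deg/non-deg ×
region/rest) and up/down skew (up/down × region/rest) — BH-adjusted within
each family, with the direction of deviation annotated separately from the
p-value (excess and deficit are both reportable). Regions without detected
genes are dropped before adjustment to avoid untestable rows. The
DU-exon analogue replaces genes by differentially used exons and the up
fraction by the global increased:decreased usage ratio. Agreement between
expected and actual vectors is summarised by Spearman ρ (undefined on
constant vectors, flagged).

## Differential exon usage

Flattening splits each gene's exonic territory at every isoform's exon
boundaries into disjoint bins with recorded parent-transcript sets. Bin
counting adds a pair to every bin one of its blocks overlaps (deterministic
whole-pair counting; fractional assignment was rejected for determinism).
The usage statistic contrasts ln(bin/remainder-of-gene) of normalized
counts between conditions with NB delta-method variances (dispersions
estimated separately for bin and remainder matrices); usage_lfc > 0 means
increased usage in the first condition. Because usage is a within-gene
ratio, a uniform expression change of a condition cancels exactly — the
statistic is invariant to doubling all counts of a group (tested to
1e−12). Genes with a single bin are skipped. Gene-level q: Šidák
aggregation of the minimum bin p (1 − (1 − p_min)^k), BH across genes.
Significant bins map to the union of their parent transcripts, one
instance per transcript per usage direction.

## Biotypes and PCCR

DU transcripts are tallied by Ensembl biotype (processed transcripts =
ORF-lacking; nonsense-mediated decay = NMD) and direction. The DEG
association test compares, per biotype, the up/down split of DEGs hosting
a DU transcript of that biotype against DEGs hosting DU transcripts of
other biotypes (gene–biotype pairs by default, so a gene with two DU
biotypes legitimately appears on both sides; an exclusive-gene mode is
provided). Groups under 20 DEGs are excluded before adjustment — this
automatically removes the typically tiny lncRNA group. Expected
downregulated counts are group size × the global down fraction.

PCCR per gene and condition is coding/(coding + noncoding) with noncoding
= retained_intron + orf_lacking + nmd. lncRNA sits in neither pool by
default (the strict formula); `include_lncrna` moves it into the noncoding
pool for the broader reading — both definitions are first-class because
the two conventions coexist in practice. Classification uses strict
inequality at 0.01 with a 1e−12 guard so an exact one-percent-point delta
is constant under any float representation. The ratio is invariant to
per-condition rescaling (depth robustness) and classification is
antisymmetric under swapping the two conditions, both tested exactly.
Association with DE is a per-class × per-layer Fisher test of the up/down
split against all other genes, with the expected split from the layer-wide
DEG background and stars at fdr < 0.05 / < 0.01.

## Enrichment

ORA: two-sided Fisher on set membership after intersecting sets with the
detected universe; p depends only on the four margins. Preranked: genes
ranked by decreasing statistic (the Wald z), ties broken by gene id;
weighted running sum with weight |stat| (exponent 1) for hits and a
uniform decrement for misses; the enrichment score is the extreme of
largest magnitude (first occurrence on ties), always in [−1, 1]. The null
permutes which genes carry the set label: when C(N, K) ≤ n_perm every
subset is enumerated and p is exact; otherwise n_perm seeded draws with
the +1 correction, giving a permutation floor of 1/(n_perm + 1) — very
small p-values are therefore not resolvable, a documented limitation of
the simple permutation null. p is the two-sided fraction of null |ES| at
least as large as observed; NES divides ES by the mean |null ES| of the
same sign (a sign-conditional convention; other tools normalise
differently, so NES values are comparable within a run, not across tools).
Sets larger than 400 genes are excluded before testing. The packaged
55-gene cytoskeletal–nuclear mechanical axis GMT expands the named gene
families (lamins, cytoskeletal actins and tubulins, LINC components,
nucleoporins and NPC-associated factors) to standard HGNC symbols; exact
membership of the open families is a reconstruction, as flagged in the
file.

## Pipeline

A YAML config drives the stages; validation runs before any compute and
reports every problem at once. All outputs are plain TSV/JSON under the
run directory, listed in a manifest with per-file SHA-256 and a parameter
hash; nothing timestamped, so a rerun with the same seed is byte-identical
(asserted in the tests). The demo generates the full synthetic study and
runs every stage in a couple of seconds at its default size of 1,200 genes
— sizes chosen so the complete validation suite exercises every stage many
times while staying interactive.

## Known limitations

* The DE stage is a calibrated stand-in with DESeq2 semantics (shared size
  factors, observability via independent filtering, Wald calls), not a
  numerical replica: no Cox–Reid dispersion adjustment, no outlier
  replacement, no lfc shrinkage.
* The mechanism-discrimination recovery rate for a twofold degradation
  step at 3 minutes plateaus near 75–80% under the default study
  conditions: the step expresses only ~53% of its asymptotic effect by
  3 min, shared median-of-ratios normalization absorbs ~10% of it under
  such widespread downregulation, and 4v4 replicate power at dispersion
  0.05 bounds the rest. This is a property of the design, not the code;
  the corresponding check in the test suite documents the measured value.
* The permutation-null enrichment cannot produce p below the permutation
  floor; redundancy collapse across overlapping gene sets is out of scope.
* Cytoband assignment uses the strand-aware 5′ end of each gene; genes
  spanning band boundaries are assigned to the band containing that single
  position.
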