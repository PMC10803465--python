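# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the design choices behind `homoeobias`.

## Study design and data model

The analysis compares five groups: two diploid parents (PK, PT), reciprocal
F1 hybrids (F1K, F1T; the letter names the maternal parent) and a natural
allotetraploid (ALLO), with 3/3/3/2/3 biological replicates by default.
Parents contribute one count column per replicate over their own reference
genes. Hybrid and allotetraploid libraries are homoeolog-resolved upstream
(read sorting is out of scope), so each replicate contributes two columns —
one per subgenome — over the corresponding parental reference genes. The
unit of analysis is the *single-copy ortholog pair*: an orthogroup with
exactly one gene in each parental species.

Because a hybrid replicate's two columns partition one sequencing library,
the package re-assembles replicate-level libraries by summing the two
subgenome columns (the gene sets are disjoint) wherever whole-library
quantities are needed: TPM normalization, pair-total differential
expression, and MDS QC. All inference runs on *pair-level* matrices (pair
totals, or per-side columns), never on the raw gene-level matrix, because
gene-level rows are species-specific and would make parent and hybrid
columns incomparable.

## Filtering

1. **Single-copy filter** — orthogroups with exactly one member per parent
   become gene pairs; everything else is dropped.
2. **Co-expression filter** — a pair is retained when its group-level TPM
   strictly exceeds the threshold in *all five* groups. Group level =
   arithmetic mean over replicates; for hybrid groups the pair's expression
   is the sum of its two homoeolog TPMs by default (`filter_mode="sum"`;
   `either`/`both` are available). TPM uses the standard rate
   normalization, count/length scaled to 1e6 per library; hybrid TPMs are
   normalized over the replicate's whole (re-assembled) library. The
   canonical thresholds 0.0 / 0.5 / 1.0 are always swept and reported; 0.5
   is the default analysis set. Retention is monotone non-increasing in the
   threshold by construction.

The comparison is strict (`>`), so a pair sitting exactly at the threshold
is dropped, and the mean-over-replicates choice (rather than per-replicate
thresholding) matches the use of mean CPM elsewhere in the pipeline.

## Normalization and differential expression

**TMM.** Scaling factors use the trimmed mean of M-values with the
canonical constants: 30% two-sided trim on M, 5% on A, precision
weighting, reference column chosen as the sample whose upper-quartile
count proportion is closest to the mean of that proportion. Factors are
re-centred to geometric mean 1. Identical columns and pure depth changes
yield factors of exactly 1; a sample sharing no positive genes with the
reference is an error naming the sample. The implementation is verified
against an independently coded step-by-step reference (1e-10) and against
edgeR's `calcNormFactors` (1e-9).

**Fisher-exact DEG.** The named test is the two-sided Fisher exact test on
a per-gene 2x2 table. Replicates enter by pooling: each sample is rescaled
to the mean TMM-effective library size (count x N̄ / (N_s·f_s)), counts are
summed within each group and rounded, and the table
`[[g_A, L_A−g_A], [g_B, L_B−g_B]]` is tested with L_X = |X|·N̄. This keeps
the count nature required by an exact test while honouring normalization,
and makes the group-swap symmetry exact (p invariant, log2FC negated).
log2FC = log2((meanCPM_A + c)/(meanCPM_B + c)) with pseudo-count c = 0.5
CPM. Calls are UP/DOWN at |log2FC| > 1 and BH FDR < 0.05, both strict, FDR
adjusted per contrast. Seven contrasts are computed: PKvsPT and each focal
group versus each parent (focal-over-parent orientation; the parental
contrast is K-over-T).

A pooled exact test ignores biological replicate variance, so its
p-values are anti-conservative under NB overdispersion; the BH step and
the effect-size gates (|log2FC| > 1, |magnitude| > 1) are what keep false
calls controlled. In a fully null family this suffices (see the null
acceptance run); in families with substantial true signal the BH threshold
relaxes and weakly-expressed null pairs can pass, which is the expected
behaviour of FDR control (it bounds the false fraction of *calls*, not the
error rate per null pair). Users wanting per-replicate dispersion
modelling should treat the DEG stage as exchangeable with an edgeR-style
NB test; the classification layers above it are agnostic to how the three
calls were produced.

**BH adjustment** is the step-up procedure computed directly
(`adj(p_(i)) = min_{j≥i} m·p_(j)/j`, capped at 1), exact against a
reference implementation and cross-checked against
`scipy.stats.false_discovery_control`.

**MDS QC** uses the leading-logFC convention: the distance between two
samples is the root-mean-square of their `n_top = 500` largest absolute
log2 differences of log2(CPM + 2), followed by classical (Torgerson)
multidimensional scaling. QC only; nothing downstream depends on it.

## ELD classification

The three trinary calls (focal/PK, focal/PT, PK/PT) index a fixed decision
table over all 27 patterns:

- focal not different from either parent → **No Change** (this takes
  precedence over the parental contrast);
- parents differ and the focal matches the higher/lower parent →
  dominance toward that parent (II/XI T-dominance, IV/IX K-dominance);
- focal beyond both parents → transgressive up (V, VI, VIII) or down
  (III, VII, X);
- focal between two differing parents → additivity (I, XII).

Twelve patterns fit none of the above: six where the focal differs from
exactly one parent although the parents do not differ, and six internally
contradictory ones (e.g. focal above the higher parent yet below the
lower). These are labelled **AMBIGUOUS** and reported separately rather
than silently folded away; `ambiguous_mode="fold_into_nc"` merges them
into No Change for users who prefer the permissive convention. The table
is total, single-valued, and symmetric under exchanging the parents
(swapping the two focal calls and inverting the parental call maps
II↔IV, XI↔IX, I↔XII, III↔X, V↔VIII and fixes VI, VII, No Change,
AMBIGUOUS) — verified exhaustively.

Categories collapse to six labels (ADD, T_DOM, K_DOM, TUR, TDR, NC);
transitions between F1K and ALLO are cross-tabulated with marginals equal
to each group's category counts.

## HEB detection

Per focal group, mean CPMs are computed over the focal K- and T-side
columns and the parental columns of a pair-level side matrix with its own
TMM factors. The focal and parental log2 ratios share the pseudo-count
(0.5 CPM), so the magnitude equals their difference *exactly* and also
equals the log2 ratio-of-ratios computed directly — an identity asserted
to 1e-12. The significance test is a two-sided Fisher exact test on the
2x2 table of rounded mean CPMs `[[focal_T, focal_K], [parent_T,
parent_K]]`; rounding is needed because an exact test requires integers,
while the magnitude itself uses unrounded means. FDR families are per
focal group. Calls: T_BIAS iff magnitude > 1 ∧ p < 0.05 ∧ FDR < 0.05;
K_BIAS mirrored; otherwise NON_BIAS. Relabelling the subgenomes negates
every ratio and magnitude, leaves p-values unchanged and swaps the calls.

Distribution summaries per group report mean, median, kurtosis and a
two-sided one-sample t-test against 0, BH-adjusted across the groups
summarized together. Kurtosis defaults to the excess convention
(m4/m2² − 3, normal = 0); the Pearson convention (normal = 3) is a flag.
Strong-bias tallies count called pairs beyond |magnitude| > 10 and report
mean/median magnitude over all called pairs per direction. The shared-HEB
fraction is |biased in F1K ∩ biased in ALLO| / |biased in F1K|.

## Synthetic data model

The generator plants, per pair:

- a baseline expression level `base ~ lognormal(ln 50, 1.2²)` CPM at the
  nominal depth of 1e6 reads — spanning weakly to highly expressed genes
  so the TPM filter and the detectability limits are both exercised;
- an ELD state for F1K drawn from configurable collapsed-class
  proportions (defaults NC 0.70, ADD 0.02, T_DOM 0.05, K_DOM 0.05,
  TUR 0.08, TDR 0.10), realized as a concrete category chosen uniformly
  within the class;
- a HEB call drawn from configurable proportions (defaults NON_BIAS 0.90,
  T_BIAS 0.05, K_BIAS 0.05) with planted magnitude ±3.

The parental configuration is a property of the pair (the parents are the
same individuals in every comparison): dominance and transgressive
categories with differing parents use a log2 gap of `eld_effect` (default
2); additivity uses a gap of `2·eld_effect` so that the mid-parent level
sits `eld_effect` away from each parent — with a gap of exactly
`eld_effect` an additive pattern is undetectable because the |log2FC| > 1
criterion is strict. Focal totals follow the category (resembled parent
for dominance, log-space mid-parent for additivity, one `eld_effect`
beyond the extreme parent for transgressive classes, parental average for
No Change) and are split between homoeologs so the focal log2(T/K) equals
the parental ratio plus the planted magnitude.

F1T and ALLO re-draw their state with retention probability 0.7 toward the
F1K state; re-draws are confined to categories compatible with the pair's
parental gap and weighted by the configured proportions, so group-level
mixes stay close to the configuration while state transitions between
groups occur at a realistic rate.

Planted HEB is restricted to pairs with baseline ≥ 20 CPM and balanced
parental expression. The expression floor matches the detectability
condition under which recovery is a meaningful measure of classifier
behaviour rather than sequencing depth; the parental-balance restriction
keeps the planted magnitude identical to the focal homoeolog ratio and
makes planted bias broaden the mid-scale of the ratio distribution rather
than extend its extreme tail — which is exactly the empirical phenomenon
of interest: the parental ortholog-ratio distribution is the most peaked
(highest excess kurtosis) and the allotetraploid's the least, because
hybridization and polyploidization add ratio-perturbed pairs.

An optional maternal cytonuclear subset (`cyto_fraction`, default 0)
receives an extra bias of `cyto_magnitude` toward the maternal subgenome —
K-ward in F1K and ALLO, T-ward in F1T, reflecting maternal organelle
inheritance. Truth labels always reflect the effective planted magnitude.

Counts are negative binomial with `variance = mu + phi·mu²` (default
φ = 0.05, typical for bulk RNA-seq biological replicates; φ = 0 gives
Poisson), with per-library depth factors drawn uniformly from 0.7–1.3.
Gene effective lengths are log-uniform on 0.5–5 kb so TPM and CPM genuinely
differ. Everything is deterministic under the seed. A homoeolog
misassignment parameter is stubbed at 0 (validated; not implemented) —
counts are treated as correctly sorted.

What the generator does *not* emulate: read-level effects (mapping
ambiguity, positional bias), correlated expression between genes,
shared-individual correlation between a hybrid's two homoeolog columns
beyond the common library depth, tissue or environmental variation, and
continuous effect-size spectra (planted effects sit at the configured
point values). Passing recovery tests therefore demonstrates correctness
and power of the statistical machinery at the stated effect sizes, not
performance on any particular real dataset.

## Problem sizes and numerical conventions

Study-scale validation runs use 5,000 pairs (the acceptance suite and
`scripts/acceptance.py`); examples use 1,000–2,000. Fisher p-values follow
the standard two-sided definition (sum of table probabilities not
exceeding the observed, with the customary 1e-7 relative tie gate) and are
verified against exact integer-arithmetic enumeration over all 2x2 tables
with margins ≤ 30. Pseudo-counts: 0.5 CPM throughout, shared between the
quantities whose difference defines the magnitude. All thresholds are
strict inequalities exactly as stated. TSV outputs are UTF-8,
tab-delimited, `\n`-terminated, unquoted, so write→read round-trips are
byte-exact; run directories are written atomically and a re-run with the
same inputs and configuration is byte-identical (the manifest contains a
hash of the analysis parameters and no timestamps).

## Known limitations

- The pooled Fisher test is anti-conservative under overdispersion (see
  above); the two-replicate F1T group is the most affected.
- The AMBIGUOUS handling and the pooled-replicate scheme are this
  package's own conventions where the classical workflow leaves the choice
  open; both are exposed as options and reported explicitly.
- Strong-bias tallies at |magnitude| > 10 are empty under the default
  generator (planted magnitudes are ±3; enable the cytonuclear subset for
  stronger planted bias).
- The t-test in the distribution summary assumes approximate normality of
  the ratio distribution's mean; with the heavy-tailed mixtures involved
  it is a descriptive, not a calibrated, statistic.
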