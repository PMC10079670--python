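# Methods

`depsel` implements the statistical core of a selective-dependency mapping
analysis: a small disease group of screened cancer cell lines (the
motivating case is chordoma, four lines) is compared against a large
reference panel (hundreds of lines) of genome-scale CRISPR-Cas9 knockout
screens, and the nominated dependencies are characterized through
co-essentiality, biomarker and signature analyses. This note records the
models, the defaults and why, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Screen scores

Two per-gene, per-cell-line measures are consumed, never computed here:

* **gene effect** (CERES-style): magnitude of the knockout fitness effect,
  more negative = stronger dependency;
* **dependency probability**: certainty in [0, 1] that gene loss impairs
  viability.

Fitting these from raw sgRNA counts is out of scope; matrices arrive in the
DepMap tabular dialect (`"SYMBOL (ID)"` headers are reduced to the symbol,
empty/NA cells are missing and never imputed).

## Moderated differential essentiality

For each gene, complete observations are split into group and reference
arms (>= 2 per arm required). The effect is the difference of arm means —
the coefficient a two-group linear model reports, conventionally labelled
log2 fold-change even though screen scores are not log-ratios; a literal
log2 ratio of means is undefined for negative gene effects and is exposed
only behind `lfc_as_ratio_of_means` for probability scores, without
endorsement. The pooled variance s² with df = n₁ + n₂ − 2 is shrunk by
empirical Bayes: s² | σ² ~ σ²·χ²_df/df with a scaled inverse chi-square
prior σ² ~ d₀·s₀²/χ²_d₀. Hyperparameters are estimated by moment matching
on log s² (mean and variance of log s² against digamma/trigamma of df/2;
the trigamma inverse by Newton iteration), giving the posterior variance

    s̃² = (d₀·s₀² + df·s²) / (d₀ + df)

a moderated t = Δmean / sqrt(s̃²·(1/n₁ + 1/n₂)), and two-sided P from a t
distribution with d₀ + df degrees of freedom. Degenerate cases: with no
excess dispersion of log s², d₀ = ∞, s̃² = s₀² = exp(mean adjusted log s²)
and the reference distribution is normal; genes with s² = 0 take the
pure-shrinkage posterior d₀·s₀²/(d₀ + df) rather than an infinite t. The
implementation is verified against a from-the-formulas oracle (1e-10) and
against R limma on the same table; the two diverge only in the degenerate
branch, where limma substitutes mean(s²) for exp(mean log s²) — we keep the
moment-matching form. Q values are Benjamini-Hochberg
(statsmodels).

## Nomination gates

Both gates are applied to the paired differential tables (gene effect and
dependency probability over the same gene universe):

* **stringent**: P < 0.01 and |lfc| > 0.5 on both measures;
* **relaxed**: effect P < 0.02, |effect lfc| > 0.4, |probability lfc| > 0.3.

Direction criteria then classify survivors: *group-selective* requires mean
group dependency probability > 0.5 and positive probability-lfc;
*reference-selective* requires mean group probability <= 0.5 and negative
probability-lfc. Direction is enforced at both gates
(`direction_at_stringent` reverses this). Gates are monotone: loosening a
threshold never removes a nomination.

## Co-essentiality and interaction networks

Pairwise Pearson correlations between dependency-probability profiles use
pairwise-complete observations with a floor of 3 shared lines (the source
analyses state no explicit floor; 3 is the smallest n for which r is not
degenerate). Edges connect pairs with r >= 0.18, inclusive; constant
profiles yield missing r with a warning. Interaction networks are induced
subgraphs of a local edge table at confidence >= 0.4, inclusive, with
singletons retained as isolated nodes. No graph layout is computed.

## Biomarker scans

One dependency's gene-effect profile is correlated against every feature of
a matrix — expression log2(TPM+1), gene-level copy number, or binary
mutation indicators (one feature per gene and optionally per variant
class). Each pair gets pairwise-complete Pearson r and a univariate OLS fit
(slope t-test with n − 2 df; a perfect fit reports the smallest positive
float, never 0). Results are ranked lists, not significance calls, so no
multiple-testing correction is applied; mutation scans rank by increasing
r (dependency-increasing mutations first), the others by decreasing r.
Constant features and under-observed pairs are emitted with missing r and a
reason code rather than dropped silently.

## Copy-number window scan

Copy-number segments span many genes, so a dependency's copy-number
correlates cluster around the causal locus. For a nominated anchor gene,
windows w = 5×10⁵ … 5×10⁶ bp (step 5×10⁵) are interpreted as centered
spans of total width w: members are genes on the anchor's chromosome whose
interval midpoints lie within w/2 of the anchor midpoint, bounds inclusive,
anchor included (both config-reversible; the geometry is not specified by
the source analyses, and total-width keeps the printed grid on the extent
scale). Midpoint membership avoids double counting boundary-straddling
genes. Each member set is tested by pre-ranked enrichment against the full
correlate list ranked by decreasing r, with a same-size random-set
permutation null; the selected window has the smallest permutation p, ties
broken by larger |ES|, then smaller w. Member sets are nested and monotone
in w by construction. Note the selected p is a minimum over ~10 nested
windows and is therefore selection-inflated under the null (measured ~20%
below 0.05 at 10 windows); per-window p values are calibrated, and callers
comparing windows should treat the selected p as descriptive.

## Enrichment statistics

* **Pre-ranked GSEA**: the classic weighted running sum (weight exponent
  1): hits add |metric|^1 normalized by the in-set total, misses subtract
  1/(N − n_hits); ES is the deviation of maximal absolute value (exact
  magnitude ties resolve positive). The null is Monte Carlo over gene
  labels — random same-size sets — not the adaptive multilevel scheme of
  fgsea. NES divides ES by the mean |null ES| of matching sign (missing
  with < 3 sign-matched draws). p = (1 + #{|null ES| >= |ES|})/(1 +
  n_perm): the two-sided count keeps p uniform under the null while
  honoring the 1/(n_perm + 1) floor; a sign-restricted count with the same
  denominator cannot exceed ~0.5 under a symmetric null. BH across sets.
* **Hypergeometric over-representation**: upper-tail P(overlap >= k)
  (scipy).
* **Network list enrichment** (a simplification of gene-list network
  enrichment analysis): statistic = number of graph edges with one endpoint
  in the list and one in the set, each edge once; null lists are redrawn
  stratified by degree decile; p = (1 + #{null >= observed})/(1 + n_perm).
  The contract is calibration, not numerical identity with the published
  tool. Because the statistic is integer-valued, the conservative count is
  super-uniform on sparse graphs; calibration checks therefore run on
  graphs dense enough (~400 nodes, 3000 edges, |set| 60, |list| 40) that
  the statistic is near-continuous.
* **List-size-normalized AUC**: given adjusted enrichment p-values for all
  top-list sizes g = 1..G (G = 200), AUC = (1/(G·p_min)) Σ min(−log10
  p_adj(g), p_min), with p_adj = 0 mapped to the ceiling p_min = 52 — the
  printed saturation constant, taken as authoritative since its stated
  derivation from floating-point accuracy is ambiguous. The integral is
  discretized as a unit-step sum over integer g (step vs trapezoid is
  unstated in the source; unit-step is our choice). Missing g values are an
  error, never interpolated.

## ISG signature scoring

Expression TPM is transformed per gene to modified z-scores: center =
median across cell lines, scale = mean absolute deviation about the median
— the literal reading of the source procedure; the conventional
median-absolute-deviation scale is available via `scale_mode`, and no
consistency constant is applied. No pseudocount or log transform in the
default path. Zero-scale genes are dropped and listed. The ISG core score
is the mean modified z over the packaged 38-gene signature (the printed
list's "SP1*10*" is read as SP110). Lineage ranking takes per-lineage
medians over annotated reference lines, drops unannotated lines, configured
exclusion labels ("Engineered" by default) and lineages with < 2 lines, and
reports the disease group's rank (1 = highest; name-ordered ties).

## Synthetic panel

The generator's defaults are the study conditions: 4 group lines vs 500
reference lines, 1000 genes, 20 group-selective genes planted at gene
effect −1.0 (matching the common-essential depth), 50 common-essential, 5
reference-selective, observation noise sd 0.2. Dependency probability is a
logistic transform p = 1/(1 + exp(k·(effect − x₀))), k = 6, x₀ = −0.5, plus
N(0, 0.02) noise clipped to [0, 1] — only monotonicity and range are
contractual, not the real probability model. Genes sit on 5 chromosomes at
100 kb spacing; copy number is segment-shared (8-gene segments, sd 0.5,
per-gene jitter 0.15) so neighbors co-vary. Planted biomarkers: a paralog
pair (a group-selective gene's effect couples to a neutral anchor's
segment deviation with slope 0.6, and the anchor's ±2-gene block shares
its segment — sized to fit inside the smallest 0.5 Mb scan window so the
covering window is unambiguous); a mutation pair (a neutral gene whose
effect drops by 1.0 in carriers of a background mutation feature,
prevalence 0.15); and ISG elevation (+3 per-gene sd on the 38 ISG-named
genes in group lines). Expression is dosage-coupled to copy number, so
copy-number correlates reappear at the expression level, as in real
panels. Reference lines cycle through 20 lineage labels, with one
unannotated line, one "Engineered" and one singleton lineage planted to
exercise the exclusion rules. All randomness flows from one seed through
fixed named substreams, so resizing one planted structure does not perturb
the others' draws.

What the panel does *not* emulate: screen quality variation, copy-number
artifact correction, guide-level effects, expression distributions with
realistic dispersion/zero-inflation, lineage-correlated dependency
structure, and the weak panel-wide correlation background of real
screens. Passing the recovery benchmark therefore demonstrates the
pipeline's correctness and power under clean planted signal, not expected
sensitivity on real data.

## Problem sizes and numerics

Tests and the acceptance script run the default panel (504 × 1000), null
calibrations at 500 regression replicates, 200 gene sets × 1000
permutations (GSEA) and 200 lists × 400 permutations (network enrichment),
window scans at 1000 permutations — sizes chosen to estimate each rate to
within a few percent. Permutation p-values honor the (1 + x)/(1 + n)
floor and are bit-reproducible given a seed. Thresholds compare
inclusively where the source states ">=" and strictly where it states
"exceeds"/"lower than". Known limitations: no multi-factor designs or
batch covariates in the differential model; no sample-permutation GSEA; no
multivariate biomarker models; enrichment p-values are plain Monte Carlo
and bounded below by 1/(n_perm + 1).
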