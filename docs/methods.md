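# Methods

## The HOX-code model

Each tissue t with labeled samples S_t gets a reference profile over the
39 human HOX genes (HOXA1-13, HOXB1-13, HOXC4-13, HOXD1-13 per HGNC, with
the cluster gaps those ranges imply):

    code_t[g] = median_{s in S_t} f(x[g, s])

where x is a non-negative abundance (FPKM or comparable; the pipeline is
unit-agnostic as long as units are consistent across samples) and f is the
working transform. Even-sized groups use the standard median convention
(mean of the two middle order statistics). A sample is scored against every
code by the sample Pearson correlation of f(x[:, s]) with code_t, giving a
sample × tissue score matrix in [-1, 1].

**Transform.** The default is f = log2(x+1), applied before the median and
before every correlation. On raw FPKM the correlation is dominated by the
one or two highest-expressed genes (in prostate, HOXB13), so raw-scale
scores mostly measure agreement on a single gene; the log scale weights the
full combinatorial pattern. `transform="none"` is available for the
raw-scale reading, and a code table records the transform it was built
under so scoring always happens on the same scale.

**Classification.** With a home (tissue-of-origin) label and threshold
r* (default 0.3, strict inequality):

- `kept` — home score > r*;
- `switched_to_other` — home score ≤ r* but some other code scores > r*
  (the best such tissue is reported);
- `switched_no_identity` — no code scores > r*: identity lost without a
  replacement, the operational encoding of neuroendocrine
  trans-differentiation's "lost prostate identity, gained none";
- `undefined` — the sample's score row is entirely missing (zero-variance
  profile); degenerate samples never abort a cohort run.

Without a home label the call collapses to best-match reporting: `kept`
when exactly one code exceeds r* (that code is the assigned identity),
`ambiguous` when two or more do, `switched_no_identity` when none does.
Ties for the best tissue break lexicographically so output is
deterministic.

**Validation.** The code table is checked by the self-correlation
procedure: entry (t, u) of the validation matrix is the median over
samples labeled t of their correlation with code u. A well-separated code
set shows a dominant diagonal. This validation is deliberately circular —
samples are scored against codes they contributed to — matching how such
heatmaps are usually produced; a leave-one-out variant is not provided
because at the default group sizes the medians barely move.

## Two-group comparison

Per gene, Welch's unequal-variance two-sided t-test on the transformed
scale, chosen over the pooled Student variant because cohort group sizes
in this setting are typically unbalanced (34 vs 15 in the emulated
contrast); the pooled test is available by flag. Benjamini-Hochberg
q-values are always reported across the tested gene family, but the
`significant_raw` flag follows the raw p < 0.05 convention used for
per-gene star annotation in this literature. Genes flat in both groups
with equal means are reported as t = 0, p = 1. "Most changed" ranks genes
by |t| descending with alphabetical tie-break.

## H-score statistics

H = 1·pct1 + 2·pct2 + 3·pct3 over four staining-intensity levels 0-3 (the
universal H-score convention), range [0, 300]; input percentages must sum
to 100 ± 0.5 to absorb pathologist rounding. Grade is ordinal with benign
hyperplasia below all Gleason scores (BPH < GS6 < ... < GS10); sub-pattern
distinctions (3+4 vs 4+3) are not modeled. Association is measured by
Spearman's rho with average-rank tie handling and a two-sided p from the
large-sample t approximation; rho is undefined (NaN) when either variable
is constant.

## Synthetic cohorts

The generator emulates a multi-tissue cell-line compendium at the scale of
the public resources this kind of analysis is run on: 24 tissues by
default, 8 samples per tissue, archetype log2 profiles with entries i.i.d.
uniform on [0, 12] (roughly the log2(FPKM+1) dynamic range of HOX genes in
bulk RNA-seq), and per-sample Gaussian noise on the log2 scale (sd 0.25
default — log-normal dispersion on the raw scale). Raw values are
2^z − 1 truncated at 0, the exact inverse of the working transform.
Lineage-switch samples draw a fresh archetype of their own, decorrelating
them from every tissue's code. The contrast generator plants additive
log2 shifts on named genes in a 34-vs-15 two-group design; the H-score
generator draws intensity percentages from a Dirichlet whose mean follows
a Binomial(3, mu/3) profile with mu rising by a configurable trend per
grade step. All draws come from numpy's PCG64 stream seeded explicitly;
there is no hidden global state, and identical config + seed is
bit-identical across platforms.

What the generator does **not** model: read counts and library size,
batch/platform effects between cohorts, correlated co-expression within
HOX clusters, single-cell dropout, and — importantly — the mutual
correlation of real tissue codes (real tissues share broad 3' HOX
activation; uniform archetypes are mutually near-orthogonal). Passing
tests therefore demonstrate that the pipeline recovers planted structure
under idealized noise, not that real cohorts will separate as cleanly.

One consequence of the near-orthogonal archetypes is worth stating: a
fully decorrelated 39-gene profile still crosses r = 0.3 for *some* one of
23 alternative codes about half the time (per-code null sd of r is
1/sqrt(38) ≈ 0.16, so each code is crossed with probability ≈ 0.03), so
roughly half of synthetic switch samples are labeled `switched_to_other`
on a single-sample basis even though no *consistent* new identity exists
at the group level. Per-sample calls at a fixed cutoff cannot distinguish
a chance single-code crossing from a genuine identity, and users reading
cohort summaries should interpret `switched_to_other` counts with that
multiplicity in mind.

## Numerical and interface choices

- Correlations are clipped to [-1, 1] to absorb floating-point overshoot;
  zero-variance vectors yield NaN rather than an exception.
- Gene symbols are matched case-insensitively with a built-in legacy-alias
  map (pre-1992 HGNC symbols such as HOX1F → HOXA1) because GEO and
  cell-line exports vary; subsetting to the gene set follows the canonical
  gene order regardless of input order, and the `intersect` policy refuses
  to run below 10 present genes, where a 39-gene correlation loses meaning.
- GCT 1.2 and 1.3 are parsed natively (the dialect is a thin TSV wrapper);
  1.3 row/column metadata beyond the id is discarded. Delimited reads use
  exact round-trip float parsing so write-then-read is bit-identical.
- Tables are written as TSV with row labels in the first column and ≥ 6
  significant digits; heatmaps use a diverging map symmetric about 0 over
  [-1, 1] for correlation matrices, grey for missing cells, and optional
  average-linkage/Euclidean clustering of rows and columns (fixed
  alphabetical order is the default for reproducibility).
- The pipeline driver computes everything before writing, removes partial
  outputs on failure, and logs transform, threshold and versions so any
  artifact can be reproduced exactly.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the study's native scale: the default 24 × 8 cohort (192 samples), a
100-sample held-out switch group, 100 seeded replicates of the 34-vs-15
contrast, 200 replicates of a 1000-gene × 20-sample null for type-I
calibration, 200 random vector pairs for the Pearson oracle and 1000
simplex draws for the H-score oracle. The full suite completes in well
under a minute on one core.

## Known limitations

- Real cohort counts from the motivating application (e.g. specific
  kept/switched tallies in published prostate-cancer cohorts) require
  controlled-access expression data and are not reproduced here; the
  operations are sufficient to compute them when such data is supplied.
- The 0.3 cutoff is adopted as the field's stated convention, not
  re-derived; no attempt is made to calibrate it per cohort.
- No batch correction or cross-platform normalization: microarray and
  RNA-seq inputs are treated identically, with transform responsibility on
  the caller.
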