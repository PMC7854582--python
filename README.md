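# hoxcode

Tissue-of-origin scoring of bulk expression data through HOX codes:
per-tissue median expression profiles over the 39 human HOX genes, used to
ask whether a tumor sample still "remembers" the developmental identity of
its tissue of origin.

Humans carry 39 HOX transcription-factor genes in four clusters (HOXA-D,
paralogs 1-13) whose combinatorial expression patterns the body axes during
development and remains tissue-specific in the adult. A tissue's **HOX
code** is defined here as the vector of per-gene median expression over
that tissue's samples, taken on the log2(FPKM+1) scale:

&nbsp;&nbsp;&nbsp;&nbsp;code_t[g] = median over samples s with label t of log2(x[g,s] + 1)

A sample is scored against every code by the Pearson correlation r of its
39-gene profile with the code vector, and classified at the cutoff
**r > 0.3**: it has *kept* its lineage identity when its home tissue's
score exceeds the cutoff, *switched to another* identity when only a
different tissue's code does, or — the pattern typical of neuroendocrine
trans-differentiation in prostate cancer — *switched with no new identity*
when no code correlates at all. Companion modules cover the per-gene
two-group comparison of HOX expression (Welch's t-test, two-sided, with
Benjamini-Hochberg q-values), the immunohistochemistry H-score
(H = 1·pct1 + 2·pct2 + 3·pct3 ∈ [0, 300]) with its Spearman correlation
against ordinal tumor grade, and a seeded synthetic-cohort generator so
every stage is testable without any external download.

Intended users: computational biologists studying lineage plasticity who
have a gene × sample abundance matrix (TSV/CSV/GCT) and a sample → tissue
label table.

## Worked example

```sh
hoxcode simulate cohort --seed 7 --n-tissues 6 --samples-per-tissue 5 --out-prefix demo
hoxcode build-codes --expr demo_expr.tsv --meta demo_meta.tsv \
    --out demo_codes.tsv --validate demo_validation.tsv
hoxcode score --expr demo_expr.tsv --codes demo_codes.tsv --out demo_scores.tsv
hoxcode classify --scores demo_scores.tsv --meta demo_meta.tsv \
    --threshold 0.3 --out demo_calls.tsv --summary demo_summary.tsv
```

which prints

```
wrote 30 samples x 39 genes -> demo_expr.tsv
wrote 6 tissue codes x 39 genes -> demo_codes.tsv
wrote validation matrix -> demo_validation.tsv
scored 30 samples against 6 codes -> demo_scores.tsv
classified 30 samples (30 kept, threshold r > 0.3) -> demo_calls.tsv
wrote per-group summary -> demo_summary.tsv
```

All 30 synthetic samples keep their generating tissue's identity: each
sample's correlation with its own tissue's code exceeds 0.3 (here, in a
low-noise simulation, it is near 1), while correlations with the other five
codes scatter around zero. `demo_calls.tsv` holds one row per sample
(home tissue and score, best-matching tissue and score, call) and
`demo_summary.tsv` the per-tissue call counts and fraction kept.

The same workflow runs end to end in one command (`hoxcode run --expr ...
--meta ... --out-dir out/`), and the equivalent library calls are shown in
the numbered scripts under `analysis/` (build codes and validate them,
classify in-cohort and held-out decorrelated samples, recover a planted
AdPCa-vs-NEPCa differential pattern, H-score vs grade statistics), each of
which writes its tables under `results/` and prints what it found.

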