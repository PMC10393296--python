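# ciliareg

A regulatory-genomics toolkit for asking how a battery of ciliary effector
genes is co-regulated, built around the analysis workflow used to screen for
transcription-factor (TF) co-regulators of the *C. elegans* sensory ciliome.

## The problem

Ciliated sensory neurons express a battery of cilium effector genes — IFT
particles, BBSome subunits, kinesins, dyneins, channels — largely under the
control of RFX-family TFs, which bind a long palindromic motif called the
X-box. But RFX loss never silences the battery completely, which points to
additional TFs acting in concert. Finding such a co-regulator
computationally requires stitching together several kinds of evidence:

1. **Battery accounting** — a curated effector-gene list partitioned into
   *core* (all cilia), *subtype-specific*, *broad* and *male* categories.
2. **Expression screening** — which TFs are enriched in ciliated cells in
   single-cell RNA-seq, at a fold threshold *f* ≥ 5 and FDR ≤ 0.001.
3. **ChIP-seq binding** — annotate each TF's peaks to genes under a
   strand-aware TSS window (−2000/+1000 bp), count battery genes bound, and
   regress battery binding on total peak count across TFs: a genuine
   co-regulator is an *outlier* above the line (externally studentized
   residual, Bonferroni-adjusted t threshold), not merely a promiscuous
   binder.
4. **Motif positional statistics** — scan fixed 420-bp windows centred on
   peaks for the X-box PWM; under the null the best site per window lands
   uniformly, so central concentration is a binomial tail test
   P(K ≥ k), K ~ Bin(n, w/(L−m+1)) over a grid of central widths w
   (Bonferroni over the grid). Plus X-box–to–peak-centre distances and a
   four-way "dual signature" classification of battery genes
   (X-box ∧ peak / peak only / X-box only / neither).
5. **Genetic synergy** — per-animal reporter-positive neuron counts,
   converted to fold changes against a reference genotype. Under the
   multiplicative (independence) null the triple-mutant fold change is the
   product of the double-mutant fold changes,
   E = m̂_a · m̂_b,  sd_E = E·(s_a/m̂_a + s_b/m̂_b),
   and a one-sample t test of the observed triple-mutant fold changes
   against E calls a *synergistic loss* when the observed mean falls
   significantly below E.

`ciliareg` implements every stage as a library with a thin CLI, plus a
synthetic-data generator that emulates all of the study's inputs with known
ground truth — so the whole pipeline is testable end to end without any
external downloads.

## Worked example

The end-to-end simulated run executes every stage on a small synthetic
dataset (6 Mb genome, 500 genes, 44-gene battery, a 200-peak regulator among
12 background TFs, 1,000-cell expression matrix, 10 animals per genotype):

```bash
ciliareg run --seed 1
```

prints (abridged):

```json
{
  "stages": {
    "battery":  {"counts": {"core": 20, "subtype": 15, "broad": 5, "male": 4}, "total": 44},
    "annotate": {"battery_fraction": 0.409, "core_fraction": 0.75, "subtype_fraction": 0.067},
    "rank_tfs": {"top_tf": "REG", "outliers": ["REG"]},
    "centrimo": {"match_fraction": 0.23, "central_p": 5.21e-06},
    "sc_screen": {"passing": ["fkh-8"]},
    "synergy":  {"expected_fc": 0.0706, "observed_mean_fc": 0.0891,
                 "p_value": 0.151, "verdict": "consistent_with_multiplicative"}
  }
}
```

Reading the output: the battery partitions into its four categories; 41% of
battery genes (75% of core but only 7% of subtype genes) carry a regulator
peak in their TSS window; the regulator ranks first by battery binding and
is the only TF flagged as a regression outlier; X-box matches occur in 23%
of peak windows and concentrate centrally (p ≈ 5×10⁻⁶); the expression
screen recovers the planted ciliated-cell regulator; and the triple-mutant
reporter counts, generated here under the multiplicative null, are correctly
called consistent with it (p = 0.15).

Individual stages are exposed as subcommands operating on standard formats —
`ciliareg promoters|scan|kmers|annotate|rank-tfs|centrimo|distances|
signatures|sc-screen|sc-corr|synergy|reporter-tests|behavior|simulate` —
reading FASTA, GFF3/TSV gene tables, ENCODE narrowPeak, JASPAR PFMs,
MTX/TSV count matrices and long-format reporter TSVs.

## Layout

```
src/ciliareg/
  battery.py     gene-battery model and TSV loader
  seqmotif.py    promoters, PWMs, scanning, k-mer over-representation
  peaks.py       narrowPeak I/O, TSS-window annotation, TF prioritization
  positional.py  central enrichment, distance profiles, dual signatures
  scexpr.py      single-cell enrichment screen and correlation profiling
  genstats.py    reporter-count t procedures, multiplicative synergy model,
                 Fisher rescue tests, behavioral indexes
  synthetic.py   ground-truth generators for all of the above
  cli.py         click CLI and the end-to-end pipeline
docs/methods.md  modelling assumptions, parameter defaults, limitations
```
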