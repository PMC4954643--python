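# mirclash

Discriminative miRNA target prediction learned directly from
interaction-level data: CLASH chimeric reads, which ligate a miRNA to the
mRNA fragment it was bound to, and AGO CLIP peaks, which mark where the
Argonaute/miRNA complex sits on 3'UTRs. Instead of scoring candidate
sites with fixed seed rules or thermodynamic energies, `mirclash` learns
two complementary models from these data and is aimed at computational
biologists studying post-transcriptional regulation:

1. **A duplex model** — a latent structural SVM over miRNA–mRNA duplex
   alignments. A duplex is an event sequence (base pairs per miRNA
   position, loop openings, symmetric/asymmetric loop extensions, paired
   indicators), and its score is additive: for the feature vector
   φ(miRNA, site) of an alignment, score = **w**·φ. The same vector
   **w** is therefore simultaneously the SVM model and the local
   pairwise-alignment scoring system; training alternates computing
   optimal alignments under **w** (dynamic programming) with max-margin
   updates of **w** given the alignments. Biology is built into the
   grammar: miRNA position 1 may pair only opposite an adenosine (the
   m1A rule), and non-canonical sites (seed mismatches, bulges, G:U
   wobbles, 3'-supplementary pairing) are first-class alignments rather
   than exceptions.

2. **An AGO binding model** — a kernel SVM separating AGO-bound from
   unbound seed matches. The 30-nt flanks on each side of the match are
   scored with positional weighted degree string kernels
   (k = 1…6, β_k-weighted positional k-mer matches), and the site's place
   in the 3'UTR isoform structure — distances from the anchor (the base
   opposite miRNA nt 2) to the stop codon and to the next/previous
   isoform 3' end from a polyadenylation atlas — with an RBF kernel on
   log distances. Data sets from different cell types are combined with
   a multi-task kernel, K_st(x, z) = (μ + δ_st)·K(x, z), yielding a
   cell-type-agnostic *common* model plus per-cell-type corrections.

On top sit the published filtering rules for building training sets
(chimeric-read filters, mispaired decoys at 15×, CLIP negatives at 1×),
held-out-family evaluation (auROC, auPR, auPR50), and interpretation:
positional oligomer importance matrices (POIMs) computed exactly from the
dual SVM, per-position score decomposition, and RNAcompete probe
enrichment tests with a label-permutation empirical FDR. A synthetic data
generator with planted, known structure makes every component testable
without downloads.

## Worked example

```bash
python examples/02_train_duplex_model.py
```

```
training examples      : 1784
held-out positives     : 46
held-out negatives     : 310
held-out family auROC  : 0.971
weight-change trace    : [1.67, 0.38, 0.23, 0.23, 0.16, 0.24, 0.32, 0.15, 0.08, 0.23, 0.02, 0.0]
final step / ||w||     : 0.0000
```

This simulates a catalog of 8 seed families and 300 UTRs, plants a known
scoring vector w*, labels embedded candidate sites by their alignment
score under w*, pushes the evidence through the CLASH/CLIP filters, and
trains the structural SVM with one family held out entirely. The auROC
of 0.971 says sites of the unseen family are ranked almost perfectly; the
trace ending at 0 says the alternating optimization reached a fixed
point. `examples/03_binding_model_and_poims.py` does the analogous
recovery for the binding model (held-out auROC 0.945 and the planted
motif UGCAUG recovered as the top POIM 6-mer at its planted offset), and
`examples/01`, `04`, `05` demonstrate single-duplex alignment, motif
enrichment with empirical FDR, and positional site profiles.

The same pipelines are scriptable from the shell:

```bash
mirclash simulate --seed 1 --out-dir data/
mirclash build-trainset --mirna-fasta data/mirnas.fa --families data/families.tsv \
    --utr-fasta data/utrs.fa --atlas data/atlas.tsv \
    --interactions data/interactions.tsv --peaks data/peaks.bed --out sites.tsv
mirclash train-duplex  ... --trainset sites.tsv --out duplex.json
mirclash train-binding ... --trainset sites.tsv --out binding.json
mirclash score ... --duplex-model duplex.json --binding-model binding.json --out scores.tsv
```

## Layout

```
src/mirclash/
  io.py          typed readers/writers, UTR coordinate conventions
  trainset.py    seed scanning, CLASH/CLIP filters, negatives, holdout
  duplex.py      event grammar, DP aligner, structural-SVM trainer
  binding.py     flanks, WD + positional kernels, multi-task SVM
  interpret.py   POIMs, decomposition, enrichment, empirical FDR
  evaluate.py    auROC/auPR/auPR50, held-out-family harness
  synthetic.py   planted-structure fixture generator
  experiments.py recovery experiments wiring the pipeline together
  cli.py         thin command-line layer
```

See `docs/methods.md` for the models, parameter choices and limitations.
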