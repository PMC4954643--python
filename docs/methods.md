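# Methods

## Coordinates and alphabets

Everything lives in 3'UTR space: 0-based, half-open intervals, position 0
the first base after the stop codon. Sequences are RNA internally (T→U on
read); `N` is tolerated in UTRs but excluded from every base pair and
k-mer. Genome-to-UTR projection is out of scope — peaks, chimeric sites
and isoform 3' ends are expected pre-projected, which removes any genome
or annotation dependency.

## The duplex model

### Event grammar

A duplex alignment is an ordered event list indexed on the miRNA axis
(positions 1..27, 5'→3'; the site is traversed antiparallel):

* `PAIR(p, q, b)` with b ∈ {AU, UA, GC, CG, GU, UG} (miRNA base first);
* `LOOP_OPEN(p)`, `SYM_EXT(p)` (consumes one unpaired base from each
  strand), `ASYM_EXT_MIRNA(p)` / `ASYM_EXT_SITE(p)` (one base from one
  strand);
* a per-position paired indicator accompanies every `PAIR`.

Alignments are local on both strands, begin and end with a `PAIR`, and a
pair at p = 1 is only legal opposite `A` and is scored by one dedicated
weight (m1A) rather than a pair-type weight — so only an A across from
position 1 can contribute to the score. Mismatched opposed bases are not
pair events; they are realized as loops (one symmetric extension eats one
base from each strand). A loop consuming a miRNA-side and b site-side
bases costs one `LOOP_OPEN` plus a decomposition into SYM (1+1) and ASYM
(1+0 / 0+1) events; the dynamic program maximizes over decompositions,
which keeps the score linear in event counts. Loop events are indexed by
the miRNA position current at event time; site-side extensions carry the
last consumed miRNA position. The weight vector has
27·6 pair weights + 1 m1A + 3·27 loop weights + 27 indicators = 271
entries; the score of an alignment is exactly **w**·φ, a property the
test suite asserts to 1e-9 on 10^4 random instances.

### Alignment DP

Two matrices over the (miRNA × reversed-site) grid — best score ending in
a pair, best score inside a loop — give an O(M·L) recurrence; the
site-side loop chain is a running maximum along each row. The traceback
re-derives each decision with the same float expressions as the forward
pass, so the optimum is matched exactly; ties are broken by a fixed
preference order (stacking before loop closure; inside loops, opening
before continuation and symmetric before asymmetric), which makes output
deterministic. An alternative tie-break (fewest events, then 5'-most
starts) could be realized as a lexicographic tuple DP, but the fixed
preference order gives the same scores and the same determinism while the
vectorized rows keep full training runs in seconds rather than minutes.
An exhaustive event-sequence enumerator in the test suite confirms exact
score equality on hundreds of random instances. The empty alignment
(score 0) is returned when no legal alignment scores above 0. A
`global_mirna` mode (start at position 1, end at the last position) is
available behind a config flag; `local` is the default.

### Training

Given labeled (miRNA, site) examples, training runs 12 outer iterations
(the default). Each iteration realigns every positive under the current
weights (iteration 1 uses the initializer) and resamples negatives per
source — 15 CLASH negatives per CLASH positive, 1 CLIP negative per CLIP
positive, with an iteration-indexed seed. A negative must score low under
*every* alignment, not just one, so each iteration then runs up to 4
cutting-plane passes: fit a linear hinge-loss SVM (exact libsvm solver)
on the positives' current alignments plus each negative's working set of
alignment feature vectors, realign the negatives under the new weights,
and add any newly violated alignment to the working set, stopping early
when nothing new appears. This is the standard treatment of a latent
structural SVM (concave-convex procedure outside, cutting planes inside)
and it terminates at an exact fixed point: once the positives' alignments
and the working sets stop changing, consecutive fits are identical and
‖w_t − w_{t−1}‖ = 0. Plain realign-refit alternation (recoverable with
`inner_max=1`) was implemented first and measurably oscillates — the
negatives' max-score alignments keep flipping between near-ties, the step
norm stays at the scale of ‖w‖ and held-out auROC is several points
lower — which is why the working-set form is the default.

Hinge-loss C defaults to 0.01, chosen from {0.001, 0.01, 0.1, 1} as the
most stable/accurate on the synthetic study conditions; `C="cv"` selects
it by stratified 5-fold CV. Event-count features have scale ~10 per
example, so a small C plays the role a unit C plays on normalized
features.

The builtin initializer aligns under fixed thermodynamic-flavoured
weights (GC/CG 3, AU/UA 2, GU/UG 1 at every position; loop open −3, sym
−1, asym −2; m1A 2; indicators 0). An external initializer accepts
dot-bracket duplex structures from an RNA folding tool and converts them
to the event grammar (a position-1 pair opposite non-A is dropped).

## Training-set construction

* **CLASH positives**: interactions whose site lies in the UTR, contains
  a match within edit distance 1 (substitutions or indels; windows of
  5–7 nt) of the reverse complement of miRNA nt 2–7, and has non-chimeric
  read support ≥ 1. The site is the chimera-mapped fragment.
* **CLIP examples**: every exact 6-mer seed match of a cataloged family;
  positive if it shares ≥ 1 base with an AGO peak, negative if it
  overlaps no read evidence (an optional coverage track distinguishes
  "reads but no peak", which is excluded from both classes; without it,
  peaks stand in for read evidence). For duplex training, positives are
  restricted to peaks containing seeds of exactly one family. CLIP seed
  matches are extended 18 nt 5' and 3 nt 3' for duplex alignment (where
  3'-supplementary pairing falls); flanks and positional features use
  the bare match.
* **Mispaired decoys**: positive sites re-paired with miRNAs from
  families not bound at that site.
* **Held-out-family splits** put the held family's examples *and every
  example touching a site bound by that family* in the test split. A
  decoy negative that merely reuses a held-family miRNA on some other
  site stays in training — otherwise the 15× decoy fan-out would drag
  the majority of all examples into the test split.
* The seed-match anchor (position opposite miRNA nt 2) is the 3'-most
  matched base; for indel matches it is recomputed from the edit
  alignment with ties toward 3'.

## The binding model

Component kernels are trace-normalized to mean diagonal 1 before
summation so neither flank kernel nor the positional kernel dominates by
scale (raw summation is a config switch). WD kernel degree 6 with the
standard weights β_k = 2(d−k+1)/(d(d+1)); k-mers touching a pad or N
never match. Positional distances are transformed log10(1+d) — raw
distances span 0–10^4 nt and would saturate any single RBF width — with
γ = 1.0 by default; when no isoform end lies 5' of the anchor the
previous-end distance falls back to the distance to the UTR start and a
fourth indicator component marks the sentinel. The multi-task coupling μ
defaults to 1 (equal task/common weight) and can be grid-selected
({0.1, 0.25, 0.5, 1, 2, 4}) by stratified 5-fold CV maximizing held-out
auROC. Prediction modes: *common* (μ·K share only — cell-type agnostic)
and *task:<id>* (adds the same-task share). Duplex and binding scores
are combined by z-scoring each against its training distribution and
summing (`sum_z`; rank-based schemes available); gene-level scores take
the maximum over a gene's sites.

## Interpretation

The WD kernel's feature map is finite, so the dual SVM converts to
explicit positional k-mer weights (β_k-scaled support-vector indicator
sums, divided by the kernel normalizer, with the common/task μ-scaling).
POIMs are computed exactly from those weights under a uniform i.i.d.
background: Q(z, j) = E[f | z at j] − E[f], where overlapping sub- and
super-k-mers contribute their overlap-marginalized means and
non-overlapping features cancel. Background-weighted column means are
zero by construction, and the matrices agree with Monte-Carlo estimates
within sampling error (tested). The differential POIM summary is
D[k][j] = max_z Q − min_z Q (range; the conventional reading of "highest
differential weight"), top-position selection considers 5- and 6-mers,
and 15 top k-mers represent the motif. Per-position decomposition sums
the weights of k-mers *starting* at each position (a covering variant is
available); contributions + positional part + bias reproduce the
discriminant to 1e-9.

Probe enrichment uses a one-sided Wilcoxon rank-sum test comparing, among
the 1000 highest-intensity probes, those containing ≥ 1 of the top
k-mers against those containing none (an alternative unrestricted split
is a config switch); exact null below 50 per group, normal approximation
with continuity correction otherwise. The empirical FDR retrains the
binding SVM on permuted labels, extracts top k-mers at the same (flank,
k, position), recomputes the enrichment p, and reports
(1 + #{null p ≤ observed p}) / (n_perm + 1). The default n_perm is 100
for routine use and 1000 for a full analysis. Note a structural property
of this construction: for an *observed model that is itself
label-permuted*, the FDR is an exchangeable rank and therefore uniform
on (0, 1] — which is exactly the desired "no false confidence" behavior
(P(FDR ≤ α) ≈ α at every significance level), and what the test suite
asserts.

## Metrics

auROC is the Mann-Whitney statistic with ties counted one half. auPR
uses step-function integration (no linear interpolation of precision);
auPR50 integrates precision over recall ∈ [0, 0.5] and divides by 0.5.
Both match independent threshold-enumeration oracles to 1e-12. Paired
per-family comparisons use the Wilcoxon signed-rank test.

## The synthetic generator

The generator emulates the inputs end to end: a miRNA catalog whose
families share exact 2–7 seeds; background UTRs (default 300, mean
length 400 nt, A/C/G/U composition 0.3/0.2/0.2/0.3) with 1–3 isoform 3'
ends; chimeric interaction records; AGO peaks; RNAcompete-style probe
tables. Candidate sites of graded complementarity — seed +
3'-supplementary pairing with an A opposite position 1, seed-only, or
random, with 40% of seeds mutated to edit distance 1 (non-canonical) —
are embedded into the UTRs and labeled positive when their optimal
alignment under a planted weight vector w* scores above the 0.55
quantile of candidate scores. Defining truth through the same grammar
the model learns makes parameter recovery well-posed; real labels come
from biochemistry a fixture cannot replicate. Evidence is then derived
with noise: 2% label flips, peaks missing 2% of bound sites and covering
5% of unbound ones. AGO-binding signal is planted on bound sites as a
6-mer flank motif (UGCAUG, downstream offset 2, probability 0.85) and a
4:1 odds of placement within 150 nt upstream of an isoform end. For
binding-model experiments the bound/unbound coin is decoupled from w*
(no 3' extension) so flank and positional signals are the only cues; the
positional-ablation condition halves the motif probability (0.5) and
strengthens the positional odds (6:1) so that sequence alone does not
saturate the ranking — both conditions are fixed study designs, not
tuning knobs. Default scale (8 families, ~2000 duplex examples, a few
hundred binding sites) keeps the full test suite at minutes on one CPU.

What the generator does **not** emulate: read-level coverage,
crosslink-induced mutations (T-to-C), ligation biases,
expression-dependent occupancy, or conservation. Passing recovery tests
therefore demonstrates correctness of the estimators under the planted
model, not performance on real CLASH/CLIP libraries.

## Numerical and degenerate-input conventions

Alignment scores are compared exactly against the enumeration oracle
(identical accumulation order); model serialization round-trips
bit-for-bit; all sampling is seeded and iteration-indexed. Degenerate
cases: empty alignment for non-positive optima; enrichment with an empty
group returns p = 1 flagged; families with no test positives are skipped
with a log entry; negative pools smaller than the requested sample are
taken whole with a warning.

## Known limitations

* The duplex grammar scores internal loops linearly in their
  decomposition events; real loop energetics are nonlinear in loop size.
* Site accessibility (secondary structure of the target) and
  conservation are deliberately out of scope.
* Multi-task training stores the full kernel; example counts beyond a
  few thousand would need low-rank or subsampling strategies.
* The positional kernel assumes the isoform atlas is complete; missing
  3' ends bias the next/previous-end distances.
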