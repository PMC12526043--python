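# Methods

Quantitative conventions and design choices, in pipeline order.

## Coordinates and lesion assignment

All genomic intervals are 0-based half-open; GFF input (1-based inclusive)
is converted on load.  A CPD occupies two adjacent bases of one strand and
is stored at the half-integer position between them: a plus-strand dimer
over bases p and p+1 lives at key `(chrom, "+", p + 0.5)`.

CPD-seq reads begin immediately 3′ of the lesion on the opposite strand, so:

- a **plus-strand read** with 5′ end at x implies a **minus-strand** lesion
  over plus coordinates x−2, x−1, recorded at (x−2) + 0.5;
- a **minus-strand read** whose 5′ end (its rightmost base, y = end − 1)
  implies a **plus-strand** lesion over y+1, y+2, recorded at (y+1) + 0.5.

Reads whose implied dinucleotide, read 5′→3′ on the lesion strand, is not
one of TT/TC/CT/CC are discarded; off-chromosome implications are dropped
and counted.  The simulator's `emit_reads` is the exact inverse map, which
the tests exploit for an exact read↔lesion round trip on interior positions.

For browser export, a lesion at half position h is written in wig format at
the 1-based coordinate of its left base, floor(h) + 1, one file per strand.

## Normalization and induction channels

The naked-DNA control is scaled by one global factor so its total
dipyrimidine read count matches the cellular sample.  Two per-position
channels are derived over the union of keys:

- `induction = cellular − scaled_naked` (difference channel);
- `log2_floored = log2(max(cellular, f) / max(scaled_naked, f))` with floor
  f = 10, which suppresses ratio noise at sparsely covered positions — any
  position where both samples are below 10 reads has log ratio exactly 0.

## Motif frame and profiles

A motif occurrence has an anchor base (offset 0): for CCAAT the central A
(pattern index 2), for [C/A]TTCC the first C of the terminal CC (index 3).
Profile offsets are half-integers; offset o at a plus-strand site reads
genomic half position anchor + o, at a minus-strand site anchor − o, so
reverse-complement twins share one profile.  At each offset the two strand
channels are summed — at most one strand of a duplex position can carry a
dipyrimidine, so the sum simply selects the lesion-bearing strand.
Aggregate profiles support two denominators: `per_site` (all sites) and
`per_dipy_site` (only sites with a dipyrimidine at that offset); sites whose
window runs off a chromosome end are flagged partial and excluded from
aggregates.

## Feature schemas and classifiers

The Hap2/3/5 (CCAAT) schema uses offsets −1.5, +0.5, +2.5, +3.5, +4.5 in
both channels → 10 attributes; the Gcr1 ([C/A]TTCC) schema uses −1.5, −0.5,
+0.5, +1.5 → 8 attributes.  Training sets combine curated positives with a
seeded uniform sample (default 7,000 at study scale; the simulator planting
supplies all decoys directly) of motif instances lying ≥ 100 bp inside
ORFs, with positives excluded from the negative pool.

Four estimators are supported, configured to match the classic Weka
defaults for these estimator families so results are comparable across
toolkits:

- **random forest**: 100 trees, per-split feature subsampling of
  ⌊log2 n⌋ + 1 attributes;
- **multilayer perceptron**: one hidden layer of ⌈(n + 2)/2⌉ logistic
  units, SGD with learning rate 0.3 and momentum 0.2, exactly 500 epochs
  (convergence-based early stopping disabled), inputs min-max scaled to
  [−1, 1];
- logistic regression and Gaussian naive Bayes as baselines.

Evaluation is stratified k-fold cross-validation with pooled out-of-fold
probabilities; AUC is the rank-based (Mann–Whitney) area, verified in the
tests against an exhaustive pairwise-ordering oracle; the confusion matrix
is taken at probability threshold 0.5.  Attribute relevance uses
information gain after Fayyad–Irani MDL entropy discretization, written by
hand (the recursion accepts a cut only when the gain exceeds
(log2(N−1) + Δ)/N) and bounded in the tests by brute-force single-split
enumeration.

## Annotation statistics

Bound calls are categorized against orthogonal peak sets as training /
peak-discovered (anchor within 50 bp of a peak) / new, assigned the nearest
TSS (ties break to the lexicographically smaller gene id), and summarized
as signed TSS-distance histograms (negative = upstream of the gene).
Gene-set overlaps use the exact hypergeometric upper tail
P(overlap ≥ observed), cross-checked by exhaustive subset enumeration on
small universes.  Differential-expression filters are strict (p < 1e−6,
|log2 ratio| ≥ 0.5) with ANY-condition union semantics.

## Cross-TF atlas

Each factor contributes its per-site average induction at the 12 offsets
−5.5 … +5.5.  Rows are embedded with seeded UMAP (2 components); an
externally computed 12-value profile (e.g. from capture-based data in
another organism) can be appended and embedded jointly.

## Simulator

The generative model is deliberately minimal — every property used in an
assertion is analytically available:

- i.i.d. genome of configurable length (default 100 kb) and GC fraction
  (0.40); non-overlapping ORFs (20 × 4 kb) with equal gaps;
- bound motif instances planted in the inter-ORF gaps (30 bp pitch, 12 bp
  clearance, random strand; default 40) and unbound decoys deep inside
  ORFs (≥ 100 bp margin; default 5,000);
- every dipyrimidine on either strand draws Poisson counts with rate
  λ = depth · w / Z, where w is a per-dinucleotide propensity
  (TT 1.0, TC 0.5, CT 0.15, CC 0.1) and Z the genome-wide weight sum;
  depth defaults to the value that sets the median per-dipyrimidine naked
  rate to 20;
- the cellular rate is multiplied by the fingerprint modulation
  (−1.5 → 0.3, +0.5 → 3.0, +2.5/+3.5/+4.5 → 0.5) only at bound-site
  offsets, so E[cellular − naked] = λ(m − 1) there — the identity the
  acceptance tests check to within 3 standard errors.

Out of scope by design: sequencing error, alignment ambiguity, and UV-dose
response.  Problem sizes (20-seed recovery sweeps, 100 kb genomes, 5,040
training instances) were chosen so the full suite runs on one CPU in about
ten minutes.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng` and the scikit-learn `random_state` plumbing.
Every CLI artifact starts with a header carrying the version, seed, and a
SHA-256 hash of the effective parameters, and identical invocations
reproduce outputs byte for byte.
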