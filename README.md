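# cpdfingerprint

Map UV-induced DNA damage at single-nucleotide resolution and use the
position-specific damage pattern around transcription-factor motifs — the
**CPD fingerprint** — to call which motif occurrences are actually bound in
living cells.

## The scientific problem

UV light crosslinks adjacent pyrimidines on the same DNA strand into
cyclobutane pyrimidine dimers (CPDs, at TT/TC/CT/CC dinucleotides).
CPD-seq reads out each lesion's position: sequencing reads start immediately
3′-adjacent to the lesion on the opposite strand, so every lesion is located
*between* two bases and is recorded at a half-integer coordinate (a dimer on
the plus strand spanning bases 10 and 11 sits at position 10.5).

A protein bound to DNA changes how UV damages the DNA underneath it.
Comparing lesion counts in irradiated cells against irradiated naked
(protein-free) DNA gives the **damage induction** at each position:

```
induction      = cellular_count − scaled_naked_count
log2_floored   = log2(max(cellular, 10) / max(scaled_naked, 10))
```

where the naked track is first scaled so both samples have the same total
dipyrimidine read count.  Around a bound motif the induction profile shows a
reproducible pattern of enhanced and suppressed positions — e.g. for the
CCAAT motif of the Hap2/3/5 complex, strong induction at motif-frame offset
+0.5 and suppression at −1.5, +2.5, +3.5 and +4.5 (offsets are half-integers
relative to the motif anchor; minus-strand sites are mirrored through the
anchor).  Those per-offset values, in both channels, form a 10-attribute
feature vector that a classifier (random forest, multilayer perceptron,
logistic regression, or naive Bayes) uses to separate bound sites from the
thousands of unbound motif matches, with stratified cross-validation and
rank-based AUC as the evaluation.

Because real deep-sequencing data sets are far beyond desk scale, the
package ships a generative simulator that plants bound motifs between
synthetic ORFs, plants unbound decoys deep inside them, draws Poisson lesion
counts with per-dinucleotide propensities, and multiplies the cellular rate
by the fingerprint modulation only at bound sites — providing exact ground
truth for every downstream claim.

## Worked example

Lesion positioning is exact and hand-checkable.  A minus-strand read whose
5′ end is at base 9 implies a plus-strand dimer over bases 10–11:

```python
from cpdfingerprint.genome_io import GenomeSequence, GenomicInterval
from cpdfingerprint.lesion_map import reads_to_lesions

genome = GenomeSequence({"chr1": "G" * 10 + "TT" + "G" * 10})
read = GenomicInterval("chr1", 5, 10, "-", "r1")
print(reads_to_lesions([read], genome).counts)
```

```
{('chr1', '+', 10.5): 1}
```

A full simulated study — 100 kb genome, 40 planted bound CCAAT sites, 5,000
intragenic decoys, auto-calibrated sequencing depth — runs in under a
minute:

```python
from cpdfingerprint import classify, pipeline
from cpdfingerprint.simulate import SimConfig, simulate

cfg = SimConfig(seed=1)
truth = simulate(cfg)
track = pipeline.induction_from_truth(truth)
ts = pipeline.truth_training_set(truth, track)
report = classify.cross_validate(ts, "random_forest", k=5, seed=1)
print(f"AUC {report.auc:.3f}  sensitivity {report.sensitivity:.2f}  "
      f"specificity {report.specificity:.4%}")
print(f"null AUC {pipeline.null_auc(cfg):.3f}")
```

```
AUC 1.000  sensitivity 1.00  specificity 100.0000%
null AUC 0.492
```

The planted fingerprint is strong enough that the forest recovers all 40
bound sites with zero decoy false positives, while the no-modulation null
collapses to chance (AUC 0.492).  Ranking the 10 attributes by
MDL-discretized information gain puts the +0.5 induction channel first
(gain 0.0668), matching the planted enhancement at that offset.

The same pipeline is available as composable commands:

```bash
cpdfp simulate --seed 1 --out-dir sim/
cpdfp induction --cellular sim/cellular.track.tsv --naked sim/naked.track.tsv --out ind.tsv
cpdfp cv --induction ind.tsv --genome sim/genome.fa \
         --positives sim/bound_sites.tsv --orfs sim/orfs.bed --out cv.tsv
```

Every tabular output begins with a comment header carrying the package
version, the seed, and a hash of the effective parameters; rerunning a
command with identical inputs reproduces the file byte for byte.

## Package layout

| module        | contents                                                       |
|---------------|----------------------------------------------------------------|
| `genome_io`   | FASTA/BED/GFF parsing, IUPAC motif scanning on both strands    |
| `lesion_map`  | read→lesion assignment, replicate merging, normalization, wig  |
| `fingerprint` | induction channels, motif-frame site and aggregate profiles    |
| `classify`    | feature schemas, training sets, info gain, CV, genome scoring  |
| `annotate`    | peak-overlap categories, nearest-TSS genes, DE overlap tests   |
| `tf_atlas`    | cross-TF profile matrix and seeded UMAP embedding              |
| `simulate`    | generative model with exact ground truth, read emission        |
| `cli`         | `cpdfp` command group over a YAML config                       |

See `docs/methods.md` for the quantitative conventions (coordinate system,
normalization, classifier hyperparameters, simulator design) and their
rationale.

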