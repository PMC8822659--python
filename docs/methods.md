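# Methods

This note records the model, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data tests do and do not
demonstrate.

## Dissimilarity representation

A query protein is represented not by its own residues but by its
similarity to every sequence of the curated TF database. For query *q*
and database sequence *d*, the feature is the normalized bit score

    x_q[d] = min( S'(q,d) / S'(q,q), 1 ),   x_q[d] = 0 when no hit survives,

where S' is the bit score of the optimal local alignment. Dividing by
the query's self-alignment bit score bounds features in [0, 1] and makes
a database member's own column exactly 1; encoding missing hits as 0
treats "no detectable similarity" as maximal distance. The denominator
is a design choice of this package — other normalizations (e.g. by the
subject's self score, or min/max of both) would also bound the value;
the query-side choice keeps a row's scale independent of which database
sequence it is compared against.

### Alignment backend

The reference backend computes optimal Smith–Waterman local alignments
with BLOSUM62 and affine gap costs (a gap of length k costs 11 + k),
using Bio.Align.PairwiseAligner for the DP itself. Raw scores are
converted to bits with Karlin–Altschul statistics using the standard
gapped BLOSUM62 constants λ = 0.267, K = 0.041:

    S' = (λS − ln K) / ln 2,     E = m · N · 2^(−S'),

with search space m·N = query length × total database residues. Both
constants and the search-space convention are configurable on
`AlignerParams`; they are conventions, not fitted values. Hits must
satisfy identity ≥ 20 % (identities / alignment columns, gaps included)
and E ≤ 10⁻¹⁰; at most 10,000 hits per query are kept, ties broken by
(bit score desc, subject id asc) for determinism. The deliberately
relaxed identity floor together with the stringent e-value means the
e-value does nearly all the filtering: unrelated random proteins
essentially never reach the ≈ 56 bits that an e-value of 10⁻¹⁰ demands
at fixture scale.

An external `blastp` backend (`AlignerParams(backend="blast")`) is wired
for large inputs and must honour the same threshold contract; the test
suite checks the built-in backend against an independent brute-force
Gotoh DP written in the tests, so implementation and oracle remain
separate routes.

## Classifier

A feed-forward network maps the feature vector through **four dense
hidden layers** (depth is fixed by design) with ReLU activations to a
softmax over TF families, trained with cross-entropy. Unstated
hyper-parameters were chosen small and are all configurable and recorded
in the model's provenance:

| parameter | default | rationale |
|---|---|---|
| hidden widths | 0.5/0.25/0.1/0.05 × input dim, min 16 | geometric taper to "dense and abstract" features |
| optimizer | Adam, lr 1e-3 | robust default for small dense nets |
| epochs / batch | 200 / 32 | converges on fixture-scale feature matrices |
| class weights | inverse-frequency, on | TF family sizes are highly skewed in real databases |
| prob_threshold | 0.5 | calls below it are TF-unclassified rather than forced into a family |
| self-hits in training features | retained | the representation is defined against *all* database sequences; a flag removes them |

The network is implemented directly on numpy so that training is
bit-reproducible given (database, config, seed) and saved bundles
(JSON manifest + npz weights + the training database) round-trip to
bit-identical predictions; the manifest embeds a SHA-256 digest of the
weights so corruption is detected at load.

Non-TF rejection is two-staged: a query with zero surviving alignment
hits is `non-TF` before the network runs (the softmax otherwise has no
abstain option), and a best-family probability below the threshold
yields `TF-unclassified`. Both knobs are explicit because neither stage
has a canonical setting.

## Database curation

Sources are local exports: FASTA plus TSV metadata. CollecTF-like
records default to evidence EV (experimentally validated), UniProt-like
to PU (putative) unless an evidence column says otherwise. Curation
drops records without a family, normalizes family labels (strip header
artifacts, collapse whitespace, casefold) and de-duplicates on (exact
sequence, normalized family), preferring EV over PU, then first-seen.
The same sequence under two distinct families is deliberately kept
twice — collapsing it would require deciding which family is right.
Provenance counters satisfy merged = kept + dropped_no_family +
dropped_duplicate, and curation is idempotent. Taxonomy comes from the
metadata columns only; leave-taxon-out subsetting (`exclude_taxon`)
matches genus or taxonomic family case-insensitively and labels the
subset `no-<name>`.

## Six-frame translation and back-mapping

Frames 1–3 are forward offsets 0–2; frames 4–6 the same offsets on the
reverse complement (EMBOSS transeq suffix dialect). Codons containing N
translate to X; stops are `*` internally and never appear in emitted
peptides. Frame translations are split at stop codons and fragments
shorter than 60 aa dropped before prediction — splitting avoids
chimeric queries spanning gene boundaries; the cutoff (and splitting
itself, `--no-orf-split`) is configurable, and 60 aa is roughly the
smallest complete DNA-binding domain. Coordinates are 0-based
half-open; the back-mapping arithmetic is validated by an exhaustive
property: extract + re-translate equals the source peptide for every
peptide of ≥ 1,000 random contigs in all six frames.

## Expression mapping

A region's read count includes primary, mapped alignments with ≥ 1
aligned base overlapping the region; secondary/supplementary records
are excluded, duplicates kept. Covered fraction is the union of aligned
intervals clipped to the region over region length. The default
expression call is ≥ 1 read and no coverage floor — a deliberate
weakest-useful-default since no canonical threshold exists; both knobs
(`min_reads`, `min_covered_fraction`) are recorded in output metadata,
and expressed counts are monotone non-increasing in both. Family ×
sample matrices are clustered after log1p on rows and columns with
average-linkage Euclidean distance; labels are sorted before linkage so
leaf order is deterministic, and dendrograms export as Newick.

## Evaluation metrics

Performance = 100 × predicted/annotated; accuracy = 100 ×
correct/predicted on the EV and PU partitions of the predictions
(partitioned by the *reference's* evidence class; queries absent from
the reference fall in the EV partition and count as incorrect).
"Correct" means: the reference marks the query a TF and, when both
sides carry a family label, the normalized labels match — the
comparator is a plain function argument and can be swapped. A TF
predicted with the wrong family counts as both a false positive and a
missed annotation, which keeps tp + fn equal to the reference
positives. 0/0 precision/recall/F1 cases are defined as 0; an undefined
putative accuracy renders as an em dash. Percentages are rounded
half-up to 2 decimals only at rendering.

## Synthetic data: what it does and does not show

The generator grows each family from one uniform-random ancestor by
independent per-site substitutions (default study scale: 10 families ×
20 members, 150 aa, 5 % per-site mutation; two members then share
≈ 90.3 % identity in expectation). Genes are reverse-translated with
uniformly random synonymous codons, embedded between random spacers on
either strand, and reads are placed uniformly inside chosen regions and
written as plain SAM (flag 0/16 semantics, constant qualities).

This emulates the *structure* of the problem — families that are tight
clusters in alignment space, genes recoverable from six-frame
translation, expression decidable from coverage — but not real data's
difficulties: real TF families share DNA-binding domains across family
boundaries, real databases have label noise and wildly skewed family
sizes, real contigs contain overlapping genes and frameshifts, and real
reads have errors, pairs, and uneven coverage. Passing the recovery
tests therefore demonstrates that the pipeline's machinery is correct
and self-consistent, not that the accuracy figures transfer to real
(meta)genomes.

Problem sizes in the test suite and acceptance script (held-out split
160/40, one excluded genus of 40 members, 100 negatives, 30 embedded
genes, 1,000 random contigs/cases) were chosen as the smallest scales at
which the measured rates are stable across seeds.

## Known limitations

- The aligner is exact but O(mn) per pair; for large metagenomes use
  the blastp backend (identical contract, heuristic seeding).
- No per-family probability calibration beyond the single threshold.
- Expression profiling does not model multi-mapping reads or
  strandedness, and performs no differential-expression statistics.
- BED round-trips recover '-'-strand frames only when contig lengths
  are supplied (frame is not representable in BED6).
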