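# Methods

## Model

`mitannot` treats annotation as label transfer. The reference database is a
set of annotated mitogenomes represented by their (k+1)-mer content — the
edge set of a de Bruijn graph over the collection, kept as an occurrence
index rather than an explicit graph: per canonical (k+1)-mer (lexicographic
minimum of the string and its reverse complement) the list of
(genome, position, orientation) occurrences, each carrying the annotations
overlapping its footprint and the footprint sub-range they cover. The two
representations support the same queries; the index form is simpler to
persist and to diff.

Mapping transfers labels position-exactly: an input (k+1)-mer at position
`p` whose edge weight (distinct genomes containing it) reaches the
`edge_weight` threshold marks, for each occurrence label, the input
positions corresponding to the annotated part of the footprint. Transferring
labels per position rather than to the whole footprint keeps self-matches
boundary-exact and prevents labels bleeding `k` nt into neighbouring genes.
Orientation is resolved through the canonical form; with the default odd
edge length (k+1 = 25) a (k+1)-mer can never equal its own reverse
complement, so orientation is unambiguous (even lengths record
self-complementary edges as forward).

Per (reference genome, gene, strand), maximal runs of labelled positions
become interval predictions; runs separated by an unlabelled gap of at most
`gap_bridge` nt are merged. This positional gap-merging stands in for
bridging unmatched regions through the graph; at the scale of a single
mitogenome the two are functionally equivalent, and the parameter retains
the observable behaviour that raising `edge_weight` creates more unmatched
regions to bridge.

Per gene, predictions from different references are clustered by
agglomerative average linkage on d(a, b) = 1 − positional Jaccard overlap
(positions taken modulo the sequence length so wrapped intervals compare
correctly), and the dendrogram is cut at `cluster_cut`. A cluster's relative
frequency is its share of the gene's predictions; clusters reaching
`alpha` × the maximum relative frequency are selected, so `alpha = 0` keeps
every cluster and `alpha = 1` only the maximal ones (ties all kept). The
consensus interval is the member-wise lower-median start and end; the strand
is the member majority, ties to `+`. The linkage choice, the cut, and the
median consensus are this package's own concrete instantiation of a
"cluster the predictions, select by relative frequency" routine; they are
isolated behind `cluster_and_select` so they can be swapped.

## Taxonomic filter

The taxonomy is a rooted tree in NCBI style: every node points to its
parent, the root is its own parent, nodes carry scientific names, synonyms,
common names, and the labels of reference genomes classified there. Name
lookup is a normalized-name dictionary (case-fold, collapse whitespace);
exact matches precede prefix matches. The LCA of several taxa is found by
intersecting root-paths and taking the deepest shared node; a single taxon
is its own LCA. The filter extracts the genome labels in the LCA's subtree:
include keeps exactly those, exclude keeps the complement, so the two modes
partition the reference set. A multi-taxon include filter deliberately uses
the LCA's subtree, not the union of the taxa's subtrees — "include A and B"
therefore also admits everything between them. An include filter that
leaves no genomes is an error, since annotation cannot proceed.

## Boundary correction

Reference-transferred protein boundaries are often a few nt off the true
initiation/termination codons. Given the input's NCBI translation table,
each boundary is re-examined in the gene's reading direction within a
window of `window` nt (default 6) each way, at every nucleotide offset (not
frame-locked — a mis-predicted boundary may itself be out of frame):

* a boundary already on a valid codon is kept;
* otherwise the valid codon at minimal |offset| wins; at equal distance the
  offset that extends the gene wins (upstream for starts, downstream for
  stops; configurable);
* an opposite-set codon in the examined region (a stop while searching for
  a start, a start while searching for a stop) restricts the search to
  offsets strictly downstream of the most downstream such codon — extending
  a start upstream past a stop would place a terminator in frame. With the
  shipped tables no codon is both a start and a stop; if a custom table had
  one, it would act as its own barrier and be skipped.

Start and stop move independently (corrected length need not stay ≡ 0 mod
3). Minus-strand genes are corrected on the reverse complement with
coordinates mapped back; on circular sequences the window may cross the
origin. Codons containing ambiguity codes never match either set, so
unknown bases cannot trigger shifts. In the degenerate case where the two
shifts would collapse an interval below one codon, the prediction is left
unchanged. The effect is quantified by codon precision: the fraction of
protein predictions whose first codon is an initiation codon (and last a
termination codon) of the table.

## Synthetic data

The simulator emulates exactly what the pipeline consumes. A random rooted
taxonomy (ids 1..n, parents drawn uniformly among earlier ids) gets unique
binomial-style names, occasional synonyms and common names. One ancestral
circular genome (default 16,500 nt — the average length of a complete
metazoan mitogenome — with 13 protein genes named after the canonical
mitochondrial complement, plus rRNA/tRNA genes) is placed at the root; each
protein gene starts with an initiation codon and ends with a termination
codon of the chosen table (default: table 2, vertebrate mitochondrial).
Sequences evolve along tree edges by per-site point substitutions at the
branch rate (default 1%), plus one private round per genome, so divergence
grows with tree distance. Substitutions only — no indels — so annotation
coordinates remain exact ground truth; an indel mode was deliberately left
out to keep every oracle exact.

Boundary perturbation shifts each protein boundary by a uniform signed
offset of 1..`perturbation_max` (≤ the correction window), rejecting offsets
whose window would be ambiguous: the original codon must remain the unique
nearest valid codon from the shifted position, and no opposite-set codon may
bar it. The recorded shifts are the oracle; correction must invert them
exactly. What passing these tests shows is that the machinery is correct
under the stated model; real mitogenomes add rearrangement, duplication,
indels, heteroplasmy and assembly artefacts that the simulator does not
model, so measured recall/precision here characterise the implementation,
not expected field performance.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k` | 24 | node k-mer size; indexed edges are 25-mers, near-unique in a 16.5-kb genome yet shared across relatives |
| `edge_weight` | 2 | min. genomes containing an input (k+1)-mer for it to vote |
| `prediction_count` | 2 | min. distinct genomes predicting a gene for it to be kept |
| `alpha` | 0.5 | cluster selection threshold relative to the most frequent cluster |
| `gap_bridge` | 2k | max. unmatched gap (nt) merged between runs of one (genome, gene, strand) |
| `cluster_cut` | 0.5 | Jaccard-distance cut of the per-gene dendrogram |
| `window` | 6 | boundary-correction search radius (nt) |
| `circular` | true | input treated as a circular molecule |

The thresholds default to 2 so that they are meaningful on small synthetic
families while remaining overridable; with `edge_weight` ≥ 2, (k+1)-mers
private to a single reference (e.g. carrying a private mutation) never vote.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive; origin-crossing genes are represented with end > length and
  written as two GFF3/BED parts sharing an ID.
* Cluster selection compares member counts (integers) with a 1e-9 slack so
  `alpha = 1` keeps all tied maximal clusters.
* All randomness flows through seeded NumPy generators; outputs are
  byte-reproducible. The index TSV is sorted and versioned for bit-exact
  diffing.
* Linear sequences: window candidates outside the sequence are skipped,
  never an error; a linear genome shorter than k+1 contributes nothing to
  the index (logged). (k+1)-mers containing N are excluded from the index
  and from voting.
* Genes predicted by zero references after filtering yield an empty result
  with a warning, not an error.

## Scale of the shipped checks

Tests and the acceptance script run on reduced problem sizes chosen as the
package's own desk-scale defaults: genomes of 6,000–16,500 nt, families of
4–5 genomes, 5–13 protein genes, 1,000-case oracle sweeps, 10 replicates
for the mutation-robustness estimate. All are regenerated from seeds at run
time; nothing is downloaded.

## Known limitations

* The reference-side behaviour is reconstructed at the level of its
  observable contract (mapping, bridging, counting, clustering semantics);
  explicit graph topology and succinct structures are out of scope.
* The simulator's substitution-only model cannot probe robustness to
  indels or rearrangement.
* BED output carries the gene kind in a seventh column — a private dialect
  read back by this package's own reader.
* Incomplete or misassembled input genomes are annotated on a best-effort
  basis only; nothing detects misassembly.
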