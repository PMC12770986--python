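# Methods

## Scope and pipeline

`panfam` turns a collection of annotated prokaryotic genomes into a
pangenome: a partition of genes into families plus a presence-band label
per family.  The pipeline is ingest → genome tagging → clustering →
genome tracing → band classification → outputs, with two shortcuts
(Partial mode starts from an existing clustering; Recluster mode starts
from a previous run plus new sequences).  Everything downstream of
clustering is a pure function of the clustering, which is what makes
Full/Partial mode equivalence exact and testable.

## Ingest and genome tagging

GFF3 is parsed directly as 9-column records; sequences come from the
embedded `##FASTA` block or a sibling `.fasta`/`.fna`/`.fa`.  Coordinates
stay 1-based inclusive throughout (the GFF3 convention); minus-strand
features are reverse-complemented on extraction, and CDS features are
translated with the bacterial code (table 11, overridable per run), the
terminal stop stripped and internal stops flagged but retained.  Two
deliberate simplifications:

* **Single-span features only.**  Joined (multi-span) CDS are vanishingly
  rare in prokaryotes; features sharing an ID are skipped with a logged
  warning rather than guessed at.
* **Non-coding features are DNA-only.**  Protein-space clustering silently
  excludes records without a translation.

Every gene ID is prefixed with its genome of origin plus a separator
(default `|`, configurable; a separator occurring inside a genome ID or a
resulting ID collision is a hard error).  The tagging scheme is this
package's own convention; the genome is always recoverable by splitting on
the first separator occurrence.

## The reference clusterer

Greedy incremental clustering with the two parameters every practitioner
knows from CD-HIT:

* `c` — identity threshold (fraction),
* `s` — length-difference cutoff: minimum shorter/longer length ratio.

Sequences are processed longest first (ties by ID); each joins the
earliest-founded representative passing both tests, else founds a new
cluster.  In DNA mode both strands are tried (the reverse complement only
when the forward strand fails the threshold, which cannot change the
accept/reject outcome).

**Identity definition.**  Matches are counted in the best local alignment
under match +1, mismatch −1, gap open −2, gap extend −1 (constants chosen
here and centralised in `reference_clusterer`; they are deliberately *not*
a reconstruction of any external tool's internal scoring).  The
denominator is the full length of the shorter sequence.  This has two
consequences worth understanding:

* a short sequence entirely contained in a longer one scores ~100%
  identity — the longer sequence's overhang costs nothing, which is
  exactly the local-overlap behaviour that lets a shared domain cluster
  genes of very different lengths once `s` is relaxed toward 0;
* a merely windowed similarity (a few dozen matching positions between
  otherwise unrelated genes) cannot reach a high percentage, because the
  denominator is the whole shorter gene.

A `strict_identity` mode adds internal alignment gap columns to the
denominator, for quantifying how much "gaps are free" inflates identity.

**Determinism.**  The clusterer holds no resource-dependent state: no
thread pools, no memory-bounded word tables, no input-order sensitivity
beyond the documented longest-first ordering.  Identical inputs and
parameters produce byte-identical `.clstr` files whatever thread or memory
budget the run configuration declares (those settings are recorded in
provenance and passed to external tools only).  `c` and `s` are normalised
to exactly two decimal places at ingest, so `0.9` and `0.90` are the same
parameterisation by construction.

**Word prefilter.**  Before aligning, candidate representatives are
screened by shared 8-mer count.  The threshold is a lower bound derived
from the identity threshold — with at most `(1−c)·L` differing positions,
each destroying at most `k` of the `L−k+1` windows, at least
`(L−k+1) − k·⌈(1−c)L⌉` windows must survive — halved as a safety margin
for gapped alignments.  The filter is a pure optimisation: tests verify
that disabling it does not change any partition.

## Band classification

A family present in `k` of `n` genomes has presence `100·k/n`, compared as
an exact rational (`fractions.Fraction`) against band lower bounds.  Bands
are lower-inclusive, the top band additionally contains exactly 100%.
Defaults: `First_core_99` `[99,100]`, `First_core_95` `[95,99)`,
`First_core_15` `[15,95)`, `First_core_0` `[0,15)` — the conventional
core / soft-core / shell / cloud scheme.  Exact arithmetic makes boundary
cases like 19/20 = 95% deterministic; there is no float rounding anywhere
in classification.  Schemes are user-definable as any strictly decreasing
bound list ending at 0, with names printed verbatim in outputs.

The `summary_statistics.txt` line `Total genes:` counts gene *families*
(the sum of the band counts), following the convention of the established
summary format this file mirrors; the total number of member sequences is
printed on a separate `Total gene sequences:` line.  The presence-absence
CSV uses the established quoted-CSV dialect with fixed leading columns and
one column per genome, member gene IDs tab-joined inside a cell.

## Reclustering

Given a first-round pangenome and a clustering of old + new sequences,
every combined cluster is mapped to the set of first-round families its
old members came from and labelled:

| track | condition |
|---|---|
| `only_second` | no old members |
| `combined` | ≥ 2 origin families |
| `extended` | band strictly higher than the single origin family's first-round band |
| `second` | band over old members alone (within the union genome set) strictly lower than the band over all members |
| `first` | none of the above |

Precedence is top-to-bottom.  The `second`/`extended` disambiguation is a
design decision this package fixes explicitly: `extended` compares against
the origin family's *first-round* band, `second` against the old members
re-evaluated over the union genome set — so `second` captures families
that hold their band only thanks to new members (typically when new
genomes joined the run), without having exceeded their first-round band.
Bands are always computed over the union genome set; first-round records
are never mutated.  An origin family whose members scatter over several
combined clusters is *fragmented*: this is reported as an explicit
origin→cluster fan-out table rather than being folded into the four
tracks, because a fragmentation is a clustering outcome, not a category of
family.

## Robinson–Foulds concordance

Trees are parsed with dendropy; split extraction and the distance are
computed here by explicit traversal.  A split is a non-trivial bipartition
encoded as the side not containing the lexicographically smallest leaf
(rooting-independent).  `rf = |S1 Δ S2|`; `max_rf = |S1| + |S2|`, which
equals `2(n−3)` per tree only for fully binary trees and remains a true
maximum for multifurcations — normalised values are therefore comparable
across tools only when the normaliser is stated, which is why it is stated
here.  Two star trees (no non-trivial splits) are defined to have distance
0.  RF analysis is intended for single-copy core families: representative
selection enforces one gene per genome, and the `longest` policy is the
field's default precisely so that its pathology (a lone long outlier
elected over dozens of typical-length members) can be reproduced and
contrasted with `medoid_length`, which minimises summed absolute length
deviation over the family.

## Diagnostics

`group_summary` reports, per cluster: member count, genome count, mean
length (2 dp), length range, mean identity (2 dp).  The representative has
no printed identity in `.clstr` files; by default it enters the mean as
100.00 (it is trivially identical to itself), and a flag excludes it —
both conventions exist in the wild and the table header does not say which
is in use, so this package makes it a parameter.

`compare_partitions` diffs two clusterings restricted to their shared
universe: `moved_genes` (co-member set changed), `pairwise_disagreement`
(gene pairs co-clustered in exactly one run; computed from cluster-overlap
counts `Σ C(n_a,2) + Σ C(n_b,2) − 2 Σ C(n_ab,2)`, identical to exhaustive
enumeration), and split/merge events counted as clusters of one run whose
members occupy more than one cluster of the other.  Other event
definitions exist (e.g. on a maximum-weight matching); the fan-out
definition is used because it is symmetric, cheap, and counts exactly the
clusters a reviewer would need to inspect.

`find_sequence` resolves CD-HIT-truncated IDs by prefix matching and flags
ambiguity when a query prefix-matches more than one stored ID.

## Synthetic pangenomes

The generator emulates the *identity structure* of a pangenome, nothing
more: random-uniform nucleotide ancestors of 300–1500 nt (codon-aligned),
one mutated copy per carrying genome at `mutation_rate` per-site
substitutions (default 0.01 — two copies then differ by ~2%, comfortably
above a 0.90 identity threshold, while unrelated families sit at the ~25%
random background), core families in all genomes, accessory presence drawn
uniformly from 10–90% of genomes.  Paralogs are modelled as a second
independently mutated copy; fragmentation as a codon-aligned uniform cut
into two partial genes.  Default sizes (20 genomes, 100 core + 50
accessory) are the package's standard study condition: large enough that
every band is populated and boundary cases occur, small enough that the
full pipeline runs in tens of seconds on one CPU.

What this does **not** emulate: real gene length/GC distributions, indels,
recombination or HGT, shared domains between families, annotation noise.
Passing the planted-recovery tests therefore shows that the machinery is
correct under separable identity structure — it does not certify clustering
accuracy on real genomes, where family boundaries are genuinely ambiguous.

Second-round fixtures plant the three tracked outcomes: gap-fillers
(ancestor copies for genomes missing the lowest-presence accessory
family → `extended`), a bridge (concatenation of two accessory ancestors,
one copy per genome carrying either family → `combined`), and a novel
family in every genome (→ `only_second`).  Recluster fixtures are
clustered at `s = 0.00`: the bridge is roughly twice as long as the
families it spans, so any non-trivial length cutoff would veto the merge —
relaxing `s` is precisely the regime in which long second-round sequences
reshape pangenomes.

Generation is a pure function of the spec including its seed; the same
spec writes byte-identical files.

## Numerical and formatting choices

* Band bounds and presence percentages: exact rationals, no tolerance.
* Identities in `.clstr`: printed and parsed at two decimals, never
  recomputed on read.
* Representative of edge-list clusters: longest member if lengths are
  known, else lexicographically smallest ID (edge lists carry neither
  representative nor identity information, so the choice is declared).
* Family IDs `group_<k>` in cluster order; presence-absence rows sorted by
  (descending genome count, family index).
* Greedy tie-breaks: sequence processing by (length desc, ID asc);
  equal-score alignment tracebacks resolved by the aligner's deterministic
  first path.
* Degenerate inputs: empty clustering → header-only outputs and zero
  totals; empty sequence → hard error in alignment; trees with < 3 leaves
  → RF undefined, hard error.

## Known limitations

* The built-in clusterer aims at semantic transparency, not performance
  parity with production clusterers; its complexity is O(sequences ×
  surviving candidates × alignment), practical to a few thousand genes.
* External-tool identities (e.g. CD-HIT's per-mode identity definition)
  are treated as observed behaviour, not reproduced; imported `.clstr`
  identities are taken as printed.
* Multi-span CDS and alternative genetic codes beyond a per-run table
  override are out of scope.
* The chi-square style functional-shift analyses on external annotations,
  and synteny-aware paralog splitting, are deliberately not implemented:
  they belong to the external tools whose behaviour this package is built
  to interrogate.
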