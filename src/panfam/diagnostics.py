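"""Interrogation utilities: cluster summaries, sequence lookup, run diffs.

Three tools for exposing what a clustering actually did:

* :func:`group_summary` — per-cluster statistics (member count, genome
  count, mean/range of lengths, mean identity) in the style of a
  group-summary table; sorting by descending size surfaces the large,
  length-diverse clusters that local-overlap identity permits when the
  length-difference cutoff is relaxed.
* :func:`find_sequence` — locate a gene ID across heterogeneous output
  artifacts (``.clstr`` files, presence-absence CSVs, family FASTAs),
  resolving CD-HIT-truncated IDs by prefix matching.
* :func:`compare_partitions` — a structural diff of two clusterings of the
  same genes: preserved clusters, split/merge events, the set of genes
  whose co-membership changed, and the pairwise disagreement count (gene
  pairs co-clustered in exactly one of the two runs).  This is the
  instrument for demonstrating that a clusterer's output depends on
  resource parameters that should be semantically inert.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable

from .cluster_io import ClusterSet, parse_clstr
from .seq_ingest import DEFAULT_SEPARATOR, split_tagged_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSummaryRow:
    cluster_id: int
    n_seqs: int
    n_genomes: int
    avg_len: float
    len_range: tuple[int, int]
    avg_ident: float


def group_summary(
    cs: ClusterSet,
    separator: str = DEFAULT_SEPARATOR,
    include_representative_identity: bool = True,
) -> list[ClusterSummaryRow]:
    """One summary row per cluster, sorted by descending member count.

    The representative carries no printed identity in ``.clstr`` files; by
    default it is counted as 100.00 in ``avg_ident`` (it is trivially
    identical to itself).  Set ``include_representative_identity=False`` to
    average over non-representative members only.
    """
    rows: list[ClusterSummaryRow] = []
    for c in cs.clusters:
        lengths = [m.length for m in c.members]
        idents = [
            100.0 if m.is_representative else m.identity_pct
            for m in c.members
            if include_representative_identity or not m.is_representative
        ]
        genomes = set()
        for m in c.members:
            try:
                genomes.add(split_tagged_id(m.seq_id, separator)[0])
            except Exception:
                genomes.add(m.seq_id)  # untagged input: every id its own genome
        rows.append(
            ClusterSummaryRow(
                cluster_id=c.index,
                n_seqs=len(c.members),
                n_genomes=len(genomes),
                avg_len=round(sum(lengths) / len(lengths), 2),
                len_range=(min(lengths), max(lengths)),
                avg_ident=round(sum(idents) / len(idents), 2) if idents else 0.0,
            )
        )
    rows.sort(key=lambda r: (-r.n_seqs, r.cluster_id))
    return rows


def write_group_summary(rows: Iterable[ClusterSummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ID\t# Seqs\t# Genomes\tAvg len\tLen range\tAvg ident\n")
        for r in rows:
            fh.write(
                f"{r.cluster_id}\t{r.n_seqs}\t{r.n_genomes}\t{r.avg_len:.2f}\t"
                f"{r.len_range[0]}-{r.len_range[1]}\t{r.avg_ident:.2f}\n"
            )


@dataclass(frozen=True)
class SequenceLocation:
    file: str
    container: str  # cluster index, family id, or record position
    role: str  # "representative" | "member" | "cell" | "fasta_record"
    matched_id: str
    ambiguous: bool = False


def _clstr_hits(query_id: str, path: Path) -> list[SequenceLocation]:
    cs = parse_clstr(path)
    hits: list[SequenceLocation] = []
    prefix_matches: list[tuple[int, str, bool]] = []
    for c in cs.clusters:
        for m in c.members:
            # stored IDs may be truncated by the producer: prefix match
            if m.seq_id == query_id or (
                m.seq_id != query_id and query_id.startswith(m.seq_id)
            ):
                prefix_matches.append((c.index, m.seq_id, m.is_representative))
    ambiguous = len({sid for _, sid, _ in prefix_matches}) > 1
    if ambiguous:
        logger.warning(
            "%s: query %r prefix-matches %d distinct stored ids",
            path,
            query_id,
            len({sid for _, sid, _ in prefix_matches}),
        )
    for idx, sid, is_rep in prefix_matches:
        hits.append(
            SequenceLocation(
                file=str(path),
                container=f"cluster {idx}",
                role="representative" if is_rep else "member",
                matched_id=sid,
                ambiguous=ambiguous and sid != query_id,
            )
        )
    return hits


def _csv_hits(query_id: str, path: Path) -> list[SequenceLocation]:
    hits: list[SequenceLocation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        for row in reader:
            for cell in row[1:]:
                if query_id in cell.split("\t"):
                    hits.append(
                        SequenceLocation(
                            file=str(path),
                            container=row[0] if row else "?",
                            role="cell",
                            matched_id=query_id,
                        )
                    )
                    break
    return hits


def _fasta_hits(query_id: str, path: Path) -> list[SequenceLocation]:
    hits: list[SequenceLocation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">") and line[1:].split()[0] == query_id:
                hits.append(
                    SequenceLocation(
                        file=str(path),
                        container=path.stem,
                        role="fasta_record",
                        matched_id=query_id,
                    )
                )
    return hits


def find_sequence(
    query_id: str, artifacts: Iterable[str | Path]
) -> list[SequenceLocation]:
    """Locate ``query_id`` across output artifacts.

    Recognised formats by extension: ``.clstr``, ``.csv`` (presence-absence),
    ``.fasta``/``.fa``/``.fna``/``.faa``.  Unrecognised files produce a
    per-file warning, never a failure.  An empty result means "not found".
    """
    hits: list[SequenceLocation] = []
    for raw in artifacts:
        path = Path(raw)
        suffix = path.suffix.lower()
        try:
            if suffix == ".clstr":
                hits.extend(_clstr_hits(query_id, path))
            elif suffix == ".csv":
                hits.extend(_csv_hits(query_id, path))
            elif suffix in (".fasta", ".fa", ".fna", ".faa"):
                hits.extend(_fasta_hits(query_id, path))
            else:
                logger.warning("find_sequence: unrecognised file type %s", path)
        except OSError as exc:
            logger.warning("find_sequence: cannot read %s: %s", path, exc)
    return hits


@dataclass
class PartitionDiff:
    preserved: int
    split_events: int
    merge_events: int
    moved_genes: set[str] = field(default_factory=set)
    pairwise_disagreement: int = 0

    @property
    def identical(self) -> bool:
        return (
            self.split_events == 0
            and self.merge_events == 0
            and not self.moved_genes
            and self.pairwise_disagreement == 0
        )


def compare_partitions(a: ClusterSet, b: ClusterSet) -> PartitionDiff:
    """Structural diff between two clusterings of the same gene universe.

    If the universes differ, the comparison is restricted to their
    intersection with a logged warning.  ``moved_genes`` are the IDs whose
    co-member set changed; ``pairwise_disagreement`` counts unordered gene
    pairs co-clustered in exactly one run (computed from cluster-overlap
    counts, equivalent to enumerating all pairs); ``split_events`` counts
    clusters of ``a`` whose members occupy more than one cluster of ``b``,
    and ``merge_events`` the converse.
    """
    ua, ub = a.universe, b.universe
    common = ua & ub
    if ua != ub:
        logger.warning(
            "compare_partitions: universes differ (%d only in a, %d only in b); "
            "restricting to %d shared ids",
            len(ua - ub),
            len(ub - ua),
            len(common),
        )

    groups_a = [
        frozenset(sid for sid in c.seq_ids if sid in common) for c in a.clusters
    ]
    groups_b = [
        frozenset(sid for sid in c.seq_ids if sid in common) for c in b.clusters
    ]
    groups_a = [g for g in groups_a if g]
    groups_b = [g for g in groups_b if g]

    set_b = {g for g in groups_b}
    preserved = sum(1 for g in groups_a if g in set_b)

    group_of_b: dict[str, int] = {}
    for j, g in enumerate(groups_b):
        for sid in g:
            group_of_b[sid] = j
    group_of_a: dict[str, int] = {}
    for i, g in enumerate(groups_a):
        for sid in g:
            group_of_a[sid] = i

    moved: set[str] = set()
    for g in groups_a:
        for sid in g:
            peers_a = g - {sid}
            peers_b = groups_b[group_of_b[sid]] - {sid}
            if peers_a != peers_b:
                moved.add(sid)

    # overlap counts n_ij between a-cluster i and b-cluster j
    overlap: dict[tuple[int, int], int] = {}
    for sid in common:
        key = (group_of_a[sid], group_of_b[sid])
        overlap[key] = overlap.get(key, 0) + 1

    same_a = sum(comb(len(g), 2) for g in groups_a)
    same_b = sum(comb(len(g), 2) for g in groups_b)
    same_both = sum(comb(n, 2) for n in overlap.values())
    disagreement = same_a + same_b - 2 * same_both

    fanout_a: dict[int, set[int]] = {}
    fanout_b: dict[int, set[int]] = {}
    for i, j in overlap:
        fanout_a.setdefault(i, set()).add(j)
        fanout_b.setdefault(j, set()).add(i)
    split_events = sum(1 for targets in fanout_a.values() if len(targets) > 1)
    merge_events = sum(1 for sources in fanout_b.values() if len(sources) > 1)

    return PartitionDiff(
        preserved=preserved,
        split_events=split_events,
        merge_events=merge_events,
        moved_genes=moved,
        pairwise_disagreement=disagreement,
    )
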