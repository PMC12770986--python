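"""Clustering-result I/O: CD-HIT ``.clstr`` files and generic edge lists.

A clustering is represented as a :class:`ClusterSet`: an ordered partition of
sequence IDs into clusters, each with exactly one representative.  Cluster
sets come from three places — CD-HIT's ``.clstr`` report, two-column
tab-separated edge lists (the first two columns of BLAST outfmt 6 are
accepted), or the built-in greedy clusterer — and all downstream pangenome
inference consumes the same structure.

The ``.clstr`` dialect parsed and emitted here::

    >Cluster 0
    0	291nt, >genomeA|gene1... *
    1	249nt, >genomeB|gene7... at +/98.39%

Member IDs are stored exactly as printed (CD-HIT truncates long headers at
the ``...``); resolving truncated IDs back to full ones is the job of the
diagnostics Seq-Finder, which does prefix matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx


class ClusterFormatError(ValueError):
    """Raised for malformed cluster files or invalid cluster sets."""


@dataclass(frozen=True)
class ClusterMember:
    """One sequence inside a cluster.

    ``identity_pct`` is the percent identity to the representative as printed
    (two decimals); it is ``None`` on the representative itself.  ``strand``
    is only present for nucleotide clustering.
    """

    seq_id: str
    length: int
    identity_pct: float | None = None
    strand: str | None = None
    is_representative: bool = False


@dataclass
class Cluster:
    index: int
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def representative(self) -> ClusterMember:
        reps = [m for m in self.members if m.is_representative]
        if len(reps) != 1:
            raise ClusterFormatError(
                f"cluster {self.index} has {len(reps)} representatives (need 1)"
            )
        return reps[0]

    @property
    def representative_id(self) -> str:
        return self.representative.seq_id

    @property
    def seq_ids(self) -> list[str]:
        return [m.seq_id for m in self.members]


@dataclass
class ClusterSet:
    """An ordered partition of sequence IDs into clusters."""

    clusters: list[Cluster] = field(default_factory=list)

    @property
    def universe(self) -> set[str]:
        return {m.seq_id for c in self.clusters for m in c.members}

    def validate(self) -> None:
        """Assert the partition invariant and one-representative rule."""
        seen: set[str] = set()
        for c in self.clusters:
            if not c.members:
                raise ClusterFormatError(f"cluster {c.index} has zero members")
            c.representative  # raises if not exactly one
            for m in c.members:
                if m.seq_id in seen:
                    raise ClusterFormatError(
                        f"sequence {m.seq_id!r} appears in more than one cluster"
                    )
                seen.add(m.seq_id)

    def membership(self) -> dict[str, int]:
        """seq_id -> cluster index map."""
        return {m.seq_id: c.index for c in self.clusters for m in c.members}


_MEMBER_RE = re.compile(
    r"^(\d+)\t(\d+)(aa|nt), >(.*?)(\.\.\.)? (\*|at (?:([+-])/)?([\d.]+)%)\s*$"
)


def parse_clstr(path: str | Path) -> ClusterSet:
    """Read a CD-HIT ``.clstr`` file into a :class:`ClusterSet`.

    Lengths, per-member identities, strands and the ``*`` representative
    flag are captured; identities are kept to the two decimals printed, never
    recomputed.  A cluster without exactly one representative is an error.
    """
    path = Path(path)
    cs = ClusterSet()
    current: Cluster | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">Cluster"):
                if current is not None:
                    _close_cluster(current, path, lineno)
                try:
                    idx = int(line.split()[1])
                except (IndexError, ValueError) as exc:
                    raise ClusterFormatError(
                        f"{path}:{lineno}: bad cluster header {line!r}"
                    ) from exc
                current = Cluster(index=idx)
                cs.clusters.append(current)
                continue
            m = _MEMBER_RE.match(line)
            if m is None or current is None:
                raise ClusterFormatError(
                    f"{path}:{lineno}: unparseable member line {line!r}"
                )
            _, length, _unit, seq_id, _dots, flag, strand, pid = m.groups()
            is_rep = flag == "*"
            current.members.append(
                ClusterMember(
                    seq_id=seq_id,
                    length=int(length),
                    identity_pct=None if is_rep else float(pid),
                    strand=strand,
                    is_representative=is_rep,
                )
            )
    if current is not None:
        _close_cluster(current, path, lineno)
    cs.validate()
    return cs


def _close_cluster(cluster: Cluster, path: Path, lineno: int) -> None:
    if not cluster.members:
        raise ClusterFormatError(
            f"{path}: cluster {cluster.index} (before line {lineno}) has zero members"
        )
    cluster.representative  # exactly-one check


def write_clstr(cs: ClusterSet, path: str | Path, unit: str = "nt") -> None:
    """Emit the ``.clstr`` dialect that :func:`parse_clstr` accepts.

    Cluster order and member order are preserved verbatim, so
    parse -> write -> parse is a fixpoint.
    """
    if unit not in ("nt", "aa"):
        raise ValueError(f"unit must be 'nt' or 'aa', got {unit!r}")
    with open(path, "w") as fh:
        for c in cs.clusters:
            fh.write(f">Cluster {c.index}\n")
            for i, m in enumerate(c.members):
                if m.is_representative:
                    tail = "*"
                elif m.strand is not None:
                    tail = f"at {m.strand}/{m.identity_pct:.2f}%"
                else:
                    tail = f"at {m.identity_pct:.2f}%"
                fh.write(f"{i}\t{m.length}{unit}, >{m.seq_id}... {tail}\n")


def parse_edge_list(
    path: str | Path, universe: Iterable[str] | None = None
) -> tuple[set[frozenset[str]], set[str]]:
    """Read a ``Node1<TAB>Node2`` file into an undirected edge set.

    Columns beyond the second are ignored, which makes BLAST outfmt-6 output
    directly usable.  Self-hits are dropped (the node is still recorded) and
    duplicate/reversed edges collapse.  Returns ``(edges, nodes)`` where
    nodes includes the supplied universe, if any.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    nodes: set[str] = set(universe) if universe is not None else set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ClusterFormatError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            a, b = cols[0], cols[1]
            nodes.update((a, b))
            if a != b:
                edges.add(frozenset((a, b)))
    return edges, nodes


def clusters_from_edges(
    edges: Iterable[frozenset[str] | tuple[str, str]],
    universe: Iterable[str],
    lengths: Mapping[str, int] | None = None,
) -> ClusterSet:
    """Derive clusters as connected components of an undirected graph.

    Sequences in ``universe`` that touch no edge become singletons.  The
    representative is the longest member when ``lengths`` are supplied
    (ties broken lexicographically), else the lexicographically smallest ID.
    Edge lists carry no identities, so ``identity_pct`` is absent throughout.
    """
    g = nx.Graph()
    g.add_nodes_from(universe)
    for e in edges:
        a, b = tuple(e)
        g.add_edge(a, b)

    def rep_key(sid: str) -> tuple:
        if lengths is not None:
            return (-lengths.get(sid, 0), sid)
        return (sid,)

    # Deterministic cluster order: sort components by their smallest member.
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda comp: comp[0],
    )
    cs = ClusterSet()
    for idx, comp in enumerate(components):
        rep = min(comp, key=rep_key)
        members = [
            ClusterMember(
                seq_id=sid,
                length=lengths.get(sid, 0) if lengths else 0,
                identity_pct=None,
                strand=None,
                is_representative=(sid == rep),
            )
            for sid in comp
        ]
        cs.clusters.append(Cluster(index=idx, members=members))
    cs.validate()
    return cs
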