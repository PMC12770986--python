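"""Deterministic greedy incremental clusterer with CD-HIT-style semantics.

This is a transparent re-statement of greedy incremental clustering: sort
sequences longest-first, and let each sequence join the first existing
representative that passes both the length-difference cutoff ``s``
(shorter/longer length ratio >= s) and the identity threshold ``c``
(percent identity over the local overlap >= 100*c); otherwise it founds a
new cluster.  Unlike heuristic production clusterers, the outcome here is a
pure function of the input and parameters — no thread-, memory- or
word-table-dependent state — so two runs with identical configuration are
byte-identical.  That determinism is the point: it gives pangenome
pipelines a stable clustering baseline against which the fragility of
external tools can be measured.

Identity is computed from the best local alignment (match +1, mismatch -1,
gap open -2, gap extend -1 — constants declared here, not borrowed from any
external tool) as ``100 * matches / len(shorter sequence)``: matched
positions are found by local alignment, but the denominator is the full
length of the shorter sequence.  A short sequence fully contained in a long
one can therefore reach 100% identity (the overhang of the longer sequence
costs nothing — the local-overlap semantics that let short conserved
segments cluster length-disparate genes once the length cutoff ``s`` is
relaxed), while a merely windowed similarity between unrelated sequences
cannot.  A ``strict`` mode that also charges internal alignment gaps as
differences is exposed to quantify the "gaps do not contribute to sequence
differences" effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

from Bio import Align

from .cluster_io import Cluster, ClusterMember, ClusterSet
from .seq_ingest import reverse_complement

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN_SCORE = -2
GAP_EXTEND_SCORE = -1


def _two_dp(x: float) -> float:
    """Normalise a parameter to exactly two decimal places (0.8 -> 0.80)."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClusteringParams:
    """Greedy-clustering parameters.

    ``c``: identity threshold as a fraction in [0,1];
    ``s``: length-difference cutoff (min shorter/longer ratio) in [0,1];
    ``mode``: ``dna`` (both strands considered) or ``aa``;
    ``word_size``: k-mer size for the candidate prefilter (optimisation
    only — disable with ``use_prefilter=False`` for exhaustive comparison).

    ``c`` and ``s`` are normalised to exactly two decimals on construction,
    so 0.9 and 0.90 are one and the same parameterisation.
    """

    c: float = 0.90
    s: float = 0.80
    mode: str = "dna"
    word_size: int = 8
    use_prefilter: bool = True
    strict_identity: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", _two_dp(self.c))
        object.__setattr__(self, "s", _two_dp(self.s))
        if not (0 <= self.c <= 1 and 0 <= self.s <= 1):
            raise ValueError("c and s must lie in [0,1]")
        if self.mode not in ("dna", "aa"):
            raise ValueError(f"mode must be 'dna' or 'aa', got {self.mode!r}")
        if self.word_size < 2:
            raise ValueError("word_size must be >= 2")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    # first gap position scores GAP_OPEN_SCORE, each further one GAP_EXTEND_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(
    a: str, b: str, strict: bool = False
) -> tuple[float, int]:
    """Percent identity and overlap length of the best local alignment.

    Returns ``(identity_pct, overlap_len)``.  ``overlap_len`` is the number
    of residues of the shorter sequence covered by the alignment.  Matches
    are counted in the best-scoring local alignment;
    ``identity_pct = 100 * matches / len(shorter)``.  With ``strict=True``
    internal gap columns of the alignment are added to the denominator, so
    gapped alignments score lower.  Ties among optimal-score alignments are
    broken by the aligner's deterministic first traceback.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    short_len = min(len(a), len(b))
    alignments = _ALIGNER.align(a, b)
    if alignments.score <= 0:
        return 0.0, 0
    aln = alignments[0]
    a_is_shorter = len(a) <= len(b)
    matches = 0
    covered = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        seg_a = a[sa:ea]
        seg_b = b[sb:eb]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        covered += (ea - sa) if a_is_shorter else (eb - sb)
    denom = short_len
    if strict:
        # internal gap columns: local-alignment span minus aligned residues
        blocks_a, blocks_b = aln.aligned
        span_a = blocks_a[-1][1] - blocks_a[0][0]
        span_b = blocks_b[-1][1] - blocks_b[0][0]
        aligned_a = sum(e - s for s, e in blocks_a)
        aligned_b = sum(e - s for s, e in blocks_b)
        gap_cols = (span_a - aligned_a) + (span_b - aligned_b)
        denom += gap_cols
    return 100.0 * matches / denom, int(covered)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_word_lower_bound(short_len: int, k: int, c: float) -> int:
    """Minimum k-mer window hits compatible with identity >= c.

    If at least ``c * short_len`` positions of the shorter sequence match,
    at most ``(1-c) * short_len`` positions differ and each destroys at most
    ``k`` of the ``short_len - k + 1`` windows.  Halved as a safety margin
    for gapped alignments (gap openings can break windows beyond this
    count); the filter must only skip *hopeless* comparisons.
    """
    import math

    mismatch_budget = math.ceil((1.0 - c) * short_len)
    bound = (short_len - k + 1) - k * mismatch_budget
    return max(1, bound // 2)


class _RepIndex:
    """k-mer window index over representatives (prefilter only).

    A representative is a candidate for a query when the number of query
    windows found among the representative's k-mers reaches the
    :func:`shared_word_lower_bound` for the query's length.
    """

    def __init__(self, k: int, c: float) -> None:
        self.k = k
        self.c = c
        self.rep_kmers: list[set[str]] = []
        self.by_kmer: dict[str, list[int]] = {}

    def add(self, rep_idx: int, seq: str) -> None:
        kms = _kmers(seq, self.k)
        assert rep_idx == len(self.rep_kmers)
        self.rep_kmers.append(kms)
        for km in kms:
            self.by_kmer.setdefault(km, []).append(rep_idx)

    def candidates(self, seq: str) -> set[int]:
        if len(seq) < self.k:
            return set(range(len(self.rep_kmers)))  # too short to filter
        counts: dict[int, int] = {}
        for i in range(len(seq) - self.k + 1):
            for rep_idx in self.by_kmer.get(seq[i : i + self.k], ()):
                counts[rep_idx] = counts.get(rep_idx, 0) + 1
        threshold = shared_word_lower_bound(len(seq), self.k, self.c)
        return {rep_idx for rep_idx, n in counts.items() if n >= threshold}


def greedy_cluster(seqs: Mapping[str, str], params: ClusteringParams) -> ClusterSet:
    """Cluster sequences greedily, longest first.

    Sequences are processed in (descending length, ascending id) order.
    Each sequence joins the earliest-founded cluster whose representative
    passes the length-ratio test (``>= s``) and the identity test
    (``>= 100*c``); in ``dna`` mode both strands are tried and the better
    one recorded.  Otherwise the sequence founds a new cluster and becomes
    its representative.
    """
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    min_pct = 100.0 * params.c
    reps: list[tuple[str, str]] = []  # (rep_id, rep_seq) in founding order
    cs = ClusterSet()
    index = _RepIndex(params.word_size, params.c) if params.use_prefilter else None

    for sid in order:
        seq = seqs[sid]
        if not seq:
            raise ValueError(f"sequence {sid!r} is empty")
        cand: set[int] | None = None
        if index is not None:
            cand = index.candidates(seq)
            if params.mode == "dna":
                cand |= index.candidates(reverse_complement(seq))
        placed = False
        for rep_pos, (rep_id, rep_seq) in enumerate(reps):
            if cand is not None and rep_pos not in cand:
                continue
            # reps are processed longest-first, so rep_seq is never shorter
            ratio = len(seq) / len(rep_seq)
            if ratio < params.s:
                continue
            ident, _ = pairwise_identity(seq, rep_seq, strict=params.strict_identity)
            strand = "+"
            if params.mode == "dna" and ident < min_pct:
                # only try the other strand when the forward one fails
                ident_rc, _ = pairwise_identity(
                    reverse_complement(seq), rep_seq, strict=params.strict_identity
                )
                if ident_rc > ident:
                    ident, strand = ident_rc, "-"
            if ident >= min_pct:
                cs.clusters[rep_pos].members.append(
                    ClusterMember(
                        seq_id=sid,
                        length=len(seq),
                        identity_pct=round(ident, 2),
                        strand=strand if params.mode == "dna" else None,
                        is_representative=False,
                    )
                )
                placed = True
                break
        if not placed:
            pos = len(reps)
            reps.append((sid, seq))
            cs.clusters.append(
                Cluster(
                    index=pos,
                    members=[
                        ClusterMember(
                            seq_id=sid,
                            length=len(seq),
                            identity_pct=None,
                            strand="+" if params.mode == "dna" else None,
                            is_representative=True,
                        )
                    ],
                )
            )
            if index is not None:
                index.add(pos, seq)
    cs.validate()
    return cs
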