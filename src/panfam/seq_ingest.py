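"""Genome annotation ingest: GFF3 parsing, CDS extraction and genome tagging.

Reads annotated prokaryotic genomes supplied as GFF3 with an embedded
``##FASTA`` section (the Prokka/Bakta convention) or as a GFF3 file with a
sibling FASTA carrying the same contig IDs.  Every extracted gene is turned
into a :class:`GeneRecord`; a whole genome becomes a
:class:`GenomeAnnotation`.  Before clustering, genes from many genomes are
pooled with :func:`tag_and_combine`, which prefixes each gene ID with its
genome of origin so that downstream family classification can trace every
cluster member back to the genome it came from.

Coordinates follow GFF3 throughout: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Sibling-FASTA extensions probed when a GFF3 file has no ``##FASTA`` section.
FASTA_SUFFIXES = (".fasta", ".fna", ".fa")

DEFAULT_SEPARATOR = "|"


class IngestError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene feature.

    ``start``/``end`` are 1-based inclusive (GFF3 convention); ``dna`` is the
    strand-corrected nucleotide sequence (reverse-complemented for ``-``
    features) and ``aa`` its translation for coding features, with the
    terminal stop stripped.  ``aa`` is ``None`` for non-coding features.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    dna: str
    aa: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise IngestError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise IngestError(
                f"feature {self.gene_id}: end {self.end} < start {self.start}"
            )


@dataclass
class GenomeAnnotation:
    """All extracted gene records of one genome, in annotation order."""

    genome_id: str
    records: list[GeneRecord] = field(default_factory=list)
    source_path: str = ""


def translate_cds(dna: str, table_id: int = 11) -> str:
    """Translate a coding sequence using the bacterial code (table 11).

    The terminal stop is stripped.  Internal stops are retained in the
    returned protein but flagged through :mod:`warnings`, as are sequences
    whose length is not a multiple of three (the trailing 1-2 nt are
    truncated rather than the gene dropped).
    """
    if not dna:
        raise IngestError("cannot translate an empty sequence")
    rem = len(dna) % 3
    if rem:
        warnings.warn(
            f"CDS length {len(dna)} not divisible by 3; truncating {rem} trailing nt",
            stacklevel=2,
        )
        dna = dna[: len(dna) - rem]
    aa = str(Seq(dna).translate(table=table_id))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn(
            f"internal stop codon in translated CDS (length {len(dna)} nt)",
            stacklevel=2,
        )
    return aa


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _read_contigs(path: Path, lines: list[str], fasta_start: int | None) -> dict[str, str]:
    """Contig sequences, from the embedded ##FASTA block or a sibling file."""
    if fasta_start is not None:
        text = "".join(lines[fasta_start:])
        handle = io.StringIO(text)
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    for suffix in FASTA_SUFFIXES:
        sibling = path.with_suffix(suffix)
        if sibling.exists():
            return {
                rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(sibling), "fasta")
            }
    raise IngestError(
        f"{path}: no ##FASTA section and no sibling FASTA "
        f"({'/'.join(FASTA_SUFFIXES)}) found"
    )


def _parse_attributes(col9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def parse_gff_with_fasta(
    path: str | Path,
    feature_types: Iterable[str] = ("CDS",),
    genome_id: str | None = None,
    translation_table: int = 11,
) -> GenomeAnnotation:
    """Parse one annotated genome and extract the requested feature types.

    Parameters
    ----------
    path
        GFF3 file; sequence data must follow a ``##FASTA`` directive in the
        same file or live in a sibling ``.fasta``/``.fna``/``.fa`` file with
        matching contig IDs.
    feature_types
        Feature types (GFF3 column 3) to extract, e.g. ``{"CDS", "rRNA"}``.
        Non-CDS features are extracted as DNA only.
    genome_id
        Defaults to the file stem.

    Multi-span features (two or more feature lines sharing one ID) are
    skipped with a logged warning: joined CDS are vanishingly rare in
    prokaryotes and single-span semantics keep coordinates unambiguous.
    """
    path = Path(path)
    wanted = set(feature_types)
    gid = genome_id if genome_id is not None else path.stem
    lines = path.read_text().splitlines(keepends=True)

    fasta_start: int | None = None
    feature_lines: list[tuple[int, str]] = []  # (1-based line number, line)
    for i, line in enumerate(lines):
        if line.startswith("##FASTA"):
            fasta_start = i + 1
            break
        if not line.strip() or line.startswith("#"):
            continue
        feature_lines.append((i + 1, line.rstrip("\n")))

    contigs = _read_contigs(path, lines, fasta_start)

    # First pass: collect spans per feature, detect multi-span IDs.
    raw: list[tuple[int, str, str, int, int, str, str, str]] = []
    id_counts: dict[str, int] = {}
    anon = 0
    for lineno, text in feature_lines:
        cols = text.split("\t")
        if len(cols) != 9:
            raise IngestError(
                f"{path}:{lineno}: malformed GFF line "
                f"({len(cols)} columns, expected 9)"
            )
        contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
        if ftype not in wanted:
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise IngestError(
                f"{path}:{lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
            ) from exc
        attributes = _parse_attributes(attrs)
        fid = attributes.get("ID") or attributes.get("locus_tag")
        if fid is None:
            anon += 1
            fid = f"{ftype}_{anon}"
        id_counts[fid] = id_counts.get(fid, 0) + 1
        raw.append((lineno, fid, contig, start, end, strand, ftype, attrs))

    multi = {fid for fid, n in id_counts.items() if n > 1}
    for fid in sorted(multi):
        logger.warning(
            "%s: feature %s has %d spans; multi-span features are skipped",
            path,
            fid,
            id_counts[fid],
        )

    records: list[GeneRecord] = []
    for lineno, fid, contig, start, end, strand, ftype, _attrs in raw:
        if fid in multi:
            continue
        if contig not in contigs:
            raise IngestError(
                f"{path}:{lineno}: feature {fid} references missing contig {contig!r}"
            )
        seq = contigs[contig]
        if end > len(seq) or start < 1:
            raise IngestError(
                f"{path}:{lineno}: feature {fid} spans {start}..{end} but contig "
                f"{contig} has length {len(seq)}"
            )
        dna = seq[start - 1 : end]
        if strand == "-":
            dna = reverse_complement(dna)
        aa: str | None = None
        if ftype == "CDS":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aa = translate_cds(dna, translation_table)
        records.append(
            GeneRecord(
                gene_id=fid,
                genome_id=gid,
                contig_id=contig,
                start=start,
                end=end,
                strand=strand,
                feature_type=ftype,
                dna=dna,
                aa=aa,
            )
        )
    return GenomeAnnotation(genome_id=gid, records=records, source_path=str(path))


def parse_genome_dir(
    directory: str | Path,
    feature_types: Iterable[str] = ("CDS",),
    translation_table: int = 11,
) -> list[GenomeAnnotation]:
    """Parse every ``.gff``/``.gff3`` in a directory, sorted by file name."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".gff", ".gff3")
    )
    if not paths:
        raise IngestError(f"no GFF3 files found in {directory}")
    annotations = [
        parse_gff_with_fasta(p, feature_types, translation_table=translation_table)
        for p in paths
    ]
    seen: dict[str, str] = {}
    for ann in annotations:
        if ann.genome_id in seen:
            raise IngestError(
                f"duplicate genome_id {ann.genome_id!r} "
                f"({seen[ann.genome_id]} and {ann.source_path})"
            )
        seen[ann.genome_id] = ann.source_path
    return annotations


def split_tagged_id(tagged_id: str, separator: str = DEFAULT_SEPARATOR) -> tuple[str, str]:
    """Recover ``(genome_id, gene_id)`` from a tagged sequence ID."""
    genome_id, sep, gene_id = tagged_id.partition(separator)
    if not sep:
        raise IngestError(
            f"sequence id {tagged_id!r} does not contain separator {separator!r}"
        )
    return genome_id, gene_id


def tag_and_combine(
    annotations: Iterable[GenomeAnnotation],
    separator: str = DEFAULT_SEPARATOR,
    mode: str = "dna",
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Pool genes from many genomes under genome-tagged IDs.

    Returns ``(records, id_map)`` where ``records`` is a list of
    ``(tagged_id, sequence)`` pairs ready to write as a combined FASTA and
    ``id_map`` lists ``(tagged_id, genome_id, original_id)`` rows.  Genomes
    are emitted in lexicographic order, genes in annotation order, so output
    is deterministic.  In ``aa`` mode records without a translation
    (non-coding features) are excluded.
    """
    if mode not in ("dna", "aa"):
        raise ValueError(f"mode must be 'dna' or 'aa', got {mode!r}")
    anns = sorted(annotations, key=lambda a: a.genome_id)
    records: list[tuple[str, str]] = []
    id_map: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    collisions: list[str] = []
    for ann in anns:
        if separator in ann.genome_id:
            raise IngestError(
                f"separator {separator!r} occurs in genome id {ann.genome_id!r}"
            )
        for rec in ann.records:
            if mode == "aa" and rec.aa is None:
                continue
            tagged = f"{ann.genome_id}{separator}{rec.gene_id}"
            if tagged in seen:
                collisions.append(tagged)
                continue
            seen.add(tagged)
            records.append((tagged, rec.dna if mode == "dna" else rec.aa))
            id_map.append((tagged, ann.genome_id, rec.gene_id))
    if collisions:
        raise IngestError(
            "duplicate tagged ids after genome tagging: " + ", ".join(sorted(collisions))
        )
    return records, id_map


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_id_map(id_map: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tagged_id\tgenome_id\toriginal_id\n")
        for tagged, genome, original in id_map:
            fh.write(f"{tagged}\t{genome}\t{original}\n")
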