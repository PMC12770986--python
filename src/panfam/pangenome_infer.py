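"""Pangenome inference: genome tracing, presence-band classification, outputs.

Given a clustering of genome-tagged gene IDs, each cluster becomes a gene
family whose members are traced back to their source genomes.  Families are
then classified into ordered presence bands — by default the conventional
core (>=99% of genomes, including exactly 100%), soft-core [95,99), shell
[15,95) and cloud [0,15) — and written out in formats downstream tools
already understand: a Roary-dialect ``gene_presence_absence.csv``, a
``summary_statistics.txt``, and per-family FASTA files.

Band boundaries are compared with exact rational arithmetic
(:class:`fractions.Fraction`), so a family present in 19 of 20 genomes sits
exactly on the 95% bound and deterministically takes the soft-core band
(bounds are lower-inclusive).  Floating-point boundary fragility is a real
failure mode of clustering pipelines; it is eliminated here by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cluster_io import ClusterSet
from .seq_ingest import DEFAULT_SEPARATOR, split_tagged_id, write_fasta

PRESENCE_ABSENCE_FIXED_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, named presence-percentage bands.

    ``bands`` is a list of ``(name, lower_bound_pct)`` with strictly
    decreasing lower bounds ending at 0.  Each band covers
    ``[lower, next_higher_lower)`` percent of genomes, lower-inclusive; the
    top band additionally includes exactly 100%.
    """

    bands: tuple[tuple[str, Fraction], ...]

    @classmethod
    def from_bounds(
        cls, bounds: Sequence[float | int], names: Sequence[str] | None = None
    ) -> "CategoryScheme":
        fr = [Fraction(b).limit_denominator(10_000) for b in bounds]
        if names is None:
            names = [f"First_core_{int(b) if b == int(b) else b}" for b in fr]
        if len(names) != len(fr):
            raise ValueError("bounds and names must have equal length")
        if any(b2 >= b1 for b1, b2 in zip(fr, fr[1:])):
            raise ValueError(f"lower bounds must strictly decrease: {bounds}")
        if fr[-1] != 0:
            raise ValueError("last lower bound must be 0 so the bands cover [0,100]")
        if not (0 <= fr[0] <= 100):
            raise ValueError("bounds must lie in [0,100]")
        return cls(bands=tuple(zip(names, fr)))

    @classmethod
    def default(cls) -> "CategoryScheme":
        return cls.from_bounds(
            [99, 95, 15, 0],
            ["First_core_99", "First_core_95", "First_core_15", "First_core_0"],
        )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.bands]

    def intervals(self) -> list[tuple[str, Fraction, Fraction]]:
        """(name, lower, upper) with upper = previous band's lower (top: 100)."""
        out = []
        upper = Fraction(100)
        for name, lower in self.bands:
            out.append((name, lower, upper))
            upper = lower
        return out


def classify_family(
    genome_count: int, total_genomes: int, scheme: CategoryScheme | None = None
) -> str:
    """Band name for a family present in ``genome_count`` of ``total_genomes``.

    The presence percentage ``100 * genome_count / total_genomes`` is
    compared against band lower bounds as an exact rational, so boundary
    cases (e.g. 19/20 = 95%) are deterministic and lower-inclusive.
    """
    if total_genomes <= 0:
        raise ValueError("total_genomes must be positive")
    if not 1 <= genome_count <= total_genomes:
        raise ValueError(
            f"genome_count {genome_count} outside [1, {total_genomes}]"
        )
    if scheme is None:
        scheme = CategoryScheme.default()
    pct = Fraction(100 * genome_count, total_genomes)
    for name, lower in scheme.bands:
        if pct >= lower:
            return name
    raise AssertionError("bands must terminate at lower bound 0")


@dataclass
class GeneFamily:
    """One gene family: a cluster traced back to its source genomes."""

    family_id: str
    members_by_genome: dict[str, list[str]]
    representative_id: str
    category: str | None = None

    @property
    def genome_count(self) -> int:
        return len(self.members_by_genome)

    @property
    def gene_count(self) -> int:
        return sum(len(v) for v in self.members_by_genome.values())

    def member_ids(self) -> list[str]:
        """All tagged member IDs, genomes in sorted order."""
        return [
            gid
            for genome in sorted(self.members_by_genome)
            for gid in self.members_by_genome[genome]
        ]


@dataclass
class PangenomeResult:
    genomes: list[str]
    families: list[GeneFamily]
    scheme: CategoryScheme

    @property
    def totals(self) -> dict[str, int]:
        counts = {name: 0 for name in self.scheme.names}
        for fam in self.families:
            counts[fam.category] += 1
        return counts

    @property
    def total_gene_count(self) -> int:
        return sum(f.gene_count for f in self.families)


def trace_genomes(
    cs: ClusterSet, separator: str = DEFAULT_SEPARATOR
) -> list[GeneFamily]:
    """One uncategorised :class:`GeneFamily` per cluster.

    Member IDs are split on the first ``separator`` to recover the genome of
    origin; paralogs (several genes of one genome in a cluster) land in the
    same genome list.
    """
    families: list[GeneFamily] = []
    for cluster in cs.clusters:
        by_genome: dict[str, list[str]] = {}
        for member in cluster.members:
            genome_id, _gene = split_tagged_id(member.seq_id, separator)
            by_genome.setdefault(genome_id, []).append(member.seq_id)
        families.append(
            GeneFamily(
                family_id=f"group_{cluster.index}",
                members_by_genome=by_genome,
                representative_id=cluster.representative_id,
            )
        )
    return families


def infer_pangenome(
    cs: ClusterSet,
    separator: str = DEFAULT_SEPARATOR,
    scheme: CategoryScheme | None = None,
    genomes: Iterable[str] | None = None,
) -> PangenomeResult:
    """Trace, classify and assemble the full pangenome result.

    ``genomes`` may enumerate the run's genome set explicitly (e.g. genomes
    contributing no clustered gene); by default it is the union observed in
    the clustering.
    """
    if scheme is None:
        scheme = CategoryScheme.default()
    families = trace_genomes(cs, separator)
    observed = sorted({g for f in families for g in f.members_by_genome})
    genome_list = sorted(set(genomes)) if genomes is not None else observed
    missing = set(observed) - set(genome_list)
    if missing:
        raise ValueError(f"clusters reference genomes outside the run: {sorted(missing)}")
    total = len(genome_list)
    for fam in families:
        fam.category = classify_family(fam.genome_count, total, scheme)
    return PangenomeResult(genomes=genome_list, families=families, scheme=scheme)


def _fmt_avg(value: float) -> str:
    """Minimal decimal rendering: 1.5 -> '1.5', 2.0 -> '2', 1.333.. -> '1.33'."""
    s = f"{value:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _family_sort_key(fam: GeneFamily) -> tuple:
    fid = fam.family_id
    try:
        num = int(fid.rsplit("_", 1)[1])
        return (-fam.genome_count, 0, num, fid)
    except (IndexError, ValueError):
        return (-fam.genome_count, 1, 0, fid)


def build_presence_absence(pr: PangenomeResult) -> list[list[str]]:
    """Rows of the Roary-dialect ``gene_presence_absence.csv``.

    Fixed leading columns, then one column per genome; a genome's cell lists
    its member gene IDs joined by a tab inside the quoted field, empty when
    absent.  Rows sort by descending genome presence, then family id.
    """
    header = PRESENCE_ABSENCE_FIXED_COLUMNS + list(pr.genomes)
    rows = [header]
    for fam in sorted(pr.families, key=_family_sort_key):
        avg = fam.gene_count / fam.genome_count
        row = [
            fam.family_id,
            "",
            "",
            str(fam.genome_count),
            str(fam.gene_count),
            _fmt_avg(avg),
        ]
        for genome in pr.genomes:
            row.append("\t".join(fam.members_by_genome.get(genome, [])))
        rows.append(row)
    return rows


def write_presence_absence(pr: PangenomeResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerows(build_presence_absence(pr))


def summary_statistics_lines(pr: PangenomeResult) -> list[str]:
    """``summary_statistics.txt`` content.

    One line per band — ``<name> (<lo>% <= strains < <hi>%): <count>`` with
    the top band closed at 100% — then the total number of gene families
    (the "Total genes" convention of the established summary format) and the
    total number of member sequences.
    """
    totals = pr.totals
    lines = []
    intervals = pr.scheme.intervals()
    for i, (name, lo, hi) in enumerate(intervals):
        lo_s = _fmt_avg(float(lo))
        hi_s = _fmt_avg(float(hi))
        op = "<=" if i == 0 else "<"
        lines.append(f"{name} ({lo_s}% <= strains {op} {hi_s}%): {totals[name]}")
    lines.append(f"Total genes: {len(pr.families)}")
    lines.append(f"Total gene sequences: {pr.total_gene_count}")
    return lines


def write_summary_statistics(pr: PangenomeResult, path: str | Path) -> None:
    Path(path).write_text("\n".join(summary_statistics_lines(pr)) + "\n")


def write_family_fastas(
    pr: PangenomeResult,
    sequences: Mapping[str, str],
    outdir: str | Path,
    combined_name: str = "combined_families.fasta",
) -> None:
    """One FASTA per family plus one combined FASTA, tagged IDs retained.

    Record order within a family follows genomes sorted lexicographically,
    genes in cluster order — the iteration order of
    :meth:`GeneFamily.member_ids`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined: list[tuple[str, str]] = []
    for fam in pr.families:
        recs = []
        for gid in fam.member_ids():
            if gid not in sequences:
                raise KeyError(
                    f"family {fam.family_id}: no sequence for member {gid!r}"
                )
            recs.append((gid, sequences[gid]))
        write_fasta(recs, outdir / f"{fam.family_id}.fasta")
        combined.extend(recs)
    write_fasta(combined, outdir / combined_name)
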