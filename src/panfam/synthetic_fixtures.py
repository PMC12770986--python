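"""Synthetic pangenomes with planted family structure.

Generates toy multi-genome datasets whose ground truth is known exactly, so
the whole pipeline — ingest, clustering, classification, reclustering — can
be tested end to end without any download.  Each gene family descends from
a random-uniform nucleotide ancestor (length 300-1500 nt, a multiple of 3);
per-genome copies receive independent per-site substitutions at
``mutation_rate``.  Core families are planted in every genome; accessory
families in a random subset whose size is drawn from ``presence_range``.
Optionally, (family, genome) slots receive a paralogous second copy
(``paralog_rate``) or are split into two partial genes at a uniform internal
point (``fragment_rate``), emulating fragmented annotations.

No biological realism is claimed for the sequences themselves: what matters
is a controllable identity structure — within-family identity about
``100*(1 - 2*mutation_rate)`` percent, between-family identity near the
random-sequence background — so that clustering at the conventional
thresholds (c=0.90, s=0.80) recovers the planted partition exactly.

A second-round generator emits the three kinds of follow-up sequences that
stress reclustering: gap-fillers that lift an accessory family into a
higher presence band (*extended*), long bridging sequences spanning two
families (*combined*; they only merge once the length cutoff is relaxed to
s=0), and an entirely novel near-universal family (*only_second*).

Generation is a pure function of the spec, including its ``seed``: the same
spec writes byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .pangenome_infer import CategoryScheme, classify_family
from .seq_ingest import DEFAULT_SEPARATOR, reverse_complement, write_fasta

BASES = "ACGT"
SPACER_LEN = 25


@dataclass(frozen=True)
class PangenomeSpec:
    """Parameters of a planted pangenome; generation is pure in this spec."""

    n_genomes: int = 20
    n_core: int = 100
    n_accessory: int = 50
    presence_range: tuple[float, float] = (0.10, 0.90)
    paralog_rate: float = 0.0
    mutation_rate: float = 0.01
    fragment_rate: float = 0.0
    min_len: int = 300
    max_len: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paralog_rate", "mutation_rate", "fragment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        lo, hi = self.presence_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"presence_range must satisfy 0 <= lo <= hi <= 1")
        if self.min_len < 30 or self.max_len < self.min_len:
            raise ValueError("need 30 <= min_len <= max_len")


@dataclass(frozen=True)
class TruthGene:
    tagged_id: str
    genome_id: str
    family: str
    fragment: bool = False
    paralog: bool = False


@dataclass
class PangenomeTruth:
    """Planted ground truth accompanying a generated pangenome."""

    spec: PangenomeSpec
    genes: list[TruthGene]
    #: family -> set of genomes carrying it
    presence: dict[str, set[str]]
    #: family -> planted band under the default scheme
    bands: dict[str, str]
    #: family -> ancestor sequence
    ancestors: dict[str, str]

    def family_of(self) -> dict[str, str]:
        return {g.tagged_id: g.family for g in self.genes}

    def band_counts(self) -> dict[str, int]:
        scheme = CategoryScheme.default()
        counts = {name: 0 for name in scheme.names}
        for band in self.bands.values():
            counts[band] += 1
        return counts


def _random_gene(rng: random.Random, min_len: int, max_len: int) -> str:
    length = 3 * rng.randint(min_len // 3, max_len // 3)
    return "".join(rng.choice(BASES) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _genome_names(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"genome_{i:0{width}d}" for i in range(n)]


def generate_pangenome(
    spec: PangenomeSpec, outdir: str | Path | None = None
) -> tuple[dict[str, list[tuple[str, str, int, int, str]]], PangenomeTruth]:
    """Generate a planted pangenome.

    Returns ``(layout, truth)`` where ``layout`` maps genome_id to its gene
    placements ``(gene_id, dna, start, end, strand)`` on a single contig
    (the strand-corrected gene sequence is ``dna``; on '-' the contig holds
    its reverse complement).  When ``outdir`` is given, one GFF3 file with
    embedded ``##FASTA`` per genome plus a ``truth.tsv`` table are written.
    """
    rng = random.Random(spec.seed)
    genomes = _genome_names(spec.n_genomes)

    families: list[str] = [f"fam_{i:04d}" for i in range(spec.n_core + spec.n_accessory)]
    ancestors = {
        fam: _random_gene(rng, spec.min_len, spec.max_len) for fam in families
    }

    presence: dict[str, set[str]] = {}
    for i, fam in enumerate(families):
        if i < spec.n_core:
            presence[fam] = set(genomes)
        else:
            lo, hi = spec.presence_range
            frac = rng.uniform(lo, hi)
            k = max(1, round(frac * spec.n_genomes))
            presence[fam] = set(rng.sample(genomes, k))

    genes: list[TruthGene] = []
    per_genome: dict[str, list[tuple[str, str, bool, bool]]] = {g: [] for g in genomes}
    # (gene_id, dna, fragment?, paralog?) in deterministic family order
    for fam in families:
        for genome in sorted(presence[fam]):
            copies = 1
            paralog = rng.random() < spec.paralog_rate
            if paralog:
                copies = 2
            for copy_idx in range(copies):
                dna = _mutate(rng, ancestors[fam], spec.mutation_rate)
                base_id = f"{fam}_{genome}" + (f"_p{copy_idx}" if copies > 1 else "")
                if rng.random() < spec.fragment_rate:
                    # uniform internal cut, codon-aligned, both parts non-empty
                    cut = rng.randint(len(dna) // 4, 3 * len(dna) // 4)
                    cut -= cut % 3
                    cut = max(3, min(len(dna) - 3, cut))
                    parts = [dna[:cut], dna[cut:]]
                    for j, part in enumerate(parts):
                        per_genome[genome].append(
                            (f"{base_id}_f{j}", part, True, copy_idx > 0)
                        )
                else:
                    per_genome[genome].append((base_id, dna, False, copy_idx > 0))

    layout: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for genome in genomes:
        placements: list[tuple[str, str, int, int, str]] = []
        pos = 1
        entries = per_genome[genome]
        rng.shuffle(entries)
        for gene_id, dna, fragment, paralog in entries:
            pos += SPACER_LEN
            start = pos
            end = pos + len(dna) - 1
            strand = rng.choice("+-")
            placements.append((gene_id, dna, start, end, strand))
            pos = end + 1
            fam = gene_id.split("_" + genome)[0]
            genes.append(
                TruthGene(
                    tagged_id=f"{genome}{DEFAULT_SEPARATOR}{gene_id}",
                    genome_id=genome,
                    family=fam,
                    fragment=fragment,
                    paralog=paralog,
                )
            )
        layout[genome] = placements

    bands = {
        fam: classify_family(len(presence[fam]), spec.n_genomes)
        for fam in families
    }
    truth = PangenomeTruth(
        spec=spec, genes=genes, presence=presence, bands=bands, ancestors=ancestors
    )
    if outdir is not None:
        write_pangenome_files(layout, truth, outdir, rng)
    return layout, truth


def write_pangenome_files(
    layout: dict[str, list[tuple[str, str, int, int, str]]],
    truth: PangenomeTruth,
    outdir: str | Path,
    rng: random.Random,
) -> None:
    """One GFF3 (embedded ##FASTA, single contig per genome) per genome,
    plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome, placements in layout.items():
        contig_id = f"{genome}_contig1"
        contig_parts: list[str] = []
        pos = 1
        features: list[str] = []
        for gene_id, dna, start, end, strand in placements:
            spacer = "".join(rng.choice(BASES) for _ in range(start - pos))
            contig_parts.append(spacer)
            contig_parts.append(dna if strand == "+" else reverse_complement(dna))
            pos = end + 1
            features.append(
                "\t".join(
                    [
                        contig_id,
                        "panfam_sim",
                        "CDS",
                        str(start),
                        str(end),
                        ".",
                        strand,
                        "0",
                        f"ID={gene_id}",
                    ]
                )
            )
        contig = "".join(contig_parts)
        with open(outdir / f"{genome}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {contig_id} 1 {len(contig)}\n")
            fh.write("\n".join(features) + "\n")
            fh.write("##FASTA\n")
            fh.write(f">{contig_id}\n")
            for i in range(0, len(contig), 60):
                fh.write(contig[i : i + 60] + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("tagged_id\tgenome_id\tfamily\tband\tfragment\tparalog\n")
        for g in truth.genes:
            fh.write(
                f"{g.tagged_id}\t{g.genome_id}\t{g.family}\t"
                f"{truth.bands[g.family]}\t{int(g.fragment)}\t{int(g.paralog)}\n"
            )


@dataclass
class SecondRound:
    """New sequences plus the track each is expected to produce."""

    sequences: list[tuple[str, str]]  # (tagged_id, dna)
    expected_tracks: dict[str, str]  # new tagged_id -> track
    #: track -> origin family ids involved (for combined: the two bridged)
    origins: dict[str, frozenset[str]] = field(default_factory=dict)


def generate_second_round(
    spec: PangenomeSpec, truth: PangenomeTruth, seed: int | None = None
) -> SecondRound:
    """Second-round sequences with planted reclustering outcomes.

    * gap-fillers: copies of the lowest-presence shell family's ancestor for
      every genome missing it -> that family should become *extended*;
    * a bridge: the concatenation of two accessory-family ancestors, one new
      sequence per genome carrying either family -> *combined* (requires
      reclustering at s=0 so the length test cannot veto the merge);
    * a novel family planted in every genome -> *only_second*.

    New gene IDs carry a ``new_`` prefix so they can never collide with
    first-round IDs.
    """
    rng = random.Random(spec.seed + 1 if seed is None else seed)
    accessory = [
        fam
        for fam in truth.presence
        if len(truth.presence[fam]) < spec.n_genomes
    ]
    if len(accessory) < 3:
        raise ValueError("need >= 3 accessory families for a second round")
    genomes = set(_genome_names(spec.n_genomes))

    # target for extension: accessory family with most genomes missing
    fill_fam = min(accessory, key=lambda f: (len(truth.presence[f]), f))
    bridge_pair = sorted(
        (f for f in accessory if f != fill_fam),
        key=lambda f: (len(truth.presence[f]), f),
    )[:2]

    sequences: list[tuple[str, str]] = []
    expected: dict[str, str] = {}
    origins: dict[str, frozenset[str]] = {}

    for genome in sorted(genomes - truth.presence[fill_fam]):
        dna = _mutate(rng, truth.ancestors[fill_fam], spec.mutation_rate)
        tid = f"{genome}{DEFAULT_SEPARATOR}new_fill_{fill_fam}"
        sequences.append((tid, dna))
        expected[tid] = "extended"
    origins["extended"] = frozenset({fill_fam})

    f1, f2 = bridge_pair
    chimera = truth.ancestors[f1] + truth.ancestors[f2]
    for genome in sorted(truth.presence[f1] | truth.presence[f2]):
        dna = _mutate(rng, chimera, spec.mutation_rate)
        tid = f"{genome}{DEFAULT_SEPARATOR}new_bridge_{f1}_{f2}"
        sequences.append((tid, dna))
        expected[tid] = "combined"
    origins["combined"] = frozenset({f1, f2})

    novel = _random_gene(rng, spec.min_len, spec.max_len)
    for genome in sorted(genomes):
        dna = _mutate(rng, novel, spec.mutation_rate)
        tid = f"{genome}{DEFAULT_SEPARATOR}new_novel_fam"
        sequences.append((tid, dna))
        expected[tid] = "only_second"
    origins["only_second"] = frozenset()

    return SecondRound(sequences=sequences, expected_tracks=expected, origins=origins)


def write_second_round(sr: SecondRound, path: str | Path) -> None:
    write_fasta(sr.sequences, path)
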