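"""Pipeline orchestration: Full, Partial and Recluster modes.

* **Full mode** — directory of annotated genomes in, pangenome out: parse
  GFF3(+FASTA), tag genes with their genome of origin, cluster (built-in
  greedy clusterer, or an external CD-HIT if requested), classify families
  and write every output.
* **Partial mode** — start from a pre-computed clustering (``.clstr`` or
  edge list) and run only the inference/output stages.  Given the same
  clustering, Partial mode produces byte-identical downstream outputs to
  Full mode.
* **Recluster mode** — take a previous run's output directory plus new
  sequences, recluster old+new together, and report how the new sequences
  sit relative to the original families.

Every run writes a ``provenance.json`` capturing the fully resolved
configuration — clustering thresholds at their two-decimal normal form,
declared thread/memory settings, tool versions — because resource
parameters have been observed to change external clusterers' output and
must travel with any result they shaped.  The built-in clusterer ignores
``threads``/``memory_mb`` by design; they are recorded all the same.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cluster_io import (
    ClusterSet,
    clusters_from_edges,
    parse_clstr,
    parse_edge_list,
    write_clstr,
)
from .pangenome_infer import (
    CategoryScheme,
    PangenomeResult,
    infer_pangenome,
    write_family_fastas,
    write_presence_absence,
    write_summary_statistics,
)
from .phylo_metrics import align_family, concatenate_core_alignment, select_family_representatives
from .reclusterer import (
    ReclusterReport,
    recluster,
    write_fanout_table,
    write_recluster_summary,
)
from .reference_clusterer import ClusteringParams, greedy_cluster
from .seq_ingest import (
    DEFAULT_SEPARATOR,
    parse_genome_dir,
    read_fasta,
    tag_and_combine,
    write_fasta,
    write_id_map,
)

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    mode: str  # full | partial | recluster
    output_dir: str
    input_dir: str | None = None
    clusters_file: str | None = None  # partial mode: .clstr or edge list
    first_run_dir: str | None = None  # recluster mode
    new_fasta: str | None = None  # recluster mode
    features: tuple[str, ...] = ("CDS",)
    separator: str = DEFAULT_SEPARATOR
    seq_mode: str = "dna"  # dna | aa
    params: ClusteringParams = field(default_factory=ClusteringParams)
    scheme: CategoryScheme = field(default_factory=CategoryScheme.default)
    clusterer: str = "internal"  # internal | external_cdhit
    aligner: str | None = None  # e.g. "mafft" to build a core alignment
    core_band: str | None = None  # band whose families enter the core alignment
    threads: int = 1
    memory_mb: int = 800
    translation_table: int = 11

    def __post_init__(self) -> None:
        if self.mode not in ("full", "partial", "recluster"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.clusterer not in ("internal", "external_cdhit"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")

    def provenance(self) -> dict:
        d = {
            "panfam_version": __version__,
            "python": sys.version.split()[0],
            "mode": self.mode,
            "input_dir": self.input_dir,
            "clusters_file": self.clusters_file,
            "first_run_dir": self.first_run_dir,
            "new_fasta": self.new_fasta,
            "output_dir": self.output_dir,
            "features": list(self.features),
            "separator": self.separator,
            "seq_mode": self.seq_mode,
            "clusterer": self.clusterer,
            "aligner": self.aligner,
            "core_band": self.core_band,
            "threads": self.threads,
            "memory_mb": self.memory_mb,
            "translation_table": self.translation_table,
            "params": {
                "c": f"{self.params.c:.2f}",
                "s": f"{self.params.s:.2f}",
                "mode": self.params.mode,
                "word_size": self.params.word_size,
                "use_prefilter": self.params.use_prefilter,
                "strict_identity": self.params.strict_identity,
            },
            "scheme": {
                "names": self.scheme.names,
                "bounds": [float(b) for _, b in self.scheme.bands],
            },
        }
        if self.aligner:
            d["aligner_path"] = shutil.which(self.aligner)
        return d


def _write_provenance(cfg: RunConfig, outdir: Path, timings: dict[str, float]) -> None:
    prov = cfg.provenance()
    prov["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")


def _external_cdhit(
    fasta: Path, out_prefix: Path, cfg: RunConfig
) -> ClusterSet:
    binary = "cd-hit-est" if cfg.seq_mode == "dna" else "cd-hit"
    if shutil.which(binary) is None:
        raise WorkflowError(
            f"external clusterer requested but {binary!r} is not on PATH"
        )
    cmd = [
        binary,
        "-i",
        str(fasta),
        "-o",
        str(out_prefix),
        "-c",
        f"{cfg.params.c:.2f}",
        "-s",
        f"{cfg.params.s:.2f}",
        "-d",
        "0",
        "-T",
        str(cfg.threads),
        "-M",
        str(cfg.memory_mb),
    ]
    logger.info("running: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise WorkflowError(
            f"{binary} exited with {proc.returncode}: {proc.stderr[-2000:]}"
        )
    return parse_clstr(Path(str(out_prefix) + ".clstr"))


def _infer_and_write(
    cs: ClusterSet,
    sequences: dict[str, str],
    cfg: RunConfig,
    outdir: Path,
    timings: dict[str, float],
) -> PangenomeResult:
    t0 = time.perf_counter()
    pr = infer_pangenome(cs, separator=cfg.separator, scheme=cfg.scheme)
    write_presence_absence(pr, outdir / "gene_presence_absence.csv")
    write_summary_statistics(pr, outdir / "summary_statistics.txt")
    if sequences:
        write_family_fastas(pr, sequences, outdir / "families")
    timings["infer"] = time.perf_counter() - t0

    if cfg.aligner and sequences:
        t0 = time.perf_counter()
        _core_alignment(pr, sequences, cfg, outdir)
        timings["core_alignment"] = time.perf_counter() - t0
    return pr


def _core_alignment(
    pr: PangenomeResult, sequences: dict[str, str], cfg: RunConfig, outdir: Path
) -> None:
    """Align one representative per genome for every family in the core band
    and concatenate into a super-alignment."""
    band = cfg.core_band or pr.scheme.names[0]
    per_family: dict[str, dict[str, str]] = {}
    for fam in pr.families:
        if fam.category != band:
            continue
        reps = select_family_representatives(fam, sequences, policy="longest")
        records = [(genome, sequences[gid]) for genome, gid in sorted(reps.items())]
        if len(records) < 2:
            continue
        aligned = align_family(records, aligner_cmd=cfg.aligner)
        per_family[fam.family_id] = dict(aligned)
    if not per_family:
        logger.warning("no families in band %s with >= 2 genomes; no core alignment", band)
        return
    concat = concatenate_core_alignment(per_family, pr.genomes)
    write_fasta(sorted(concat.items()), outdir / "core_gene_alignment.fasta")


def run_full(cfg: RunConfig) -> tuple[PangenomeResult, ClusterSet]:
    """Ingest -> tag -> cluster -> infer -> outputs."""
    if cfg.mode != "full":
        raise ValueError("run_full requires cfg.mode == 'full'")
    if cfg.input_dir is None:
        raise WorkflowError("full mode requires input_dir")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    annotations = parse_genome_dir(
        cfg.input_dir, cfg.features, translation_table=cfg.translation_table
    )
    records, id_map = tag_and_combine(annotations, cfg.separator, mode=cfg.seq_mode)
    sequences = dict(records)
    write_fasta(records, outdir / "combined_genes.fasta")
    write_id_map(id_map, outdir / "id_map.tsv")
    timings["ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if cfg.clusterer == "external_cdhit":
        cs = _external_cdhit(outdir / "combined_genes.fasta", outdir / "cdhit_out", cfg)
    else:
        cs = greedy_cluster(sequences, cfg.params)
    write_clstr(cs, outdir / "clusters.clstr", unit="nt" if cfg.seq_mode == "dna" else "aa")
    timings["cluster"] = time.perf_counter() - t0

    pr = _infer_and_write(cs, sequences, cfg, outdir, timings)
    _write_provenance(cfg, outdir, timings)
    return pr, cs


def load_clusters(path: str | Path, universe: set[str] | None = None) -> ClusterSet:
    """Load a clustering from ``.clstr`` or a 2-column edge list."""
    path = Path(path)
    if path.suffix == ".clstr":
        return parse_clstr(path)
    edges, nodes = parse_edge_list(path, universe)
    return clusters_from_edges(edges, nodes)


def run_partial(cfg: RunConfig) -> tuple[PangenomeResult, ClusterSet]:
    """Pre-clustered input -> infer -> outputs (identical to Full mode
    downstream of clustering)."""
    if cfg.mode != "partial":
        raise ValueError("run_partial requires cfg.mode == 'partial'")
    if cfg.clusters_file is None:
        raise WorkflowError("partial mode requires clusters_file")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    sequences: dict[str, str] = {}
    if cfg.input_dir is not None:
        # optional gene FASTA alongside the clustering, for family FASTAs
        fasta = Path(cfg.input_dir)
        if fasta.is_file():
            sequences = dict(read_fasta(fasta))
    cs = load_clusters(cfg.clusters_file, set(sequences) or None)
    timings["load_clusters"] = time.perf_counter() - t0

    pr = _infer_and_write(cs, sequences, cfg, outdir, timings)
    _write_provenance(cfg, outdir, timings)
    return pr, cs


def run_recluster(cfg: RunConfig) -> ReclusterReport:
    """Prior run + new sequences -> combined clustering -> track report."""
    if cfg.mode != "recluster":
        raise ValueError("run_recluster requires cfg.mode == 'recluster'")
    if cfg.first_run_dir is None or cfg.new_fasta is None:
        raise WorkflowError("recluster mode requires first_run_dir and new_fasta")
    first_dir = Path(cfg.first_run_dir)
    clstr = first_dir / "clusters.clstr"
    combined_fasta = first_dir / "combined_genes.fasta"
    for needed in (clstr, combined_fasta):
        if not needed.exists():
            raise WorkflowError(
                f"first-run directory {first_dir} is missing {needed.name}; "
                "was it produced by a full/partial run with sequences?"
            )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    first_cs = parse_clstr(clstr)
    first = infer_pangenome(first_cs, separator=cfg.separator, scheme=cfg.scheme)
    old_seqs = dict(read_fasta(combined_fasta))
    new_seqs = dict(read_fasta(cfg.new_fasta))
    overlap = set(new_seqs) & set(old_seqs)
    if overlap:
        raise WorkflowError(
            f"new sequences reuse first-round ids: {sorted(overlap)[:5]}"
        )
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    combined = greedy_cluster({**old_seqs, **new_seqs}, cfg.params)
    write_clstr(combined, outdir / "combined.clstr",
                unit="nt" if cfg.seq_mode == "dna" else "aa")
    timings["cluster"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = recluster(
        first, combined, set(new_seqs), scheme=cfg.scheme, separator=cfg.separator
    )
    write_recluster_summary(report, outdir / "recluster_summary.txt")
    write_fanout_table(report, outdir / "origin_fanout.tsv")
    timings["recluster"] = time.perf_counter() - t0
    _write_provenance(cfg, outdir, timings)
    return report
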