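"""Reclustering: integrate second-round sequences into an existing pangenome.

When new gene sequences become available after an initial pangenome run —
for example additional ORFs recovered from intergenic regions, which tend to
be long and are notorious for merging or fragmenting existing families
under length-first clustering — the whole dataset is reclustered (old + new
sequences) and each resulting cluster is mapped back onto the first-round
families its old members came from.  First-round results are never mutated;
instead every combined cluster is labelled with a *track* describing how it
relates to round one:

``first``
    the cluster reproduces a single first-round family whose band did not
    change (new members, if any, are band-neutral);
``extended``
    new sequences lifted a single origin family into a strictly higher
    presence band than it held in round one;
``combined``
    the cluster merges two or more first-round families;
``second``
    the cluster holds its band only thanks to its new members — the old
    members alone (evaluated over the union genome set) fall strictly
    lower — yet it neither merges families nor raises the origin family
    above its first-round band;
``only_second``
    the cluster contains no first-round sequence at all.

Precedence when several conditions hold:
``only_second > combined > extended > second > first``.

Fragmentation — a first-round family whose members scatter over several
combined clusters — is reported separately as a fan-out table rather than
being folded into the four tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .cluster_io import ClusterSet
from .pangenome_infer import (
    CategoryScheme,
    PangenomeResult,
    classify_family,
)
from .seq_ingest import DEFAULT_SEPARATOR, split_tagged_id

TRACKS = ("first", "extended", "second", "combined", "only_second")


@dataclass
class ReclusterFamily:
    family_id: str
    band: str
    track: str
    origin_family_ids: frozenset[str]
    old_seq_ids: frozenset[str]
    new_seq_ids: frozenset[str]


@dataclass
class ReclusterReport:
    families: list[ReclusterFamily]
    genomes: list[str]  # union genome set of old + new sequences
    scheme: CategoryScheme
    #: origin family -> combined family_ids its old members landed in (>1 = fragmented)
    fanout: dict[str, list[str]] = field(default_factory=dict)

    @property
    def fragmented_origin_families(self) -> list[str]:
        return sorted(f for f, tgt in self.fanout.items() if len(tgt) > 1)

    def totals(self) -> dict[tuple[str, str], int]:
        """(track, band) -> family count."""
        out: dict[tuple[str, str], int] = {}
        for fam in self.families:
            key = (fam.track, fam.band)
            out[key] = out.get(key, 0) + 1
        return out


def _band_rank(scheme: CategoryScheme) -> dict[str, int]:
    # higher rank = higher prevalence band; bands are ordered top-down
    return {name: len(scheme.bands) - i for i, (name, _) in enumerate(scheme.bands)}


def _genomes_of(ids, separator: str) -> set[str]:
    return {split_tagged_id(sid, separator)[0] for sid in ids}


def recluster(
    first: PangenomeResult,
    combined: ClusterSet,
    new_ids: set[str],
    scheme: CategoryScheme | None = None,
    separator: str = DEFAULT_SEPARATOR,
) -> ReclusterReport:
    """Map a combined (old + new) clustering onto first-round families.

    ``combined`` must partition exactly the union of the first-round
    universe and ``new_ids``; any old sequence unknown to ``first`` and any
    overlap between ``new_ids`` and the first-round universe is an error.
    Bands are computed over the union genome set.  First-round family
    records are read, never modified.
    """
    if scheme is None:
        scheme = first.scheme
    old_universe: set[str] = set()
    origin_of: dict[str, str] = {}
    first_band: dict[str, str] = {}
    for fam in first.families:
        for gid in fam.member_ids():
            old_universe.add(gid)
            origin_of[gid] = fam.family_id
        first_band[fam.family_id] = fam.category

    overlap = new_ids & old_universe
    if overlap:
        raise ValueError(
            f"new_ids overlap the first-round universe: {sorted(overlap)[:5]} ..."
        )

    all_genomes = set(first.genomes) | _genomes_of(new_ids, separator)
    total = len(all_genomes)
    rank = _band_rank(scheme)

    report_families: list[ReclusterFamily] = []
    fanout: dict[str, list[str]] = {f.family_id: [] for f in first.families}
    seen_old: set[str] = set()

    for cluster in combined.clusters:
        ids = set(cluster.seq_ids)
        news = ids & new_ids
        olds = ids - news
        unknown = olds - old_universe
        if unknown:
            raise ValueError(
                "combined clustering contains old sequences absent from the "
                f"first-round result: {sorted(unknown)[:5]}"
            )
        seen_old |= olds
        fam_id = f"group_{cluster.index}"
        origins = frozenset(origin_of[g] for g in olds)
        band = classify_family(len(_genomes_of(ids, separator)), total, scheme)

        if not olds:
            track = "only_second"
        elif len(origins) >= 2:
            track = "combined"
        else:
            (origin,) = origins
            fanout[origin].append(fam_id)
            old_band = classify_family(
                len(_genomes_of(olds, separator)), total, scheme
            )
            if rank[band] > rank[first_band[origin]]:
                track = "extended"
            elif rank[band] > rank[old_band]:
                track = "second"
            else:
                track = "first"
        if track == "combined":
            for origin in origins:
                fanout[origin].append(fam_id)
        report_families.append(
            ReclusterFamily(
                family_id=fam_id,
                band=band,
                track=track,
                origin_family_ids=origins,
                old_seq_ids=frozenset(olds),
                new_seq_ids=frozenset(news),
            )
        )

    missing = old_universe - seen_old
    if missing:
        raise ValueError(
            "old sequences missing from the combined clustering: "
            f"{sorted(missing)[:5]}"
        )
    return ReclusterReport(
        families=report_families,
        genomes=sorted(all_genomes),
        scheme=scheme,
        fanout=fanout,
    )


def _band_label(track: str, band: str) -> str:
    # First_core_99 + track "extended" -> extended_core_99
    stripped = band[len("First_") :] if band.startswith("First_") else band
    return f"{track}_{stripped}"


def recluster_summary_lines(rep: ReclusterReport) -> list[str]:
    """Per-(track, band) counts; every track/band combination is printed so
    zero counts are explicit, and the counts sum to the family total."""
    totals = rep.totals()
    lines = []
    for track in TRACKS:
        for name, _ in rep.scheme.bands:
            lines.append(f"{_band_label(track, name)}: {totals.get((track, name), 0)}")
    lines.append(f"Total gene families: {len(rep.families)}")
    if rep.fragmented_origin_families:
        lines.append(
            "Fragmented first-round families: "
            + ", ".join(rep.fragmented_origin_families)
        )
    return lines


def write_recluster_summary(rep: ReclusterReport, path: str | Path) -> None:
    Path(path).write_text("\n".join(recluster_summary_lines(rep)) + "\n")


def write_fanout_table(rep: ReclusterReport, path: str | Path) -> None:
    """Origin-family -> combined-cluster fan-out (fragmentation report)."""
    with open(path, "w") as fh:
        fh.write("origin_family\tn_combined_clusters\tcombined_family_ids\n")
        for origin in sorted(rep.fanout):
            targets = rep.fanout[origin]
            fh.write(f"{origin}\t{len(targets)}\t{','.join(sorted(targets))}\n")
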