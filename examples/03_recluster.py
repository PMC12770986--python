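"""Recluster mode: how new sequences disturb an existing pangenome.

Builds a small pangenome, then adds three kinds of second-round sequences —
gap-fillers for a low-presence family, a long bridge spanning two families,
and a novel near-universal family — reclusters everything at a relaxed
length cutoff (s=0) and prints the track assigned to each outcome.
"""

import collections

from panfam import (
    ClusteringParams,
    PangenomeSpec,
    generate_pangenome,
    generate_second_round,
    greedy_cluster,
    infer_pangenome,
    recluster,
)

spec = PangenomeSpec(n_genomes=8, n_core=10, n_accessory=6, seed=7)
layout, truth = generate_pangenome(spec)
seqs = {
    f"{genome}|{gid}": dna
    for genome, placements in layout.items()
    for gid, dna, _s, _e, _st in placements
}

first_cs = greedy_cluster(seqs, ClusteringParams(c=0.90, s=0.80))
first = infer_pangenome(first_cs)

sr = generate_second_round(spec, truth)
new = dict(sr.sequences)
combined = greedy_cluster({**seqs, **new}, ClusteringParams(c=0.90, s=0.00))
report = recluster(first, combined, set(new))

print("track counts:", dict(collections.Counter(f.track for f in report.families)))
for fam in report.families:
    if fam.track != "first":
        print(
            f"  {fam.family_id}: track={fam.track}, band={fam.band}, "
            f"origins={sorted(fam.origin_family_ids)}, "
            f"{len(fam.new_seq_ids)} new / {len(fam.old_seq_ids)} old sequences"
        )
print(
    "'extended' = new sequences lifted an origin family to a higher band; "
    "'combined' = a long bridge merged two families (possible only because "
    "s=0 removed the length-ratio veto); 'only_second' = an entirely new family."
)
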