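"""Clustering diagnostics: per-cluster summaries and run-to-run diffs.

Simulates the canonical fragility scenario: two runs of a clusterer that
agree everywhere except that a singleton gene is absorbed into another
cluster in the second run — the kind of difference resource parameters
alone have been observed to produce in external tools.
"""

import tempfile
from pathlib import Path

from panfam import compare_partitions, group_summary, parse_clstr

RUN_A = """>Cluster 0
0\t305nt, >gA|amiD... *
1\t301nt, >gB|amiD... at +/96.40%
2\t298nt, >gC|amiD... at +/95.10%
>Cluster 1
0\t280nt, >gD|lonely... *
"""

# same genes, but the singleton joined cluster 0
RUN_B = """>Cluster 0
0\t305nt, >gA|amiD... *
1\t301nt, >gB|amiD... at +/96.40%
2\t298nt, >gC|amiD... at +/95.10%
3\t280nt, >gD|lonely... at +/90.16%
"""

with tempfile.TemporaryDirectory() as tmp:
    pa, pb = Path(tmp) / "a.clstr", Path(tmp) / "b.clstr"
    pa.write_text(RUN_A)
    pb.write_text(RUN_B)
    a, b = parse_clstr(pa), parse_clstr(pb)

    print("per-cluster summary of run A (sorted by size):")
    for row in group_summary(a):
        print(
            f"  cluster {row.cluster_id}: {row.n_seqs} seqs, "
            f"{row.n_genomes} genomes, avg len {row.avg_len}, "
            f"len range {row.len_range[0]}-{row.len_range[1]}, "
            f"avg ident {row.avg_ident}"
        )

    diff = compare_partitions(a, b)
    print(
        f"\nrun A vs run B: {diff.merge_events} merge event(s), "
        f"{len(diff.moved_genes)} gene(s) with changed co-membership, "
        f"pairwise disagreement {diff.pairwise_disagreement}"
    )
    print(
        "A single absorbed singleton changes the co-membership of every gene "
        "in the receiving cluster — small parameter-driven differences are "
        "visible long before they change headline core-gene counts."
    )
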