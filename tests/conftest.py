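import random

import pytest

from panfam.cluster_io import Cluster, ClusterMember, ClusterSet
from panfam.pangenome_infer import infer_pangenome
from panfam.reference_clusterer import ClusteringParams, greedy_cluster
from panfam.synthetic_fixtures import PangenomeSpec, generate_pangenome

GFF_ONE_CDS = """##gff-version 3
ctg1\tsrc\tCDS\t1\t9\t.\t{strand}\t0\tID=gene1
##FASTA
>ctg1
ATGAAATAAGG
"""


@pytest.fixture
def gff_file(tmp_path):
    """Factory for small single-genome GFF3 files with embedded FASTA."""

    def make(body: str, name: str = "genomeA.gff3"):
        path = tmp_path / name
        path.write_text(body)
        return path

    return make


def random_cluster_set(rng: random.Random, n_clusters: int = 20) -> ClusterSet:
    """A valid fuzzed ClusterSet with identities/strands on non-representatives."""
    cs = ClusterSet()
    uid = 0
    for idx in range(n_clusters):
        size = rng.randint(1, 6)
        members = []
        rep_pos = rng.randrange(size)
        for j in range(size):
            is_rep = j == rep_pos
            members.append(
                ClusterMember(
                    seq_id=f"g{rng.randint(0, 9)}|gene_{uid}",
                    length=rng.randint(50, 900),
                    identity_pct=None if is_rep else round(rng.uniform(80, 100), 2),
                    strand=None if is_rep else rng.choice("+-"),
                    is_representative=is_rep,
                )
            )
            uid += 1
        cs.clusters.append(Cluster(index=idx, members=members))
    cs.validate()
    return cs


@pytest.fixture
def fuzzed_cluster_set():
    return random_cluster_set(random.Random(42), n_clusters=100)


# A small planted pangenome shared by workflow/recluster/acceptance tests.
SMALL_SPEC = PangenomeSpec(n_genomes=8, n_core=10, n_accessory=6, seed=7)


@pytest.fixture(scope="session")
def small_planted():
    """(sequences, truth) for a small planted pangenome."""
    layout, truth = generate_pangenome(SMALL_SPEC)
    seqs = {
        f"{genome}|{gid}": dna
        for genome, placements in layout.items()
        for gid, dna, _s, _e, _st in placements
    }
    return seqs, truth


@pytest.fixture(scope="session")
def small_clustering(small_planted):
    seqs, truth = small_planted
    cs = greedy_cluster(seqs, ClusteringParams(c=0.90, s=0.80))
    return cs


@pytest.fixture(scope="session")
def small_pangenome(small_clustering):
    return infer_pangenome(small_clustering)
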