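import random

import pytest

from panfam.cluster_io import write_clstr
from panfam.reference_clusterer import (
    ClusteringParams,
    greedy_cluster,
    pairwise_identity,
    shared_word_lower_bound,
)
from panfam.seq_ingest import reverse_complement

from oracles import gotoh_local_score


def _mutate(rng, seq, n_subs):
    seq = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(seq)


class TestClusteringParams:
    @pytest.mark.parametrize("raw, norm", [(0.9, 0.90), (0.8, 0.80), (0.955, 0.96)])
    def test_two_decimal_normalisation(self, raw, norm):
        assert ClusteringParams(c=raw).c == norm
        assert ClusteringParams(s=raw).s == norm

    def test_0_9_and_0_90_are_identical_parameterisations(self):
        assert ClusteringParams(c=0.9) == ClusteringParams(c=0.90)

    @pytest.mark.parametrize("kw", [{"c": 1.5}, {"s": -0.1}, {"mode": "rna"}, {"word_size": 1}])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            ClusteringParams(**kw)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident, overlap = pairwise_identity("ATGAAATAA", "ATGAAATAA")
        assert ident == 100.0 and overlap == 9

    def test_disjoint_alphabets_score_zero(self):
        ident, overlap = pairwise_identity("AAAA", "TTTT")
        assert ident == 0.0 and overlap == 0

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_short_sequence_contained_in_long_scores_full_identity(self):
        long = "ACGTACGTACGTACGTACGTACGTACGT"
        short = long[4:20]
        ident, overlap = pairwise_identity(short, long)
        assert ident == 100.0 and overlap == len(short)

    def test_single_substitution_identity(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + "A" + a[11:]
        assert a[10] != "A"
        ident, _ = pairwise_identity(a, b)
        assert ident == pytest.approx(100 * 19 / 20)

    def test_strict_mode_charges_internal_gaps(self):
        # b equals a with a 3-nt deletion: alignment has 3 internal gap columns
        a = "ACGTACGTTTACGTACGTAC"
        b = a[:8] + a[11:]
        lenient, _ = pairwise_identity(a, b)
        strict, _ = pairwise_identity(a, b, strict=True)
        assert strict < lenient

    def test_score_matches_gotoh_dp_oracle_on_fuzzed_pairs(self):
        """The aligner's optimal local score equals an independent Gotoh DP
        on fuzzed pairs up to 30 nt; the reported identity is bounded by the
        score (matches >= score) and by 100."""
        from panfam.reference_clusterer import _ALIGNER

        rng = random.Random(11)
        for _ in range(60):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            expected = gotoh_local_score(a, b)
            got = _ALIGNER.align(a, b).score if expected > 0 else 0
            assert got == expected
            ident, overlap = pairwise_identity(a, b)
            short = min(len(a), len(b))
            assert 0.0 <= ident <= 100.0
            assert ident >= 100.0 * expected / short - 1e-9
            assert overlap <= short


def _planted_families(rng, n_families=5, copies=6, length=120, subs=2):
    """Families of near-identical copies; inter-family identity is at the
    random background, far below threshold."""
    seqs = {}
    truth = {}
    for f in range(n_families):
        ancestor = "".join(rng.choice("ACGT") for _ in range(length))
        for c in range(copies):
            sid = f"fam{f}_copy{c}"
            seqs[sid] = _mutate(rng, ancestor, subs)
            truth[sid] = f
    return seqs, truth


class TestGreedyCluster:
    def test_two_identical_sequences_cluster_at_100(self):
        cs = greedy_cluster(
            {"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"},
            ClusteringParams(use_prefilter=False),
        )
        assert len(cs.clusters) == 1
        member = [m for m in cs.clusters[0].members if not m.is_representative][0]
        assert member.identity_pct == 100.0

    def test_length_cutoff_249_vs_291(self):
        """A 249/291 nt pair passes s=0.80 (ratio 0.8557) but fails s=0.90,
        whatever the identity."""
        rng = random.Random(5)
        long = "".join(rng.choice("ACGT") for _ in range(291))
        short = long[:249]
        assert 0.80 <= 249 / 291 < 0.90
        loose = greedy_cluster(
            {"long": long, "short": short},
            ClusteringParams(c=0.90, s=0.80, use_prefilter=False),
        )
        assert len(loose.clusters) == 1
        tight = greedy_cluster(
            {"long": long, "short": short},
            ClusteringParams(c=0.90, s=0.90, use_prefilter=False),
        )
        assert len(tight.clusters) == 2

    def test_planted_five_family_recovery(self):
        seqs, truth = _planted_families(random.Random(1))
        cs = greedy_cluster(seqs, ClusteringParams(c=0.90, s=0.80, use_prefilter=False))
        got = {frozenset(c.seq_ids) for c in cs.clusters}
        want = {
            frozenset(s for s in seqs if truth[s] == f) for f in set(truth.values())
        }
        assert got == want

    def test_reverse_complement_members_join_with_minus_strand(self):
        rng = random.Random(2)
        anc = "".join(rng.choice("ACGT") for _ in range(150))
        cs = greedy_cluster(
            {"fwd": anc, "rev": reverse_complement(_mutate(rng, anc, 2))},
            ClusteringParams(c=0.90, s=0.80, use_prefilter=False),
        )
        assert len(cs.clusters) == 1
        member = [m for m in cs.clusters[0].members if not m.is_representative][0]
        assert member.strand == "-"

    def test_determinism_byte_identical_clstr(self, tmp_path):
        seqs, _ = _planted_families(random.Random(9), n_families=4)
        outputs = []
        for run in range(2):
            cs = greedy_cluster(seqs, ClusteringParams())
            path = tmp_path / f"run{run}.clstr"
            write_clstr(cs, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_prefilter_is_a_pure_optimisation(self):
        seqs, _ = _planted_families(random.Random(13), n_families=6, copies=4)
        with_filter = greedy_cluster(seqs, ClusteringParams(use_prefilter=True))
        without = greedy_cluster(seqs, ClusteringParams(use_prefilter=False))
        assert {frozenset(c.seq_ids) for c in with_filter.clusters} == {
            frozenset(c.seq_ids) for c in without.clusters
        }

    def test_members_satisfy_both_thresholds_post_hoc(self):
        seqs, _ = _planted_families(random.Random(21), n_families=4, copies=5)
        params = ClusteringParams(c=0.90, s=0.80, use_prefilter=False)
        cs = greedy_cluster(seqs, params)
        for c in cs.clusters:
            rep_seq = seqs[c.representative_id]
            for m in c.members:
                if m.is_representative:
                    continue
                seq = seqs[m.seq_id]
                ratio = min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq))
                assert ratio >= params.s
                ident, _ = pairwise_identity(seq, rep_seq)
                assert ident >= 100 * params.c

    def test_raising_s_refines_the_partition(self):
        """On identity-separated families with heterogeneous lengths, raising
        the length cutoff can only split clusters, never merge them."""
        rng = random.Random(31)
        seqs = {}
        for f in range(4):
            anc = "".join(rng.choice("ACGT") for _ in range(200))
            for c, frac in enumerate((1.0, 0.95, 0.85, 0.7, 0.55)):
                cut = int(200 * frac)
                seqs[f"f{f}_c{c}"] = _mutate(rng, anc[:cut], 2)
        partitions = []
        for s in (0.0, 0.5, 0.8, 0.95):
            cs = greedy_cluster(
                seqs, ClusteringParams(c=0.90, s=s, use_prefilter=False)
            )
            partitions.append({frozenset(c.seq_ids) for c in cs.clusters})
        for coarse, fine in zip(partitions, partitions[1:]):
            for group in fine:
                assert any(group <= big for big in coarse)


def test_shared_word_bound_is_conservative_for_substitution_mutants():
    """Any pair differing by substitutions at rate <= 1-c shares at least the
    bound's number of k-mer windows, so the prefilter can never lose them."""
    rng = random.Random(4)
    k, c = 8, 0.90
    for _ in range(50):
        length = rng.randint(60, 600)
        a = "".join(rng.choice("ACGT") for _ in range(length))
        n_subs = int((1 - c) * length)
        b = _mutate(rng, a, n_subs)
        b_kmers = {b[i : i + k] for i in range(len(b) - k + 1)}
        hits = sum(1 for i in range(len(a) - k + 1) if a[i : i + k] in b_kmers)
        assert hits >= shared_word_lower_bound(length, k, c)
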