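import csv
import io

import pytest

from panfam.cluster_io import Cluster, ClusterMember, ClusterSet
from panfam.pangenome_infer import (
    CategoryScheme,
    GeneFamily,
    PangenomeResult,
    build_presence_absence,
    classify_family,
    infer_pangenome,
    summary_statistics_lines,
    trace_genomes,
    write_family_fastas,
    write_presence_absence,
)

from oracles import integer_band_oracle


class TestCategoryScheme:
    def test_default_bands(self):
        scheme = CategoryScheme.default()
        assert scheme.names == [
            "First_core_99",
            "First_core_95",
            "First_core_15",
            "First_core_0",
        ]
        assert [b for _, b in scheme.bands] == [99, 95, 15, 0]

    def test_intervals_cover_0_to_100(self):
        intervals = CategoryScheme.default().intervals()
        assert intervals[0][2] == 100 and intervals[-1][1] == 0
        for (_, lo1, hi1), (_, lo2, hi2) in zip(intervals, intervals[1:]):
            assert lo1 == hi2

    @pytest.mark.parametrize(
        "bounds", [[95, 99, 0], [99, 95, 15], [99, 99, 0], [120, 0]]
    )
    def test_invalid_bounds_rejected(self, bounds):
        with pytest.raises(ValueError):
            CategoryScheme.from_bounds(bounds)


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "k, n, band",
        [
            (10, 10, "First_core_99"),  # 100% sits in the top band
            (19, 20, "First_core_95"),  # exactly 95%: lower bound inclusive
            (9, 10, "First_core_15"),  # 90% is shell
            (73, 74, "First_core_95"),  # 7300/74 compared rationally
            (1, 74, "First_core_0"),
            (3, 20, "First_core_15"),  # exactly 15%
        ],
    )
    def test_boundary_examples(self, k, n, band):
        assert classify_family(k, n) == band

    def test_full_sweep_matches_integer_oracle(self):
        """All (k, n <= 200) agree with a pure-integer band oracle."""
        for n in range(1, 201):
            for k in range(1, n + 1):
                assert classify_family(k, n) == integer_band_oracle(k, n)

    def test_monotone_in_genome_count(self):
        scheme = CategoryScheme.default()
        order = {name: i for i, name in enumerate(scheme.names)}
        for n in (7, 20, 74):
            ranks = [order[classify_family(k, n)] for k in range(1, n + 1)]
            assert ranks == sorted(ranks, reverse=True)

    def test_custom_scheme_boundaries(self):
        scheme = CategoryScheme.from_bounds([90, 50, 0], ["hi", "mid", "lo"])
        assert classify_family(9, 10, scheme) == "hi"
        assert classify_family(5, 10, scheme) == "mid"
        assert classify_family(4, 10, scheme) == "lo"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_family(1, 0)
        with pytest.raises(ValueError):
            classify_family(0, 5)
        with pytest.raises(ValueError):
            classify_family(6, 5)


def _cluster(idx, ids, rep=None):
    rep = rep or ids[0]
    return Cluster(
        index=idx,
        members=[
            ClusterMember(seq_id=s, length=90, is_representative=(s == rep))
            for s in ids
        ],
    )


class TestTraceGenomes:
    def test_paralogs_collapse_into_one_genome(self):
        cs = ClusterSet(clusters=[_cluster(0, ["gA|x", "gA|y", "gB|z"])])
        (fam,) = trace_genomes(cs)
        assert fam.genome_count == 2 and fam.gene_count == 3
        assert fam.members_by_genome["gA"] == ["gA|x", "gA|y"]

    def test_singletons_from_distinct_genomes(self):
        cs = ClusterSet(
            clusters=[_cluster(i, [f"g{i}|a"]) for i in range(74)]
        )
        fams = trace_genomes(cs)
        assert len(fams) == 74 and all(f.genome_count == 1 for f in fams)

    def test_untagged_id_is_hard_error(self):
        cs = ClusterSet(clusters=[_cluster(0, ["no_separator_here"])])
        with pytest.raises(Exception, match="no_separator_here"):
            trace_genomes(cs)

    def test_gene_count_conservation_on_fuzzed_sets(self, fuzzed_cluster_set):
        fams = trace_genomes(fuzzed_cluster_set)
        assert sum(f.gene_count for f in fams) == len(fuzzed_cluster_set.universe)


def _result(families, genomes, scheme=None):
    scheme = scheme or CategoryScheme.default()
    total = len(genomes)
    for f in families:
        f.category = classify_family(f.genome_count, total, scheme)
    return PangenomeResult(genomes=sorted(genomes), families=families, scheme=scheme)


def _family(fid, members_by_genome):
    some_gene = next(iter(members_by_genome.values()))[0]
    return GeneFamily(
        family_id=fid, members_by_genome=members_by_genome, representative_id=some_gene
    )


class TestPresenceAbsence:
    def test_arithmetic_columns(self):
        pr = _result(
            [_family("group_0", {"gA": ["gA|x", "gA|y"], "gB": ["gB|z"]})],
            ["gA", "gB", "gC"],
        )
        rows = build_presence_absence(pr)
        header, row = rows
        assert header[:6] == [
            "Gene",
            "Non-unique Gene name",
            "Annotation",
            "No. isolates",
            "No. sequences",
            "Avg sequences per isolate",
        ]
        assert row[3:6] == ["2", "3", "1.5"]
        assert row[6] == "gA|x\tgA|y" and row[7] == "gB|z" and row[8] == ""

    def test_empty_pangenome_header_only(self):
        pr = _result([], [])
        assert build_presence_absence(pr) == [list(pr.scheme.names) * 0 + [
            "Gene",
            "Non-unique Gene name",
            "Annotation",
            "No. isolates",
            "No. sequences",
            "Avg sequences per isolate",
        ]]

    def test_quoted_csv_with_tab_joined_cells(self, tmp_path):
        pr = _result(
            [_family("group_0", {"gA": ["gA|x", "gA|y"]})], ["gA"]
        )
        path = tmp_path / "gpa.csv"
        write_presence_absence(pr, path)
        text = path.read_text()
        assert '"gA|x\tgA|y"' in text
        parsed = list(csv.reader(io.StringIO(text)))
        assert parsed[1][6] == "gA|x\tgA|y"

    def test_fuzzed_consistency(self, fuzzed_cluster_set):
        pr = infer_pangenome(fuzzed_cluster_set)
        rows = build_presence_absence(pr)
        assert len(rows) - 1 == len(pr.families)
        by_id = {f.family_id: f for f in pr.families}
        isolates = []
        for row in rows[1:]:
            fam = by_id[row[0]]
            non_empty = sum(1 for cell in row[6:] if cell)
            assert non_empty == fam.genome_count == int(row[3])
            assert sum(len(cell.split("\t")) for cell in row[6:] if cell) == fam.gene_count
            isolates.append(int(row[3]))
        assert isolates == sorted(isolates, reverse=True)


class TestSummaryStatistics:
    def test_default_scheme_counts(self):
        fams = [
            _family(f"group_{i}", {f"g{j}": [f"g{j}|a{i}"] for j in range(10)})
            for i in range(5)
        ] + [
            _family(f"group_{5+i}", {f"g{j}": [f"g{j}|b{i}"] for j in range(5)})
            for i in range(3)
        ]
        pr = _result(fams, [f"g{j}" for j in range(10)])
        lines = summary_statistics_lines(pr)
        assert lines[0] == "First_core_99 (99% <= strains <= 100%): 5"
        assert lines[1] == "First_core_95 (95% <= strains < 99%): 0"
        assert lines[2] == "First_core_15 (15% <= strains < 95%): 3"
        assert lines[3] == "First_core_0 (0% <= strains < 15%): 0"
        assert lines[4] == "Total genes: 8"

    def test_band_counts_partition_family_set(self, fuzzed_cluster_set):
        pr = infer_pangenome(fuzzed_cluster_set)
        assert sum(pr.totals.values()) == len(pr.families)

    def test_custom_scheme_names_verbatim(self):
        scheme = CategoryScheme.from_bounds([90, 50, 0], ["tight", "half", "rest"])
        pr = _result(
            [_family("group_0", {"gA": ["gA|x"]})], ["gA"], scheme=scheme
        )
        lines = summary_statistics_lines(pr)
        assert lines[0].startswith("tight (90% <= strains <= 100%):")
        assert lines[1].startswith("half (50% <= strains < 90%):")
        assert lines[2].startswith("rest (0% <= strains < 50%):")


class TestFamilyFastas:
    def test_per_family_files_and_conservation(self, tmp_path):
        pr = _result(
            [
                _family("group_0", {"gA": ["gA|x"], "gB": ["gB|y"]}),
                _family("group_1", {"gA": ["gA|z"]}),
            ],
            ["gA", "gB"],
        )
        seqs = {"gA|x": "ATG", "gB|y": "ATGA", "gA|z": "ATGAA"}
        write_family_fastas(pr, seqs, tmp_path)
        files = sorted(p.name for p in tmp_path.glob("*.fasta"))
        assert files == ["combined_families.fasta", "group_0.fasta", "group_1.fasta"]
        combined = (tmp_path / "combined_families.fasta").read_text()
        assert combined.count(">") == pr.total_gene_count == 3

    def test_missing_sequence_is_hard_error(self, tmp_path):
        pr = _result([_family("group_0", {"gA": ["gA|x"]})], ["gA"])
        with pytest.raises(KeyError, match="gA"):
            write_family_fastas(pr, {}, tmp_path)


def test_boundary_exactness_landing_on_bound_takes_higher_band():
    """k/n landing exactly on a bound always takes that band (lower-inclusive),
    swept with rational arithmetic over n <= 200."""
    for n in range(1, 201):
        for bound, expect in ((95, "First_core_95"), (15, "First_core_15")):
            # exact landings: 100*k == bound*n
            if (bound * n) % 100 == 0:
                k = bound * n // 100
                if 1 <= k <= n:
                    assert classify_family(k, n) == expect
    assert classify_family(99, 100) == "First_core_99"
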