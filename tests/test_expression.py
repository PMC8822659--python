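"""Expression cross-referencing, family matrix aggregation, clustering."""

import numpy as np
import pandas as pd
import pytest

from tfscout.errors import ConsistencyError, ParameterError
from tfscout.expression import (
    ExpressionParams,
    cluster_matrix,
    crossref,
    family_matrix,
)
from tfscout.simulate import (
    FamilySpec,
    embed_genes_in_contigs,
    generate_family_set,
    simulate_reads,
)


@pytest.fixture(scope="module")
def fixture_layout(tmp_path_factory):
    """Two families x 4 genes on their own contigs, reads over family A
    in sample 1 and family B in sample 2."""
    tmp = tmp_path_factory.mktemp("expr")
    records = generate_family_set(
        [FamilySpec("FamA", 4, 60, 0.05), FamilySpec("FamB", 4, 60, 0.05)], seed=13
    )
    contigs = embed_genes_in_contigs(records, spacer_length=50, strands="random", seed=13)
    regions = [(c.truth_regions[0].region, c.truth_regions[0].family) for c in contigs]
    ids_a = {r.record_id for r in records if r.family == "FamA"}
    ids_b = {r.record_id for r in records if r.family == "FamB"}
    sam_a = tmp / "sample_a.sam"
    sam_b = tmp / "sample_b.sam"
    simulate_reads(contigs, ids_a, read_length=60, depth=10, seed=1, path=sam_a)
    simulate_reads(contigs, ids_b, read_length=60, depth=10, seed=2, path=sam_b)
    return contigs, regions, sam_a, sam_b, ids_a, ids_b


class TestCrossref:
    def test_expressed_exactly_where_reads_were_placed(self, fixture_layout):
        contigs, regions, sam_a, _, ids_a, _ = fixture_layout
        profile = crossref(sam_a, regions, ExpressionParams())
        by_region = dict(zip(profile.table["region_id"], profile.table["expressed"]))
        for contig in contigs:
            truth = contig.truth_regions[0]
            assert by_region[truth.region.region_id] == (truth.record_id in ids_a)

    def test_read_counts_match_depth(self, fixture_layout):
        _, regions, sam_a, _, _, _ = fixture_layout
        profile = crossref(sam_a, regions, ExpressionParams())
        expressed = profile.table[profile.table["expressed"]]
        assert (expressed["read_count"] == 10).all()
        assert (expressed["covered_fraction"] > 0).all()
        silent = profile.table[~profile.table["expressed"]]
        assert (silent["read_count"] == 0).all()

    def test_single_base_overlap_counts(self, tmp_path, fixture_layout):
        contigs, regions, *_ = fixture_layout
        contig = contigs[0]
        region = contig.truth_regions[0].region
        # read ends exactly one base inside the region
        pos = region.start - 49  # 0-based; 50 nt read overlaps 1 base
        sam = "\n".join(
            ["@HD\tVN:1.6\tSO:coordinate"]
            + [f"@SQ\tSN:{c.contig_id}\tLN:{len(c.sequence)}" for c in contigs]
            + [
                "\t".join(
                    ("edge", "0", contig.contig_id, str(pos + 1), "60", "50M",
                     "*", "0", "0", contig.sequence[pos:pos + 50], "I" * 50)
                )
            ]
        ) + "\n"
        path = tmp_path / "edge.sam"
        path.write_text(sam)
        profile = crossref(path, regions, ExpressionParams())
        row = profile.table.set_index("region_id").loc[region.region_id]
        assert row["read_count"] == 1
        assert row["covered_fraction"] == pytest.approx(1.0 / region.length)

    def test_monotone_in_thresholds(self, fixture_layout):
        _, regions, sam_a, _, _, _ = fixture_layout
        previous = None
        for min_reads in (1, 5, 11):
            profile = crossref(sam_a, regions, ExpressionParams(min_reads=min_reads))
            n = int(profile.table["expressed"].sum())
            if previous is not None:
                assert n <= previous
            previous = n
        loose = crossref(sam_a, regions, ExpressionParams(min_covered_fraction=0.0))
        tight = crossref(sam_a, regions, ExpressionParams(min_covered_fraction=0.99))
        assert tight.table["expressed"].sum() <= loose.table["expressed"].sum()

    def test_unknown_contig_raises(self, fixture_layout, tmp_path):
        _, regions, sam_a, _, _, _ = fixture_layout
        from tfscout.translate import Region

        bad = regions + [(Region("ghost_contig", 0, 30, "+", 1), "FamZ")]
        with pytest.raises(ConsistencyError):
            crossref(sam_a, bad, ExpressionParams())


class TestFamilyMatrix:
    def test_block_structure_and_conservation(self, fixture_layout):
        _, regions, sam_a, sam_b, ids_a, ids_b = fixture_layout
        profiles = [
            crossref(sam_a, regions, ExpressionParams(), sample_id="s1"),
            crossref(sam_b, regions, ExpressionParams(), sample_id="s2"),
        ]
        matrix = family_matrix(profiles)
        assert matrix.loc["FamA", "s1"] == len(ids_a)
        assert matrix.loc["FamA", "s2"] == 0
        assert matrix.loc["FamB", "s2"] == len(ids_b)
        total_expressed = sum(int(p.table["expressed"].sum()) for p in profiles)
        assert int(matrix.to_numpy().sum()) == total_expressed

    def test_single_cell_matrix(self, fixture_layout):
        _, regions, sam_a, _, _, _ = fixture_layout
        famA_regions = [(r, f) for r, f in regions if f == "FamA"]
        profile = crossref(sam_a, famA_regions, ExpressionParams(), sample_id="only")
        matrix = family_matrix([profile])
        assert matrix.shape == (1, 1)
        assert matrix.iloc[0, 0] == len(famA_regions)

    def test_inconsistent_region_sets_rejected(self, fixture_layout):
        _, regions, sam_a, sam_b, _, _ = fixture_layout
        p1 = crossref(sam_a, regions, ExpressionParams(), sample_id="s1")
        p2 = crossref(sam_b, regions[:-1], ExpressionParams(), sample_id="s2")
        with pytest.raises(ConsistencyError):
            family_matrix([p1, p2])


class TestClusterMatrix:
    def test_identical_columns_merge_at_zero(self):
        matrix = pd.DataFrame(
            {"s1": [5, 0, 2], "s2": [5, 0, 2], "s3": [0, 9, 1]},
            index=["FamA", "FamB", "FamC"],
        )
        result = cluster_matrix(matrix)
        assert result.col_linkage[0][2] == 0.0  # first merge at distance zero
        first = {result.col_labels[int(result.col_linkage[0][0])],
                 result.col_labels[int(result.col_linkage[0][1])]}
        assert first == {"s1", "s2"}

    def test_block_diagonal_recovered_at_k2(self):
        matrix = pd.DataFrame(
            {
                "s1": [8, 7, 0, 0], "s2": [6, 9, 0, 0],
                "s3": [0, 0, 9, 6], "s4": [0, 0, 7, 8],
            },
            index=["FamA", "FamB", "FamC", "FamD"],
        )
        result = cluster_matrix(matrix)
        cut = result.cut_cols(2)
        assert cut["s1"] == cut["s2"]
        assert cut["s3"] == cut["s4"]
        assert cut["s1"] != cut["s3"]
        rows = result.cut_rows(2)
        assert rows["FamA"] == rows["FamB"] != rows["FamC"] == rows["FamD"]

    def test_permutation_invariance_of_partitions(self):
        matrix = pd.DataFrame(
            {"s1": [8, 7, 0], "s2": [0, 1, 9], "s3": [7, 6, 1]},
            index=["FamA", "FamB", "FamC"],
        )
        shuffled = matrix.iloc[[2, 0, 1], [1, 2, 0]]
        a = cluster_matrix(matrix)
        b = cluster_matrix(shuffled)
        assert a.cut_rows(2) == b.cut_rows(2)
        assert a.cut_cols(2) == b.cut_cols(2)
        assert a.row_newick == b.row_newick

    def test_single_column_trivial_dendrogram(self):
        matrix = pd.DataFrame({"s1": [3, 1]}, index=["FamA", "FamB"])
        result = cluster_matrix(matrix)
        assert result.col_linkage is None
        assert result.col_newick == "s1;"

    def test_newick_parses(self):
        matrix = pd.DataFrame(
            {"s1": [8, 0], "s2": [7, 1], "s3": [0, 9]}, index=["FamA", "FamB"]
        )
        result = cluster_matrix(matrix)
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(result.col_newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["s1", "s2", "s3"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            cluster_matrix(pd.DataFrame())
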