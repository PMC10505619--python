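import numpy as np
import pytest

from oracles import naive_unique_substitution_scan

from adaptscan.io_formats import Alignment, ConfigurationError, SeqRecord
from adaptscan.substitutions import (
    SiftTable,
    gap_mask,
    scan_unique_substitutions,
    score_impact,
)
from adaptscan.synthetic_data import simulate_protein_alignment


def aln_from_rows(rows):
    return Alignment(
        [SeqRecord(f"r{i}" if i else "FOCAL", s) for i, s in enumerate(rows)],
        "protein",
    )


class TestGapMask:
    def test_gap_free_alignment_all_allowed(self):
        aln = aln_from_rows(["MKT", "MRT", "MRT"])
        assert gap_mask(aln, 10).allowed.all()

    def test_single_gap_at_column_12_window_10(self):
        # 25 columns, gap at column 12 (1-based): only 1, 23, 24, 25 survive
        rows = ["A" * 25, "A" * 11 + "-" + "A" * 13, "A" * 25]
        mask = gap_mask(aln_from_rows(rows), 10)
        allowed_1based = [c + 1 for c in np.nonzero(mask.allowed)[0]]
        assert allowed_1based == [1, 23, 24, 25]

    def test_window_zero_excludes_only_gap_columns(self):
        rows = ["AAAA", "A-AA"]
        mask = gap_mask(aln_from_rows(rows), 0)
        assert list(mask.allowed) == [True, False, True, True]

    def test_monotone_in_window(self, rng):
        aln, _ = simulate_protein_alignment(
            8, 40, gaps=[(5, 3, [2]), (25, 2, [4])], seed=5
        )
        previous = None
        for w in range(0, 15):
            n_allowed = int(gap_mask(aln, w).allowed.sum())
            if previous is not None:
                assert n_allowed <= previous
            previous = n_allowed


class TestScanner:
    def test_hit_and_nonuniform_background(self):
        hits = scan_unique_substitutions(
            aln_from_rows(["K", "R", "R", "R"]), "FOCAL", gap_mask(aln_from_rows(["K", "R", "R", "R"]), 0)
        )
        assert len(hits) == 1
        assert (hits[0].focal_residue, hits[0].background_residue) == ("K", "R")
        none = scan_unique_substitutions(
            aln_from_rows(["K", "R", "R", "Q"]), "FOCAL"
        )
        assert none == []

    def test_focal_gap_is_not_a_substitution(self):
        aln = aln_from_rows(["-AA", "RAA", "RAA", "RAA"])
        assert scan_unique_substitutions(aln, "FOCAL", gap_mask(aln, 0)) == []

    def test_missing_focal_row_errors(self):
        aln = Alignment([SeqRecord("a", "K"), SeqRecord("b", "R"), SeqRecord("c", "R")], "protein")
        with pytest.raises(ConfigurationError, match="FOCAL"):
            scan_unique_substitutions(aln, "FOCAL")

    def test_planted_fixture_with_gap_windows(self):
        planted = [(2, "K", "R"), (20, "W", "G"), (40, "D", "E"), (60, "F", "L"), (75, "H", "Y")]
        aln, truth = simulate_protein_alignment(
            19, 80, planted=planted, gaps=[(18, 4, [3]), (58, 2, [7])], seed=11
        )
        # two planted columns fall inside the masked windows
        assert len(truth) == 3
        hits = scan_unique_substitutions(aln, "FOCAL")
        assert [h.column for h in hits] == truth

    def test_matches_naive_oracle_on_random_fixtures(self, rng):
        for i in range(100):
            n_rows = int(rng.integers(4, 12))
            n_cols = int(rng.integers(10, 50))
            planted = []
            if rng.random() < 0.7:
                cols = rng.choice(n_cols, size=min(3, n_cols), replace=False)
                planted = [(int(c), "W", "G") for c in cols]
            gaps = []
            if rng.random() < 0.5:
                gaps = [(int(rng.integers(0, n_cols - 2)), 2, [int(rng.integers(1, n_rows))])]
            aln, _ = simulate_protein_alignment(
                n_rows, n_cols, planted=planted, gaps=gaps, seed=1000 + i,
                noise=float(rng.uniform(0, 0.3)),
            )
            got = [h.column for h in scan_unique_substitutions(aln, "FOCAL")]
            assert got == naive_unique_substitution_scan(aln, "FOCAL", 10)

    def test_background_row_order_irrelevant(self, rng):
        aln, _ = simulate_protein_alignment(10, 30, planted=[(4, "K", "R")], seed=2)
        base = [h.column for h in scan_unique_substitutions(aln, "FOCAL")]
        recs = [aln.records[0]] + list(rng.permutation(aln.records[1:]))
        shuffled = Alignment(list(recs), "protein")
        assert [h.column for h in scan_unique_substitutions(shuffled, "FOCAL")] == base


class TestImpact:
    def make_hits(self, aln):
        return scan_unique_substitutions(aln, "FOCAL", gap_mask(aln, 0))

    def test_blosum62_proxy_calls(self):
        # R->K scores +2 (tolerated); W->G scores -2 (deleterious)
        aln = aln_from_rows(["KG", "RW", "RW", "RW"])
        hits = score_impact(self.make_hits(aln))
        by_col = {h.column: h for h in hits}
        assert by_col[0].impact_score == 2 and not by_col[0].deleterious
        assert by_col[1].impact_score == -2 and by_col[1].deleterious
        assert all(h.source == "proxy" for h in hits)

    def test_imported_sift_rows_take_precedence(self, tmp_path):
        p = tmp_path / "sift.tsv"
        p.write_text(
            "gene\tposition\tprediction\tscore\n"
            "geneF\t1\tTOLERATED\t0.03\n"
            "geneF\t2\tDELETERIOUS\t0.5\n"
        )
        sift = SiftTable.from_tsv(p)
        aln = aln_from_rows(["KG", "RW", "RW", "RW"])
        hits = score_impact(self.make_hits(aln), sift=sift, focal_gene="geneF")
        by_col = {h.column: h for h in hits}
        # score 0.03 <= 0.05 -> deleterious even though prediction tolerated
        assert by_col[0].deleterious and by_col[0].source == "imported"
        assert by_col[1].deleterious and by_col[1].source == "imported"
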