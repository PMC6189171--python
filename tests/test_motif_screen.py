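"""Motif scanner, expression ranking and exclusion-funnel behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from itamorigins import motif_screen as ms


class TestScanSequence:
    def test_minimal_constructed_match(self):
        hits = ms.scan_sequence("YAALGGGGGGYAAI")
        assert [(h.start, h.spacer, h.end) for h in hits] == [(1, 6, 14)]
        assert hits[0].matched_seq == "YAALGGGGGGYAAI"

    def test_two_tyrosine_geometry_at_y191_y205(self):
        # lone anchor pair at residues 191/205 -> a single 10-residue spacer,
        # the arrangement of the moesin FERM-domain tyrosines
        seq = ["A"] * 210
        seq[190], seq[193] = "Y", "L"  # Y191 .. L194
        seq[204], seq[207] = "Y", "I"  # Y205 .. I208
        hits = ms.scan_sequence("".join(seq))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].spacer) == (191, 10)

    def test_unknown_symbols_fail_anchors_but_fill_spacer(self):
        assert ms.scan_sequence("XAALGGGGGGYAAI") == []  # X cannot anchor
        assert ms.scan_sequence("YAAXGGGGGGYAAI") == []  # X cannot be tail
        hits = ms.scan_sequence("YAALXXXXXXYAAI")  # X fine inside the spacer
        assert len(hits) == 1

    def test_overlapping_and_nested_matches_all_reported(self):
        # one first half-site pairing with two second half-sites (nested)
        seq = "YAALGGGGGGYAILGGYAAI"
        hits = ms.scan_sequence(seq)
        assert [(h.start, h.spacer) for h in hits] == [(1, 6), (1, 12)]

    def test_match_length_bounds_and_sequence_end(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list(ms.AMINO_ACIDS), size=60))
            for h in ms.scan_sequence(seq):
                assert 14 <= h.end - h.start + 1 <= 20
                assert h.end <= len(seq)

    @given(
        st.text(
            alphabet=ms.AMINO_ACIDS + "XBZ*",
            min_size=0,
            max_size=80,
        )
    )
    def test_scanner_equals_brute_force_oracle(self, seq):
        fast = [(h.start, h.spacer) for h in ms.scan_sequence(seq)]
        slow = [(h.start, h.spacer) for h in ms.brute_force_scan(seq)]
        assert fast == slow

    def test_decoy_hit_rate_matches_analytic_probability(self, rng):
        # >= 1e6 random positions; expected hits within 3 binomial SE
        n_seq, length = 2000, 500
        per_pair = (1 / 20) * (2 / 20) * (1 / 20) * (2 / 20)
        n_pairs = n_seq * sum(length - 8 - s + 1 for s in range(6, 13))
        expected = n_pairs * per_pair
        se = np.sqrt(n_pairs * per_pair * (1 - per_pair))
        observed = 0
        for _ in range(n_seq):
            seq = "".join(rng.choice(list(ms.AMINO_ACIDS), size=length))
            observed += len(ms.scan_sequence(seq))
        assert abs(observed - expected) <= 3 * se
        # and the helper agrees with the hand computation per start
        assert ms.expected_match_probability() == pytest.approx(7 * per_pair)

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ms.PatternError):
            ms.MotifPattern(tail1=frozenset())
        with pytest.raises(ms.PatternError):
            ms.MotifPattern(spacer_min=0)
        with pytest.raises(ms.PatternError):
            ms.MotifPattern(spacer_min=9, spacer_max=6)

    def test_pattern_string_roundtrip(self):
        p = ms.MotifPattern.from_string("Y-X-X-[LI]-X(6,12)-Y-X-X-[LI]")
        assert p == ms.MotifPattern()
        assert ms.MotifPattern.from_string(p.to_string()) == p


class TestScanProteome:
    def test_planted_proteins_found(self):
        proteome = {
            "P1": "YAALGGGGGGYAAI" + "G" * 20,
            "P2": "G" * 30,
            "P3": "G" * 5 + "YAALGGGGGGYAAI",
            "P4": "A" * 25,
        }
        table = ms.scan_proteome(proteome)
        assert sorted(table["protein_id"]) == ["P1", "P3"]

    def test_two_disjoint_matches_one_row(self):
        # separator longer than the widest spacer so the blocks cannot pair
        seq = "YAALGGGGGGYAAI" + "G" * 20 + "YAALGGGGGGYAAI"
        table = ms.scan_proteome({"P": seq})
        assert len(table) == 1
        assert table.loc[0, "hit_count"] == 2

    def test_duplicate_ids_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(">A\nGGGG\n>A\nCCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            ms.read_proteome(fasta)


class TestRankCandidates:
    @staticmethod
    def table(genes):
        return pd.DataFrame(
            {
                "protein_id": genes,
                "gene": genes,
                "hit_count": 1,
                "first_start": 1,
                "first_spacer": 6,
            }
        )

    def test_single_dataset_order_equals_abundance_order(self):
        tab = self.table(list("ABCD"))
        ranked = ms.rank_candidates(tab, [{"A": 5.0, "B": 20.0, "C": 1.0, "D": 10.0}])
        assert list(ranked["gene"]) == ["B", "D", "A", "C"]

    def test_reversed_datasets_tie_broken_lexicographically(self):
        tab = self.table(list("DBCA"))
        up = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        down = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}
        ranked = ms.rank_candidates(tab, [up, down])
        assert ranked["aggregate_score"].nunique() == 1
        assert list(ranked["gene"]) == ["A", "B", "C", "D"]

    def test_top_n_flags_default_25(self):
        genes = [f"G{i:02d}" for i in range(30)]
        tab = self.table(genes)
        expr = {g: float(i + 1) for i, g in enumerate(genes)}
        ranked = ms.rank_candidates(tab, [expr])
        assert int(ranked["is_top"].sum()) == 25
        assert ranked["is_top"].head(25).all()

    def test_missing_gene_gets_rank_zero(self):
        tab = self.table(list("AB"))
        ranked = ms.rank_candidates(tab, [{"A": 3.0}])
        scores = dict(zip(ranked["gene"], ranked["aggregate_score"]))
        assert scores["B"] == 0.0
        assert scores["A"] > 0.0

    def test_row_order_permutation_invariance(self, rng):
        genes = [f"G{i}" for i in range(12)]
        expr = {g: float(v) for g, v in zip(genes, rng.uniform(1, 100, 12))}
        base = ms.rank_candidates(self.table(genes), [expr])
        shuffled = self.table(list(rng.permutation(genes)))
        again = ms.rank_candidates(shuffled, [expr])
        assert list(base["gene"]) == list(again["gene"])

    def test_monotone_rescaling_invariance(self, rng):
        genes = [f"G{i}" for i in range(10)]
        vals = rng.uniform(1, 100, 10)
        e1 = {g: float(v) for g, v in zip(genes, vals)}
        e2 = {g: float(np.log(v) ** 3 + 50) for g, v in zip(genes, vals)}
        r1 = ms.rank_candidates(self.table(genes), [e1])
        r2 = ms.rank_candidates(self.table(genes), [e2])
        assert np.allclose(r1["aggregate_score"], r2["aggregate_score"])

    def test_empty_expression_list_rejected(self):
        with pytest.raises(ValueError):
            ms.rank_candidates(self.table(list("AB")), [])


class TestExclusions:
    @staticmethod
    def ranked(genes):
        tab = TestRankCandidates.table(genes)
        return ms.rank_candidates(tab, [{g: float(i + 1) for i, g in enumerate(genes)}])

    def test_all_predicates_false_is_identity(self):
        tab = self.ranked(list("ABC"))
        ann = pd.DataFrame(
            {"secreted": [False] * 3}, index=pd.Index(list("ABC"), name="gene")
        )
        out = ms.apply_exclusions(tab, ann)
        assert not out["excluded"].any()
        assert len(ms.shortlist(out)) == 3

    def test_18_of_25_disqualified_leaves_7(self):
        genes = [f"G{i:02d}" for i in range(25)]
        tab = self.ranked(genes)
        ann = pd.DataFrame(
            {"secreted": [i < 18 for i in range(25)]},
            index=pd.Index(genes, name="gene"),
        )
        out = ms.apply_exclusions(tab, ann)
        assert int(out["excluded"].sum()) == 18
        assert len(ms.shortlist(out)) == 7

    def test_highest_precedence_rule_wins(self):
        rules = ms.ExclusionRules(order=["r_high", "r_low"])
        tab = self.ranked(["A"])
        for cols in (["r_high", "r_low"], ["r_low", "r_high"]):
            ann = pd.DataFrame(
                {c: [True] for c in cols}, index=pd.Index(["A"], name="gene")
            )
            out = ms.apply_exclusions(tab, ann, rules)
            assert out.loc[0, "exclusion_reason"] == "r_high"

    def test_unknown_rule_name_rejected(self):
        tab = self.ranked(["A"])
        ann = pd.DataFrame({"bogus": [True]}, index=pd.Index(["A"], name="gene"))
        with pytest.raises(ValueError, match="unknown rule"):
            ms.apply_exclusions(tab, ann)

    def test_shipped_rule_table_loads(self):
        from importlib.resources import files

        path = files("itamorigins").joinpath("data/exclusion_rules.tsv")
        rules = ms.ExclusionRules.from_tsv(str(path))
        assert rules.order[0] == "known_itam_receptor"
        assert len(rules.order) >= 4
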