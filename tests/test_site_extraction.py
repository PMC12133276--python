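import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asclust.io_core import MSA, PairwiseAlignment
from asclust.pocket import PocketDefinition
from asclust.site_extraction import (
    ActiveSiteSequence,
    IdentityReport,
    apply_gap_discard,
    apply_identity_gate,
    extract_sites_from_msa,
    global_align,
    global_align_score,
    map_pocket_through_alignment,
    percent_identity,
    read_sites_tsv,
    select_reference,
    write_sites_tsv,
)

from oracles import enumerate_global_alignment_score


def aln(ref_row, target_row, ref_id="r", target_id="t"):
    return PairwiseAlignment(ref_id, target_id, ref_row, target_row)


def seq_pocket(indices_1based, ref_sequence):
    """Pocket whose residue numbers are 1-based positions in the sequence."""
    positions = tuple(
        ("A", i, "", ref_sequence[i - 1]) for i in sorted(indices_1based)
    )
    return PocketDefinition("r", positions, "user")


class TestPercentIdentity:
    @pytest.mark.parametrize("ref,tgt,expected", [
        ("ACDE", "ACDE", 100.0),
        ("AC-E", "ACDE", 100.0),   # 3 matches over 3 both-non-gap columns
        ("AAAA", "CCCC", 0.0),
        ("----", "ACDE", 0.0),     # no both-non-gap column
    ])
    def test_examples(self, ref, tgt, expected):
        assert percent_identity(aln(ref, tgt)) == pytest.approx(expected)

    @given(st.lists(st.sampled_from(["A", "C", "D", "-"]), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_in_rows(self, chars):
        rng = np.random.default_rng(hash(tuple(chars)) % 2**31)
        row1 = "".join(chars)
        row2 = "".join(rng.choice(list("ACD-"), size=len(chars)))
        keep = [(a, b) for a, b in zip(row1, row2) if (a, b) != ("-", "-")]
        if not keep:
            return
        r1 = "".join(a for a, _ in keep)
        r2 = "".join(b for _, b in keep)
        assert percent_identity(aln(r1, r2)) == pytest.approx(
            percent_identity(aln(r2, r1, "t", "r")))


class TestSelectReference:
    def test_best_identity_wins(self):
        a1 = aln("AAAAAAAAAA", "AAAACCCCCC", ref_id="refA")  # 40%
        a2 = aln("AAAAAAAAAA", "AAAAAACCCC", ref_id="refB")  # 60%
        best, report = select_reference([a1, a2])
        assert best.ref_id == "refB"
        assert report.percent_identity == pytest.approx(60.0)

    def test_tie_prefers_first_listed(self):
        a1 = aln("AACC", "AAAA", ref_id="refA")
        a2 = aln("CCAA", "AAAA", ref_id="refB")
        best, _ = select_reference([a1, a2])
        assert best.ref_id == "refA"

    def test_single_reference_returned(self):
        a1 = aln("ACDE", "ACDE", ref_id="only")
        assert select_reference([a1])[0].ref_id == "only"

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            select_reference([])


class TestIdentityGate:
    def reports(self, *values):
        return [IdentityReport(f"m{i}", "r", v) for i, v in enumerate(values)]

    def test_just_below_threshold_discarded(self):
        kept, discarded = apply_identity_gate(self.reports(29.9))
        assert not kept and len(discarded) == 1
        assert discarded[0].reason == "identity<30"

    def test_exact_threshold_kept(self):
        kept, discarded = apply_identity_gate(self.reports(30.0))
        assert len(kept) == 1 and not discarded

    def test_zero_threshold_keeps_everything(self):
        kept, _ = apply_identity_gate(self.reports(0.0, 12.0, 99.0),
                                      threshold=0.0)
        assert len(kept) == 3


class TestPocketMapping:
    def test_identity_alignment(self):
        a = aln("ACDEF", "ACDEF")
        site = map_pocket_through_alignment(a, seq_pocket([1, 3, 5], "ACDEF"),
                                            "ACDEF")
        assert site.site == "ADF"

    def test_target_gap_becomes_gap_character(self):
        a = aln("ACDEF", "AC-EF")
        site = map_pocket_through_alignment(a, seq_pocket([3], "ACDEF"),
                                            "ACDEF")
        assert site.site == "-"

    def test_column_bookkeeping_across_reference_gap(self):
        a = aln("AC-DE", "ACXDE")
        site = map_pocket_through_alignment(a, seq_pocket([3, 4], "ACDE"),
                                            "ACDE")
        assert site.site == "DE"

    def test_mismatched_reference_sequence_errors(self):
        a = aln("ACDE", "ACDE")
        with pytest.raises(ValueError, match="does not match"):
            map_pocket_through_alignment(a, seq_pocket([1], "ACDF"), "ACDF")

    def test_pocket_beyond_reference_errors(self):
        a = aln("ACDE", "ACDE")
        with pytest.raises(ValueError, match="beyond"):
            map_pocket_through_alignment(a, seq_pocket([9], "ACDEFGHIK"),
                                         "ACDE")


class TestMsaExtraction:
    def test_rows_equal_to_reference_yield_reference_site(self):
        msa = MSA([("r", "ACDEF"), ("m1", "ACDEF"), ("m2", "ACDEF")])
        sites = extract_sites_from_msa(msa, "r", seq_pocket([1, 3], "ACDEF"),
                                       "ACDEF")
        assert [s.site for s in sites] == ["AD", "AD"]
        assert all(s.mode == "2d" for s in sites)

    def test_fully_gapped_row_gives_all_gap_site(self):
        msa = MSA([("r", "ACDEF"), ("m1", "-----")])
        sites = extract_sites_from_msa(msa, "r", seq_pocket([2, 4], "ACDEF"),
                                       "ACDEF")
        assert sites[0].site == "--"

    def test_insertion_column_outside_pocket_is_neutral(self):
        plain = MSA([("r", "ACDEF"), ("m1", "GCDEF")])
        inserted = MSA([("r", "-ACDEF"), ("m1", "WGCDEF")])
        pocket = seq_pocket([2, 4], "ACDEF")
        sites_plain = extract_sites_from_msa(plain, "r", pocket, "ACDEF")
        sites_ins = extract_sites_from_msa(inserted, "r", pocket, "ACDEF")
        assert [s.site for s in sites_plain] == [s.site for s in sites_ins]

    def test_missing_reference_errors(self):
        msa = MSA([("m1", "ACDEF")])
        with pytest.raises(ValueError, match="absent"):
            extract_sites_from_msa(msa, "r", seq_pocket([1], "ACDEF"), "ACDEF")


class TestGapDiscard:
    def site(self, s, member="m"):
        return ActiveSiteSequence(member, s, "r", "2d")

    def test_gappy_site_discarded(self):
        kept, discarded = apply_gap_discard([self.site("----AB--")])
        assert not kept
        assert discarded[0].reason == "gap_fraction>0.5"

    def test_gap_free_site_kept(self):
        kept, discarded = apply_gap_discard([self.site("ABCDEFGH")])
        assert len(kept) == 1 and not discarded

    def test_threshold_one_keeps_everything(self):
        kept, _ = apply_gap_discard([self.site("--------")],
                                    max_gap_fraction=1.0)
        assert len(kept) == 1

    def test_exactly_half_gapped_kept(self):
        kept, _ = apply_gap_discard([self.site("AB--")])
        assert len(kept) == 1  # 0.5 is not > 0.5


class TestGlobalAligner:
    def test_identical_sequences_align_gap_free(self):
        a = global_align("ACDE", "ACDE")
        assert a.ref_row == a.target_row == "ACDE"

    def test_single_mismatch_column(self):
        a = global_align("A", "G")
        assert (a.ref_row, a.target_row) == ("A", "G")

    def test_identity_score_is_diagonal_sum(self, dmat):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        seq = "ACDEFG"
        expected = sum(blosum[c, c] for c in seq)
        assert global_align_score(seq, seq) == pytest.approx(expected)

    @pytest.mark.parametrize("trial", range(25))
    def test_score_matches_exhaustive_enumeration(self, trial):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        sub = {(a, b): float(blosum[a, b])
               for a in blosum.alphabet for b in blosum.alphabet}
        rng = np.random.default_rng(9000 + trial)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        sa = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        sb = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        expected = enumerate_global_alignment_score(sa, sb, sub, 10.0, 0.5)
        assert global_align_score(sa, sb) == pytest.approx(expected)


class TestSitesTsv:
    def test_round_trip(self, tmp_path):
        sites = [ActiveSiteSequence("m1", "AC-E", "r", "3d"),
                 ActiveSiteSequence("m2", "ACDE", "r", "3d")]
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path)
        assert read_sites_tsv(path) == sites
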