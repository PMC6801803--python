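import numpy as np
import pytest

from shapefold.conservation import (AlignmentFormatError, StructuralAlignment,
                                    average_identity, covariation_scores,
                                    covariation_significance,
                                    map_structure_to_alignment, parse_ss_cons,
                                    read_stockholm, write_stockholm)
from shapefold.fold import SecondaryStructure

STO = """\
# STOCKHOLM 1.0
seq1 GGGAAACCC
seq2 GGGAAACCC
#=GC SS_cons <<<...>>>
//
"""


class TestStockholm:
    def test_parse_sequences_and_consensus_pairs(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(STO)
        aln = read_stockholm(p)
        assert aln.n_seqs == 2
        assert aln.column_pairs() == [(1, 9), (2, 8), (3, 7)]

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(STO)
        aln = read_stockholm(p)
        q = tmp_path / "b.sto"
        write_stockholm(aln, q)
        back = read_stockholm(q)
        assert back.ids == aln.ids
        assert back.seqs == aln.seqs
        assert back.column_pairs() == aln.column_pairs()

    def test_unbalanced_ss_cons_rejected(self):
        with pytest.raises(AlignmentFormatError, match="unbalanced"):
            parse_ss_cons("<<<...>>")

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentFormatError, match="ragged"):
            StructuralAlignment(ids=["a", "b"], seqs=["ACGU", "ACG"])

    def test_missing_ss_cons_is_an_error_when_pairs_needed(self):
        aln = StructuralAlignment(ids=["a", "b"], seqs=["ACGU", "ACGU"])
        with pytest.raises(AlignmentFormatError, match="SS_cons"):
            aln.column_pairs()


class TestAverageIdentity:
    def test_identical_sequences(self):
        aln = StructuralAlignment(ids=["a", "b"], seqs=["ACGU", "ACGU"])
        assert average_identity(aln) == 100.0

    def test_three_of_four(self):
        aln = StructuralAlignment(ids=["a", "b"], seqs=["ACGU", "ACGA"])
        assert average_identity(aln) == 75.0

    def test_gapped_columns_excluded_pairwise(self):
        aln = StructuralAlignment(ids=["a", "b"], seqs=["AC-U", "ACGU"])
        assert average_identity(aln) == 100.0

    def test_order_invariant(self, rng):
        seqs = ["".join(rng.choice(list("ACGU-"), 30)) for _ in range(5)]
        ids = [f"s{k}" for k in range(5)]
        a = average_identity(StructuralAlignment(ids=ids, seqs=seqs))
        perm = [3, 1, 4, 0, 2]
        b = average_identity(StructuralAlignment(
            ids=[ids[k] for k in perm], seqs=[seqs[k] for k in perm],
            ref_id=ids[3]))
        assert a == pytest.approx(b)


class TestStructureMapping:
    def test_ungapped_reference_is_identity(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        aln = StructuralAlignment(ids=["r", "h"],
                                  seqs=["GGGAAACCC", "GGGAAACCC"])
        assert map_structure_to_alignment(s, aln) == s.pair_list()

    def test_gap_shifts_columns(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        aln = StructuralAlignment(ids=["r", "h"],
                                  seqs=["-GGGAAACCC", "AGGGAAACCC"])
        assert map_structure_to_alignment(s, aln) == [
            (i + 1, j + 1) for i, j in s.pair_list()]

    def test_reference_mismatch_rejected(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        aln = StructuralAlignment(ids=["r", "h"],
                                  seqs=["GGGAAACCG", "GGGAAACCC"])
        with pytest.raises(ValueError, match="reference"):
            map_structure_to_alignment(s, aln)


def _compensatory_alignment(n_seqs=20):
    """Columns 1/10 covary perfectly (GC or AU); columns 2..9 invariant."""
    seqs = []
    for k in range(n_seqs):
        if k % 2:
            seqs.append("G" + "ACGUACGU" + "C")
        else:
            seqs.append("A" + "ACGUACGU" + "U")
    return StructuralAlignment(ids=[f"s{k}" for k in range(n_seqs)],
                               seqs=seqs)


class TestCovariation:
    def test_invariant_columns_have_zero_mi(self):
        aln = _compensatory_alignment()
        df = covariation_scores(aln, [(2, 3)])
        assert df["MI_bits"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_5050_compensatory_pair_is_one_bit(self):
        aln = _compensatory_alignment()
        df = covariation_scores(aln, [(1, 10)])
        assert df["MI_bits"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_mi_is_nonnegative(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), 20)) for _ in range(12)]
        aln = StructuralAlignment(ids=[f"s{k}" for k in range(12)], seqs=seqs)
        pairs = [(1, 20), (2, 19), (3, 18), (5, 15)]
        assert (covariation_scores(aln, pairs)["MI_bits"] >= 0).all()

    def test_sparse_pair_is_undefined(self):
        seqs = ["AC", "A-", "A-", "A-", "A-", "AC", "AC", "AC"]
        aln = StructuralAlignment(ids=[f"s{k}" for k in range(8)], seqs=seqs)
        assert np.isnan(covariation_scores(aln, [(1, 2)])["MI_bits"]).all()

    def test_too_few_sequences_rejected(self):
        aln = StructuralAlignment(ids=["a", "b"], seqs=["ACGU", "ACGU"])
        with pytest.raises(ValueError, match="sequences"):
            covariation_scores(aln, [(1, 4)])


class TestSignificance:
    def test_compensatory_pair_significant_invariant_pair_not(self):
        aln = _compensatory_alignment()
        out = covariation_significance(aln, [(1, 10), (2, 9)], n_perm=200,
                                       seed=0)
        assert bool(out["significant"].iloc[0])
        assert out["p"].iloc[1] > 0.5

    def test_same_seed_reproduces_q_values(self):
        aln = _compensatory_alignment()
        a = covariation_significance(aln, [(1, 10), (2, 9)], n_perm=150,
                                     seed=7)
        b = covariation_significance(aln, [(1, 10), (2, 9)], n_perm=150,
                                     seed=7)
        np.testing.assert_array_equal(a["q"].to_numpy(), b["q"].to_numpy())

    def test_low_n_perm_warns(self):
        aln = _compensatory_alignment()
        with pytest.warns(UserWarning, match="unstable"):
            covariation_significance(aln, [(1, 10)], n_perm=50, seed=0)
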