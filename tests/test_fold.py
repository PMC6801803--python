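import math

import numpy as np
import pytest

from shapefold.fold import (DEFAULT_MODEL, EnergyModel, InvariantViolation,
                            SecondaryStructure, energy_of,
                            enumerate_structures, fold_mfe, fold_suboptimal,
                            partition_function, pseudo_energy, read_ct,
                            read_dot_bracket, structure_stats, write_ct,
                            write_dot_bracket)
from tests.conftest import random_sequence


class TestPseudoEnergy:
    def test_zero_reactivity_gives_intercept(self):
        assert pseudo_energy(0.0) == pytest.approx(-0.8)

    def test_no_data_gives_zero(self):
        assert pseudo_energy(float("nan")) == 0.0
        assert pseudo_energy(None) == 0.0

    def test_closed_form_at_e_minus_one(self):
        assert pseudo_energy(math.e - 1) == pytest.approx(1.8, abs=1e-12)


class TestMfe:
    def test_unpairable_sequence_is_open(self):
        s = fold_mfe("AAAAAA")
        assert (s.partner == -1).all()
        assert s.energy == 0.0

    def test_length_four_cannot_close_a_hairpin(self):
        assert fold_mfe("GCGC").n_pairs == 0

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            fold_mfe("ACGX")

    def test_deterministic(self, rng):
        seq = random_sequence(rng, 60)
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert (a.partner == b.partner).all()
        assert a.energy == b.energy

    def test_matches_enumeration_minimum(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 15))
            seq = random_sequence(rng, n)
            prof = rng.gamma(1.0, 0.6, n) if rng.random() < 0.5 else None
            best = enumerate_structures(seq, profile=prof)[0]
            s = fold_mfe(seq, profile=prof)
            assert s.energy == pytest.approx(best.energy, abs=1e-9)
            assert energy_of(s, profile=prof) == pytest.approx(s.energy,
                                                               abs=1e-9)


class TestEnumeration:
    def test_unpairable_gives_single_empty_structure(self):
        assert len(enumerate_structures("AAAAA")) == 1

    def test_single_possible_pair(self):
        assert len(enumerate_structures("GAAAC")) == 2

    def test_count_matches_independent_recurrence(self, rng):
        from shapefold.fold import _BASE_INDEX, _PT

        def count(seq, i, j):
            if j - i < 4:
                return 1
            total = count(seq, i + 1, j)
            for l in range(i + 4, j + 1):
                if _PT[_BASE_INDEX[seq[i]], _BASE_INDEX[seq[l]]] >= 0:
                    total += count(seq, i + 1, l - 1) * count(seq, l + 1, j)
            return total

        for seq in ["GGAAACC", "GCGCAAAAGCGC", random_sequence(rng, 12)]:
            assert len(enumerate_structures(seq)) == count(seq, 0, len(seq) - 1)

    def test_refuses_large_inputs(self):
        with pytest.raises(ValueError, match="refused"):
            enumerate_structures("A" * 21)


class TestSuboptimal:
    def test_zero_window_returns_only_mfe(self, rng):
        seq = random_sequence(rng, 40)
        subs = fold_suboptimal(seq, window=0.0)
        assert len(subs) == 1
        assert subs[0].energy == pytest.approx(fold_mfe(seq).energy)

    def test_single_pair_sequence_has_two_structures(self):
        subs = fold_suboptimal("GAAAC", window=50.0)
        assert sorted(s.dot_bracket() for s in subs) == ["(...)", "....."]

    def test_complete_within_window(self, rng):
        seq = "GGGAGAUUUCCCAU"
        window = 4.0
        ref = {s.dot_bracket() for s in enumerate_structures(seq)
               if s.energy <= enumerate_structures(seq)[0].energy + window + 1e-9}
        got = {s.dot_bracket()
               for s in fold_suboptimal(seq, max_models=10000, window=window)}
        assert got == ref

    def test_energies_rescore_exactly(self, small_rna, small_profile):
        subs = fold_suboptimal(small_rna.sequence, small_profile, max_models=5)
        for s in subs:
            assert energy_of(s, small_profile) == pytest.approx(s.energy,
                                                                abs=1e-9)
        energies = [s.energy for s in subs]
        assert energies == sorted(energies)


class TestPartitionFunction:
    def test_no_legal_pairs_means_zero_probabilities(self):
        assert partition_function("AAAAAA").P.sum() == 0.0

    def test_two_state_closed_form(self):
        # GAAAC: only the empty structure and the lone hairpin pair exist
        model = DEFAULT_MODEL
        E = model.loop_tables(5)[0][3]  # hairpin of 3
        expected = math.exp(-E / model.RT) / (1 + math.exp(-E / model.RT))
        P = partition_function("GAAAC").P
        assert P[0, 4] == pytest.approx(expected, abs=1e-9)

    def test_matches_boltzmann_enumeration(self, rng):
        for _ in range(6):
            n = int(rng.integers(8, 14))
            seq = random_sequence(rng, n)
            structs = enumerate_structures(seq)
            w = np.exp(-np.array([s.energy for s in structs]) / DEFAULT_MODEL.RT)
            ref = np.zeros((n, n))
            for s, wi in zip(structs, w / w.sum()):
                for i, j in s.pair_list():
                    ref[i - 1, j - 1] += wi
                    ref[j - 1, i - 1] += wi
            P = partition_function(seq).P
            assert np.abs(P - ref).max() < 1e-6

    def test_raising_reactivity_never_favors_pairing(self, rng):
        seq = "GGGCAAAAGCCCAUAU"
        prof = np.full(len(seq), 0.2)
        base = partition_function(seq, prof).paired_probability()
        for pos in (1, 2, 10):
            for r in (0.8, 2.0, 5.0):
                bumped = prof.copy()
                bumped[pos] = r
                p = partition_function(seq, bumped).paired_probability()
                assert p[pos] <= base[pos] + 1e-9


class TestStructureStats:
    def test_single_hairpin(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        st = structure_stats(s)
        assert st["percent_paired"] == pytest.approx(100 * 6 / 9)
        assert st["n_helices"] == 1
        assert st["n_internal_loops"] == 0
        assert st["n_terminal_loops"] == 1
        assert st["junctions"] == {}

    def test_asymmetric_internal_loop(self):
        s = SecondaryStructure.from_dot_bracket("GGAGGAAACCCC",
                                                "((.((...))))")
        st = structure_stats(s)
        assert st["n_helices"] == 2
        assert st["n_internal_loops"] == 1
        assert st["n_asymmetric"] == 1
        assert st["n_terminal_loops"] == 1

    def test_empty_structure(self):
        s = SecondaryStructure("ACGUACGU", np.full(8, -1))
        st = structure_stats(s)
        assert st["percent_paired"] == 0.0
        assert st["n_helices"] == 0

    def test_multibranch_junction_degree(self):
        db = "((...))((...))"
        seq = "GGAAACCGGAAACC"
        outer = "(" + db + ")"
        s = SecondaryStructure.from_dot_bracket("G" + seq + "C", outer)
        assert structure_stats(s)["junctions"] == {3: 1}


class TestStructureInvariants:
    def test_rejects_pseudoknot(self):
        partner = np.full(12, -1)
        partner[0], partner[6] = 6, 0
        partner[3], partner[10] = 10, 3
        with pytest.raises(InvariantViolation, match="pseudoknot"):
            SecondaryStructure("GAAGAACAAACA", partner)

    def test_rejects_short_hairpin(self):
        partner = np.full(6, -1)
        partner[0], partner[3] = 3, 0
        with pytest.raises(InvariantViolation, match="hairpin"):
            SecondaryStructure("GAACAA", partner)

    def test_rejects_non_canonical_pair(self):
        partner = np.full(6, -1)
        partner[0], partner[5] = 5, 0
        with pytest.raises(InvariantViolation, match="non-canonical"):
            SecondaryStructure("GAAAAG", partner)


class TestStructureIO:
    def test_ct_roundtrip(self, tmp_path, small_rna):
        path = tmp_path / "s.ct"
        write_ct(small_rna.structure, path)
        back = read_ct(path)
        assert back.sequence == small_rna.structure.sequence
        assert (back.partner == small_rna.structure.partner).all()

    def test_dot_bracket_roundtrip(self, tmp_path, small_rna):
        path = tmp_path / "s.db"
        write_dot_bracket(small_rna.structure, path)
        back = read_dot_bracket(path)
        assert (back.partner == small_rna.structure.partner).all()
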