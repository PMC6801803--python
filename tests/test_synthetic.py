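import numpy as np
import pytest

from shapefold.fold import fold_mfe
from shapefold.shotgun import FragmentSpec, fragment_correlation
from shapefold.synthetic import (SimulationParams, simulate_fragment,
                                 simulate_homologs, simulate_reactivities,
                                 simulate_rna, simulate_structure,
                                 suggest_disruptive_fragment,
                                 suggest_modular_fragment)


class TestSimulateStructure:
    def test_deterministic_for_a_seed(self):
        a = simulate_structure(80, seed=3)
        b = simulate_structure(80, seed=3)
        assert a[0] == b[0]
        assert (a[1].partner == b[1].partner).all()

    def test_satisfies_structure_invariants_and_pairing_floor(self):
        seq, s = simulate_structure(150, seed=9)
        s.validate()  # raises on violation
        assert 100.0 * (s.partner >= 0).sum() / len(s) >= 30.0

    def test_rejects_short_rnas(self):
        with pytest.raises(ValueError):
            simulate_structure(20, seed=0)


class TestSimulateReactivities:
    def test_zero_dropout_has_no_missing_shape_values(self, small_rna):
        params = SimulationParams(seed=5, dropout=0.0)
        prof = simulate_reactivities(small_rna.structure, "SHAPE", params)
        assert prof.defined_mask.all()

    def test_unpaired_positions_more_reactive(self):
        params = SimulationParams(seed=2, dropout=0.0)
        rna = simulate_rna(200, 2, params)
        prof = simulate_reactivities(rna.structure, "SHAPE", params)
        paired = rna.structure.partner >= 0
        assert (prof.reactivities[~paired].mean()
                > prof.reactivities[paired].mean())

    def test_dms_has_no_data_at_g_and_u(self, small_rna):
        prof = simulate_reactivities(small_rna.structure, "DMS",
                                     small_rna.params)
        gu = np.array([b in "GU" for b in small_rna.sequence])
        assert np.isnan(prof.reactivities[gu]).all()

    def test_byte_identical_repeat(self, small_rna):
        a = simulate_reactivities(small_rna.structure, "SHAPE",
                                  small_rna.params)
        b = simulate_reactivities(small_rna.structure, "SHAPE",
                                  small_rna.params)
        np.testing.assert_array_equal(a.reactivities, b.reactivities)


class TestSimulateFragment:
    def test_noise_free_identical_structure_gives_r_one(self):
        params = SimulationParams(seed=4, dropout=0.0, point_mass=True)
        rna = simulate_rna(150, 4, params)
        spec = FragmentSpec("whole", 1, len(rna))  # same fold as full-length
        full = simulate_reactivities(rna.structure, "SHAPE", params)
        frag = simulate_fragment(rna, spec, params)
        out = fragment_correlation(full, frag, spec)
        assert out["r"] == pytest.approx(1.0, abs=1e-12)

    def test_modular_fragment_correlates_disruptive_does_not(self):
        rs_mod, rs_dis = [], []
        for seed in range(5):
            params = SimulationParams(seed=seed)
            rna = simulate_rna(200, seed, params)
            full = simulate_reactivities(rna.structure, "SHAPE", params)
            mspec = suggest_modular_fragment(rna.structure)
            dspec = suggest_disruptive_fragment(rna.structure)
            fm = simulate_fragment(rna, mspec, params)
            fd = simulate_fragment(rna, dspec, params)
            rs_mod.append(fragment_correlation(full, fm, mspec)["r"])
            rs_dis.append(fragment_correlation(full, fd, dspec)["r"])
        assert np.mean(rs_mod) >= 0.9
        assert np.mean(rs_dis) < np.mean(rs_mod)


class TestSimulateHomologs:
    def test_no_mutation_rate_gives_identical_rows(self, small_rna):
        aln = simulate_homologs(small_rna.sequence, small_rna.structure,
                                n_seqs=5, background_rate=0.0,
                                covarying_pairs=[], seed=1)
        assert all(s == small_rna.sequence for s in aln.seqs)

    def test_designated_pairs_stay_complementary(self, small_rna):
        from shapefold.fold import PAIR_TYPES

        cov = small_rna.structure.pair_list()[:8]
        aln = simulate_homologs(small_rna.sequence, small_rna.structure,
                                n_seqs=30, background_rate=0.25,
                                covarying_pairs=cov, seed=6)
        for s in aln.seqs:
            for i, j in cov:
                assert s[i - 1] + s[j - 1] in PAIR_TYPES

    def test_ss_cons_matches_the_structure(self, small_rna):
        aln = simulate_homologs(small_rna.sequence, small_rna.structure,
                                n_seqs=5, background_rate=0.1,
                                covarying_pairs=[], seed=1)
        assert aln.column_pairs() == small_rna.structure.pair_list()

    def test_rejects_pairs_not_in_structure(self, small_rna):
        with pytest.raises(ValueError, match="not in the structure"):
            simulate_homologs(small_rna.sequence, small_rna.structure,
                              n_seqs=5, background_rate=0.1,
                              covarying_pairs=[(1, 2)], seed=1)


class TestFragmentSuggestion:
    def test_modular_window_minimizes_crossings(self, small_rna):
        from shapefold.shotgun import external_pair_fraction

        spec = suggest_modular_fragment(small_rna.structure)
        dspec = suggest_disruptive_fragment(small_rna.structure)
        assert (external_pair_fraction(small_rna.structure, spec)
                <= external_pair_fraction(small_rna.structure, dspec))

    def test_disruptive_window_crosses_pairs(self, small_rna):
        from shapefold.synthetic import _crossing_count

        spec = suggest_disruptive_fragment(small_rna.structure)
        pairs = small_rna.structure.pair_list()
        crossed = _crossing_count(pairs, spec.start, spec.end)
        mspec = suggest_modular_fragment(small_rna.structure)
        assert crossed > 0
        assert crossed >= _crossing_count(pairs, mspec.start, mspec.end)

    def test_modular_rna_domains_do_not_interact(self):
        from shapefold.synthetic import simulate_modular_rna

        rna = simulate_modular_rna(200, seed=3, n_domains=2)
        boundary = 100
        for i, j in rna.structure.pair_list():
            assert (i <= boundary) == (j <= boundary)
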