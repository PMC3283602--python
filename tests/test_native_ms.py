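"""Native-MS ion arithmetic, peak assignment, and the IR_a statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4char import (
    BindingTable,
    GeneratorConfig,
    IonSpecies,
    MassSpectrum,
    assign_peaks,
    binding_table_from_assignments,
    gen_ms_spectrum,
    ira,
    oligo_mass,
    theoretical_mz,
)
from g4char.sequence_motifs import ATOMIC_MASS, RESIDUE_FORMULA, WATER_FORMULA
from g4char.native_ms import NH4_MASS, unassigned_peaks

H = ATOMIC_MASS["average"]["H"]


def adduct_oracle_mz(seq: str, a: int, b: int, z: int, ligand_mass: float) -> float:
    """Independent oracle: accumulate the full adduct's elemental formula
    (oligo + a x NH4 as N,H4), add the ligand mass, then apply the
    (M - n_H removed) / z bookkeeping element by element."""
    masses = ATOMIC_MASS["average"]
    counts: dict[str, float] = {}
    for base in seq:
        for el, n in RESIDUE_FORMULA[base].items():
            counts[el] = counts.get(el, 0) + n
    for el, n in WATER_FORMULA.items():
        counts[el] = counts.get(el, 0) + n
    counts["N"] = counts.get("N", 0) + a
    counts["H"] = counts.get("H", 0) + 4 * a
    counts["H"] -= z + a + b  # deprotonation: z charges + one per cation
    total = sum(masses[el] * n for el, n in counts.items()) + b * ligand_mass
    return total / z


class TestTheoreticalMz:
    def test_agrees_with_elemental_adduct_oracle(self, s1):
        M = oligo_mass(s1)
        for a, b, z in [(2, 0, 4), (2, 1, 4), (0, 0, 1), (3, 2, 5)]:
            sp = IonSpecies(charge=z, n_ammonium=a, n_ligand=b, ligand_cation_mass=336.4)
            expected = adduct_oracle_mz(s1.sequence, a, b, z, 336.4)
            # NH4 table vs N+4H elemental accumulation agree to < 2 mDa
            assert theoretical_mz(M, sp) == pytest.approx(expected, abs=0.002)

    def test_single_deprotonation(self, s1):
        M = oligo_mass(s1)
        assert theoretical_mz(M, IonSpecies(charge=1)) == pytest.approx(M - H)

    def test_ligand_increment_shifts_by_ligand_minus_proton_over_z(self, s1):
        M = oligo_mass(s1)
        for z in (3, 4, 5):
            lo = theoretical_mz(M, IonSpecies(charge=z, n_ammonium=2, n_ligand=1))
            hi = theoretical_mz(M, IonSpecies(charge=z, n_ammonium=2, n_ligand=2))
            assert hi - lo == pytest.approx((336.4 - H) / z, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        z=st.integers(min_value=1, max_value=8),
        a=st.integers(min_value=0, max_value=4),
        b=st.integers(min_value=0, max_value=3),
    )
    def test_charge_series_identity(self, z, a, b):
        """The neutral-complex mass recovered from any two charge states of
        the same adduct agrees to better than 1e-6 Da."""
        M = 5534.569

        def recover(zz: int) -> float:
            sp = IonSpecies(charge=zz, n_ammonium=a, n_ligand=b)
            mz = theoretical_mz(M, sp)
            return zz * mz + (zz + a + b) * H - a * NH4_MASS["average"] - b * 336.4

        assert abs(recover(z) - recover(z + 1)) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            IonSpecies(charge=0)
        with pytest.raises(ValueError):
            theoretical_mz(-1.0, IonSpecies(charge=4))


class TestMassSpectrum:
    def test_normalizes_and_orders(self):
        spec = MassSpectrum.from_arrays([1500.0, 1400.0], [50.0, 200.0])
        assert spec.peaks[0][0] == 1400.0
        assert spec.rel_intensity.tolist() == [100.0, 25.0]

    def test_invariants(self):
        with pytest.raises(ValueError):
            MassSpectrum(peaks=[(1400.0, 100.0), (1400.0, 50.0)])
        with pytest.raises(ValueError):
            MassSpectrum(peaks=[(1400.0, 50.0)])  # no base peak

    def test_csv_round_trip(self, tmp_path, binding_spectrum):
        spec, _ = binding_spectrum
        path = tmp_path / "spec.csv"
        path.write_text(
            "mz,intensity\n"
            + "\n".join(f"{m},{i}" for m, i in spec.peaks)
        )
        loaded = MassSpectrum.from_csv(path)
        assert np.allclose(loaded.mz, spec.mz)
        assert np.allclose(loaded.rel_intensity, spec.rel_intensity)


class TestAssignPeaks:
    def _candidates(self, bs=(0, 1, 2)):
        return [IonSpecies(charge=4, n_ammonium=2, n_ligand=b) for b in bs]

    def test_round_trip_assignment(self, s1, binding_spectrum):
        spec, _ = binding_spectrum
        assignments = assign_peaks(spec, s1, self._candidates(), tol=0.5)
        assert len(assignments) == 3
        assert [a.species.n_ligand for a in assignments] == [0, 1, 2]
        assert all(abs(a.mz_error) < 0.05 for a in assignments)
        assert unassigned_peaks(spec, assignments) == []

    def test_shifted_spectrum_unassigned(self, s1, binding_spectrum):
        spec, _ = binding_spectrum
        shifted = MassSpectrum(
            peaks=[(mz + 5.0, ri) for mz, ri in spec.peaks], label="shifted"
        )
        assert assign_peaks(shifted, s1, self._candidates(), tol=0.5) == []

    def test_closest_candidate_wins_tie_to_smaller_b(self, s1):
        M = oligo_mass(s1)
        c0 = IonSpecies(charge=4, n_ammonium=2, n_ligand=0)
        c1 = IonSpecies(charge=4, n_ammonium=2, n_ligand=1)
        mz0, mz1 = theoretical_mz(M, c0), theoretical_mz(M, c1)
        # one peak exactly between the two candidates, both within tolerance
        spec = MassSpectrum(peaks=[((mz0 + mz1) / 2, 100.0)])
        got = assign_peaks(spec, s1, [c1, c0], tol=(mz1 - mz0))
        assert len(got) == 1
        assert got[0].species.n_ligand == 0  # tie broken toward smaller b
        # brute force over the candidate-peak pairs: both |errors| equal
        errs = [abs((mz0 + mz1) / 2 - m) for m in (mz0, mz1)]
        assert errs[0] == pytest.approx(errs[1], abs=1e-9)

    def test_one_peak_per_species(self, s1):
        M = oligo_mass(s1)
        c0 = IonSpecies(charge=4, n_ammonium=2, n_ligand=0)
        mz0 = theoretical_mz(M, c0)
        spec = MassSpectrum(peaks=[(mz0 - 0.1, 100.0), (mz0 + 0.3, 40.0)])
        got = assign_peaks(spec, s1, [c0], tol=1.0)
        assert len(got) == 1 and got[0].peak_index == 0  # closer peak wins

    def test_empty_candidates_error(self, s1, binding_spectrum):
        spec, _ = binding_spectrum
        with pytest.raises(ValueError):
            assign_peaks(spec, s1, [], tol=1.0)


class TestBindingTableAndIra:
    def test_paper_worked_example(self):
        table = BindingTable.from_dict({0: 30, 1: 100, 2: 75, 3: 0})
        assert ira(table) == pytest.approx(0.85)
        assert ira(table, round_to=None) == pytest.approx(175 / 205)

    @pytest.mark.parametrize(
        "d, expected",
        [({0: 100}, 0.0), ({0: 0, 1: 50}, 1.0)],
    )
    def test_degenerate_tables(self, d, expected):
        assert ira(BindingTable.from_dict(d)) == expected

    def test_all_zero_undefined(self):
        table = BindingTable.from_dict({})
        assert table.empty
        with pytest.raises(ValueError):
            ira(table)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=4,
            max_size=4,
        ).filter(lambda v: sum(v) > 0)
    )
    def test_bounds_and_resummation(self, vals):
        table = BindingTable(tuple(vals))
        got = ira(table, round_to=None)
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(sum(vals[1:]) / sum(vals))

    def test_monotone_in_complex_and_free_intensity(self):
        base = BindingTable((30.0, 100.0, 75.0, 0.0))
        more_complex = BindingTable((30.0, 120.0, 75.0, 0.0))
        more_free = BindingTable((50.0, 100.0, 75.0, 0.0))
        assert ira(more_complex, None) > ira(base, None) > ira(more_free, None)

    def test_table_from_assignments_pools_charge_states(self, s1):
        spec = MassSpectrum.from_arrays(
            [1100.0, 1390.0, 1475.0], [40.0, 30.0, 100.0]
        )
        from g4char import PeakAssignment

        assignments = [
            # same stoichiometry (b=1) at two charge states pools
            PeakAssignment(0, IonSpecies(charge=5, n_ligand=1), 0.0),
            PeakAssignment(2, IonSpecies(charge=4, n_ligand=1), 0.0),
            PeakAssignment(1, IonSpecies(charge=4, n_ligand=0), 0.0),
        ]
        table = binding_table_from_assignments(assignments, spec)
        assert table.intensities == (30.0, 140.0, 0.0, 0.0)

    def test_no_assignments_flagged(self, binding_spectrum):
        spec, _ = binding_spectrum
        table = binding_table_from_assignments([], spec)
        assert table.empty


class TestPipelineRoundTrip:
    def test_generated_spectrum_recovers_programmed_ira(self, s1):
        """generate -> assign -> table -> IR_a reproduces the generator's
        programmed ratio within rounding."""
        species = [
            (IonSpecies(charge=4, n_ammonium=2, n_ligand=b), h)
            for b, h in [(0, 30.0), (1, 100.0), (2, 75.0)]
        ]
        spec, _ = gen_ms_spectrum(species, s1, cfg=GeneratorConfig(seed=3))
        candidates = [IonSpecies(charge=4, n_ammonium=2, n_ligand=b) for b in range(4)]
        table = binding_table_from_assignments(
            assign_peaks(spec, s1, candidates, tol=1.0), spec
        )
        assert ira(table) == pytest.approx(0.85)
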