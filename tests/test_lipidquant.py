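"""Peak thresholding, database matching, isotope correction, quantitation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidscreen.lipids import LipidDatabase, LipidSpecies, isotope_envelope
from lipidscreen.lipidquant import (
    Assignment,
    PeakList,
    build_matrix,
    isotope_correct,
    match_peaks,
    quantify,
    quantify_peaklists,
    threshold_peaks,
)
from lipidscreen.synthetic import SpectrumConfig, generate_peaklists


def _species(name, mz, cls="SM", is_is=False, formula=None):
    return LipidSpecies(
        name=name,
        lipid_class=cls,
        formula=formula or {"C": 40, "H": 80, "N": 2, "O": 6, "P": 1},
        adduct="[M+H]+",
        exact_mz=mz,
        is_internal_standard=is_is,
    )


class TestThresholdPeaks:
    def test_3000_count_rule_is_strict(self):
        peaks = [(500.0 + i, 1000.0 * (i + 1)) for i in range(10)]
        pl = PeakList("s", "SM", np.array(peaks))
        kept = threshold_peaks(pl, 3000.0)
        assert len(kept) == 7
        removed = sorted(set(pl.peaks[:, 1]) - set(kept.peaks[:, 1]))
        assert removed[-1] == 3000.0

    def test_zero_threshold_keeps_positive_intensities(self):
        pl = PeakList("s", "SM", np.array([(500.0, 10.0), (501.0, 1.0)]))
        kept = threshold_peaks(pl, 0.0)
        assert len(kept) == 2

    @settings(derandomize=True, max_examples=50)
    @given(
        intensities=st.lists(st.floats(0, 1e6), min_size=0, max_size=30),
        threshold=st.floats(0, 1e5),
    )
    def test_matches_brute_force_filter(self, intensities, threshold):
        mz = 400.0 + np.arange(len(intensities))
        pl = PeakList("s", "SM", np.column_stack([mz, intensities]) if intensities else np.empty((0, 2)))
        kept = threshold_peaks(pl, threshold)
        expected = [i for i in intensities if i > threshold]
        assert sorted(kept.peaks[:, 1].tolist()) == sorted(expected)


class TestMatchPeaks:
    def test_5mda_tolerance_boundary(self):
        db = LipidDatabase([_species("SM 40:1", 800.0)])
        pl = PeakList("s", "SM", np.array([(800.0049, 5000.0), (800.0051, 5000.0)]))
        got = match_peaks(pl, db, tolerance=5.0)
        assert len(got) == 1
        assert got[0].mz == pytest.approx(800.0049)

    def test_empty_peaklist_empty_result(self):
        db = LipidDatabase([_species("SM 40:1", 800.0)])
        pl = PeakList("s", "SM", np.empty((0, 2)))
        assert match_peaks(pl, db) == []

    def test_species_takes_most_intense_qualifying_peak(self):
        db = LipidDatabase([_species("SM 40:1", 800.0)])
        pl = PeakList("s", "SM", np.array([(799.998, 100.0), (800.002, 900.0)]))
        got = match_peaks(pl, db, tolerance=5.0)
        assert len(got) == 1 and got[0].intensity == 900.0

    def test_matches_brute_force_nearest_neighbour(self, rng):
        entries = np.sort(rng.uniform(700, 900, 10))
        db = LipidDatabase([_species(f"SM {30+i}:1", mz) for i, mz in enumerate(entries)])
        peaks = np.column_stack(
            [np.sort(rng.uniform(700, 900, 50)), rng.uniform(1, 1e5, 50)]
        )
        tol = 5.0
        got = {a.species.name: (a.mz, a.intensity) for a in match_peaks(PeakList("s", "SM", peaks), db, tol)}
        # exhaustive oracle: nearest entry per peak, most intense peak per entry
        best = {}
        for mz, inten in peaks:
            deltas = np.abs(entries - mz)
            j = int(np.argmin(deltas))
            if deltas[j] <= tol / 1000:
                name = f"SM {30+j}:1"
                if name not in best or inten > best[name][1]:
                    best[name] = (mz, inten)
        assert got == best

    def test_shift_invariance(self, rng):
        shift = 1.2345
        entries = np.sort(rng.uniform(700, 900, 5))
        peaks = np.column_stack([np.sort(rng.uniform(700, 900, 20)), rng.uniform(1, 1e4, 20)])
        db1 = LipidDatabase([_species(f"SM {30+i}:1", mz) for i, mz in enumerate(entries)])
        db2 = LipidDatabase([_species(f"SM {30+i}:1", mz + shift) for i, mz in enumerate(entries)])
        shifted = peaks.copy()
        shifted[:, 0] += shift
        a1 = match_peaks(PeakList("s", "SM", peaks), db1)
        a2 = match_peaks(PeakList("s", "SM", shifted), db2)
        assert [(a.species.name, a.intensity) for a in a1] == [
            (a.species.name, a.intensity) for a in a2
        ]


class TestIsotopeCorrect:
    def test_identity_for_heavy_isotope_free_formula(self):
        # phosphorus has a single stable isotope: P-only formula is inert
        sp = _species("SM 40:1", 800.0, formula={"P": 3})
        a = Assignment(800.0, 1000.0, sp, 0.0, 1000.0)
        (out,) = isotope_correct([a], LipidDatabase([sp]))
        assert out.corrected_intensity == pytest.approx(1000.0)

    def test_round_trip_against_generator_envelopes(self, small_db, is_table):
        from lipidscreen.containers import ConcentrationMatrix

        values = pd.DataFrame(
            {"Cer 34:2": [8.0], "Cer 34:1": [2.0]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        scfg = SpectrumConfig(include_isotopes=True, n_noise_peaks=0, mz_jitter_sd=0.2, seed=4)
        pls = generate_peaklists(ConcentrationMatrix(values), small_db, scfg)
        rec = quantify_peaklists(pls, small_db, is_table, min_intensity=0.0)
        assert rec.values.loc["s1", "Cer 34:2"] == pytest.approx(8.0, rel=0.01)
        assert rec.values.loc["s1", "Cer 34:1"] == pytest.approx(2.0, rel=0.01)

    def test_corrected_intensity_floored_at_zero(self, small_db):
        donor = small_db.get("Cer 34:2")
        recipient = small_db.get("Cer 34:1")
        assignments = [
            Assignment(donor.exact_mz, 1e9, donor, 0.0, 1e9),
            Assignment(recipient.exact_mz, 1.0, recipient, 0.0, 1.0),
        ]
        out = {a.species.name: a for a in isotope_correct(assignments, small_db)}
        assert out["Cer 34:1"].corrected_intensity == 0.0
        assert all(a.corrected_intensity >= 0 for a in out.values())

    def test_missing_formula_named(self):
        sp = LipidSpecies("SM 40:1", "SM", {}, "[M+H]+", 800.0)
        a = Assignment(800.0, 100.0, sp, 0.0, 100.0)
        with pytest.raises(ValueError, match="SM 40:1"):
            isotope_correct([a], LipidDatabase([sp]))


class TestQuantify:
    @pytest.mark.parametrize(
        "lipid_intensity,is_intensity,is_conc,expected",
        [(1000.0, 1000.0, 10.0, 10.0), (2500.0, 1000.0, 4.0, 10.0)],
    )
    def test_intensity_ratio_times_is_concentration(
        self, lipid_intensity, is_intensity, is_conc, expected
    ):
        lipid = _species("SM 40:1", 800.0)
        istd = _species("SM 30:1", 700.0, is_is=True)
        assignments = [
            Assignment(800.0, lipid_intensity, lipid, 0.0, lipid_intensity),
            Assignment(700.0, is_intensity, istd, 0.0, is_intensity),
        ]
        got = dict(quantify(assignments, {"SM": ("SM 30:1", is_conc)}))
        assert got["SM 40:1"] == pytest.approx(expected)

    def test_absent_is_reports_missing_not_zero(self):
        lipid = _species("SM 40:1", 800.0)
        assignments = [Assignment(800.0, 1000.0, lipid, 0.0, 1000.0)]
        got = dict(quantify(assignments, {"SM": ("SM 30:1", 10.0)}))
        assert np.isnan(got["SM 40:1"])

    def test_global_intensity_scale_invariance(self):
        lipid = _species("SM 40:1", 800.0)
        istd = _species("SM 30:1", 700.0, is_is=True)
        for scale in (1.0, 7.3):
            assignments = [
                Assignment(800.0, scale * 1500.0, lipid, 0.0, scale * 1500.0),
                Assignment(700.0, scale * 1000.0, istd, 0.0, scale * 1000.0),
            ]
            got = dict(quantify(assignments, {"SM": ("SM 30:1", 10.0)}))
            assert got["SM 40:1"] == pytest.approx(15.0)


class TestBuildMatrix:
    def test_disjoint_species_union_with_missing(self):
        m = build_matrix(
            {
                "a": [("SM 40:1", 1.0)],
                "b": [("PC 34:1", 2.0)],
                "c": [("Cer 40:1", 3.0)],
            }
        )
        assert m.shape == (3, 3)
        assert m.values.notna().sum().sum() == 3
        assert (m.provenance == "absent").sum().sum() == 6

    def test_permutation_invariance(self):
        results = {"a": [("X 30:1", 1.0)], "b": [("A 30:1", 2.0), ("X 30:1", 3.0)]}
        m1 = build_matrix(results)
        m2 = build_matrix(dict(reversed(results.items())))
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_single_sample(self):
        m = build_matrix({"only": [("SM 40:1", 5.0)]})
        assert m.shape == (1, 1)


class TestDatabaseCsv:
    def test_round_trip_preserves_species(self, small_db, tmp_path):
        from lipidscreen.lipids import LipidDatabase

        path = tmp_path / "db.csv"
        small_db.to_csv(path)
        back = LipidDatabase.from_csv(path)
        assert len(back) == len(small_db)
        for s in small_db:
            b = back.get(s.name)
            assert b.formula == s.formula
            assert b.exact_mz == pytest.approx(s.exact_mz, abs=1e-9)
            assert b.is_internal_standard == s.is_internal_standard


class TestEndToEndRoundTrip:
    def test_noise_free_recovery_within_5_percent(self, small_db, is_table, small_cohort):
        _, matrix, _ = small_cohort
        sub = matrix.subset_samples(matrix.sample_ids[:5])
        scfg = SpectrumConfig(include_isotopes=False, n_noise_peaks=0, mz_jitter_sd=0.5, seed=9)
        pls = generate_peaklists(sub, small_db, scfg)
        rec = quantify_peaklists(pls, small_db, is_table, min_intensity=0.0, isotope_correction=False)
        aligned = rec.values.reindex(index=sub.sample_ids, columns=sub.species)
        rel = np.abs(aligned / sub.values - 1.0)
        assert np.nanmax(rel.to_numpy()) < 0.05

    def test_isotopes_and_noise_recovery_within_15_percent(self, small_db, is_table, small_cohort):
        _, matrix, _ = small_cohort
        sub = matrix.subset_samples(matrix.sample_ids[:5])
        scfg = SpectrumConfig(include_isotopes=True, n_noise_peaks=5, mz_jitter_sd=1.0, seed=9)
        pls = generate_peaklists(sub, small_db, scfg)
        rec = quantify_peaklists(pls, small_db, is_table, min_intensity=3000.0)
        aligned = rec.values.reindex(index=sub.sample_ids, columns=sub.species)
        rel = np.abs(aligned / sub.values - 1.0)
        assert np.nanmax(rel.to_numpy()) < 0.15
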