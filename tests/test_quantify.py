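"""Peak-area quantification chain: correction, summation, profiles."""

import numpy as np
import pandas as pd
import pytest

from pollenomics.lipid_model import formula_of, icf, parse_species
from pollenomics.quantify import (
    correct_areas,
    modification_occurrence,
    saturation_profile,
    species_profile,
    subclass_abundance,
    sum_transitions,
    validate_peak_table,
)


def _peaks(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "subclass", "species", "transition_id", "area"]
    )


class TestCorrectAreas:
    def test_zero_area_stays_zero_and_factor_applied(self):
        peaks = _peaks(
            [
                ("S1", "PC", "PC 16:0_18:2", "T1", 0.0),
                ("S1", "PC", "PC 16:0_18:2", "T2", 100.0),
            ]
        )
        corrected, rejects = correct_areas(peaks)
        assert rejects.empty
        expected_icf = icf(formula_of(parse_species("PC 16:0_18:2")))
        assert corrected["corrected_area"].iloc[0] == 0.0
        assert corrected["corrected_area"].iloc[1] == pytest.approx(
            100.0 * expected_icf
        )

    def test_icf_is_sample_independent(self):
        peaks = _peaks(
            [
                ("S1", "PC", "PC 16:0_18:2", "T1", 10.0),
                ("S2", "PC", "PC 16:0_18:2", "T1", 99.0),
            ]
        )
        corrected, _ = correct_areas(peaks)
        assert corrected["icf"].nunique() == 1

    def test_unknown_species_reported_not_dropped_silently(self):
        peaks = _peaks(
            [
                ("S1", "PC", "PC 16:0_18:2", "T1", 10.0),
                ("S1", "ZZ", "ZZ 1:0", "T1", 5.0),
            ]
        )
        corrected, rejects = correct_areas(peaks)
        assert len(corrected) == 1
        assert len(rejects) == 1
        assert "error" in rejects.columns

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            validate_peak_table(_peaks([("S1", "PC", "PC 34:2", "T1", -1.0)]))

    def test_duplicate_key_rejected(self):
        peaks = _peaks(
            [
                ("S1", "PC", "PC 34:2", "T1", 1.0),
                ("S1", "PC", "PC 34:2", "T1", 2.0),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_peak_table(peaks)


class TestSumTransitions:
    def test_single_and_multiple_transitions(self):
        peaks = _peaks(
            [
                ("S1", "PC", "PC 34:2", "T1", 50.0),
                ("S1", "PC", "PC 34:1", "T1", 30.0),
                ("S1", "PC", "PC 34:1", "T2", 20.0),
            ]
        )
        out = sum_transitions(peaks)
        areas = out.set_index("species")["area"]
        assert areas["PC 34:2"] == 50.0
        assert areas["PC 34:1"] == 50.0

    def test_grand_total_preserved(self, rng):
        rows = [
            (f"S{s}", "PC", f"PC 34:{d}", f"T{t}", rng.uniform(0, 100))
            for s in range(3)
            for d in range(4)
            for t in range(1, 4)
        ]
        peaks = _peaks(rows)
        out = sum_transitions(peaks)
        assert out["area"].sum() == pytest.approx(peaks["area"].sum())
        # per-sample brute-force loop
        for s, grp in peaks.groupby("sample_id"):
            assert out.loc[out.sample_id == s, "area"].sum() == pytest.approx(
                grp["area"].sum()
            )


class TestSubclassAbundance:
    def _areas(self, totals):
        return pd.DataFrame(
            [
                {"sample_id": s, "subclass": "PC", "species": "PC 34:2", "area": a}
                for s, a in totals.items()
            ]
        )

    def _sheet(self, conds):
        return pd.DataFrame(
            {"sample_id": list(conds), "condition": list(conds.values())}
        )

    def test_identical_totals_normalize_to_one(self):
        areas = self._areas({"A": 100.0, "B": 100.0, "C": 100.0})
        sheet = self._sheet({"A": "RT3", "B": "RT3", "C": "HS3+3"})
        out = subclass_abundance(areas, sheet)
        assert np.allclose(out["normalized"], 1.0)

    def test_reference_mean_division(self):
        areas = self._areas({"A": 150.0, "B": 250.0, "C": 500.0})
        sheet = self._sheet({"A": "RT3", "B": "RT3", "C": "HS3+3"})
        out = subclass_abundance(areas, sheet).set_index("sample_id")
        assert out.loc["C", "normalized"] == pytest.approx(2.5)
        ref_mean = out.loc[["A", "B"], "normalized"].mean()
        assert ref_mean == pytest.approx(1.0)

    def test_zero_reference_flagged(self):
        areas = self._areas({"A": 0.0, "B": 10.0})
        sheet = self._sheet({"A": "RT3", "B": "HS3+3"})
        out = subclass_abundance(areas, sheet)
        assert out.attrs["flagged"] == ["PC"]
        assert out["normalized"].isna().all()

    def test_missing_reference_condition_rejected(self):
        areas = self._areas({"A": 1.0})
        sheet = self._sheet({"A": "HS3+3"})
        with pytest.raises(ValueError, match="reference"):
            subclass_abundance(areas, sheet)


class TestSpeciesProfile:
    def test_simple_percentages(self):
        areas = pd.DataFrame(
            [
                {"sample_id": "A", "subclass": "PC", "species": s, "area": a}
                for s, a in [("PC 34:2", 50.0), ("PC 34:1", 30.0), ("PC 34:0", 20.0)]
            ]
        )
        profile, major = species_profile(areas)
        got = profile.set_index("species")["mol_percent"]
        assert got["PC 34:2"] == 50.0
        assert got["PC 34:1"] == 30.0
        assert got["PC 34:0"] == 20.0

    def test_single_species_is_100_percent(self):
        areas = pd.DataFrame(
            [{"sample_id": "A", "subclass": "PC", "species": "PC 34:2", "area": 7.0}]
        )
        profile, _ = species_profile(areas)
        assert profile["mol_percent"].iloc[0] == 100.0

    def test_major_mask_boundary_is_strict(self):
        # one species at exactly 1.0%: excluded by the strict > rule
        areas = pd.DataFrame(
            [
                {"sample_id": "A", "subclass": "PC", "species": "PC 34:2", "area": 99.0},
                {"sample_id": "A", "subclass": "PC", "species": "PC 34:0", "area": 1.0},
            ]
        )
        _, major = species_profile(areas)
        mask = major.set_index("species")["is_major"]
        assert bool(mask["PC 34:2"]) is True
        assert bool(mask["PC 34:0"]) is False

    def test_zero_total_flagged(self):
        areas = pd.DataFrame(
            [{"sample_id": "A", "subclass": "PC", "species": "PC 34:2", "area": 0.0}]
        )
        profile, _ = species_profile(areas)
        assert profile["mol_percent"].isna().all()
        assert ("A", "PC") in profile.attrs["flagged"]


class TestSaturationProfile:
    def test_classification_and_fractions(self):
        areas = pd.DataFrame(
            [
                {"sample_id": "A", "subclass": "PC", "species": "PC 34:2", "area": 50.0},
                {"sample_id": "A", "subclass": "PC", "species": "PC 34:1", "area": 30.0},
                {"sample_id": "A", "subclass": "PC", "species": "PC 32:0", "area": 20.0},
            ]
        )
        out = saturation_profile(areas).iloc[0]
        assert out["polyunsaturated"] == pytest.approx(0.5)
        assert out["monounsaturated"] == pytest.approx(0.3)
        assert out["saturated"] == pytest.approx(0.2)

    def test_all_saturated(self):
        areas = pd.DataFrame(
            [
                {"sample_id": "A", "subclass": "PC", "species": "PC 32:0", "area": 5.0},
                {"sample_id": "A", "subclass": "PC", "species": "PC 34:0", "area": 5.0},
            ]
        )
        out = saturation_profile(areas).iloc[0]
        assert out["saturated"] == 1.0

    def test_matches_brute_force_regroup(self, rng):
        species = [f"PC 36:{d}" for d in range(5)]
        rows = [
            {"sample_id": f"S{s}", "subclass": "PC", "species": sp,
             "area": float(rng.uniform(0, 10))}
            for s in range(4)
            for sp in species
        ]
        areas = pd.DataFrame(rows)
        out = saturation_profile(areas).set_index("sample_id")
        for s, grp in areas.groupby("sample_id"):
            db = grp["species"].str.extract(r":(\d)$")[0].astype(int)
            total = grp["area"].sum()
            assert out.loc[s, "saturated"] == pytest.approx(
                grp.loc[db == 0, "area"].sum() / total
            )
            assert out.loc[s, "monounsaturated"] == pytest.approx(
                grp.loc[db == 1, "area"].sum() / total
            )
            assert out.loc[s, "polyunsaturated"] == pytest.approx(
                grp.loc[db >= 2, "area"].sum() / total
            )

    def test_sphingolipid_base_double_bond_not_counted(self):
        # 18:1;O2 base + 16:0 acyl: zero double bonds in the acyl residues
        areas = pd.DataFrame(
            [{"sample_id": "A", "subclass": "Cer",
              "species": "Cer 18:1;O2/16:0", "area": 3.0}]
        )
        out = saturation_profile(areas).iloc[0]
        assert out["saturated"] == 1.0


class TestModificationOccurrence:
    def _areas(self, species_areas, subclass="HexCer"):
        return pd.DataFrame(
            [
                {"sample_id": "A", "subclass": subclass, "species": s, "area": a}
                for s, a in species_areas.items()
            ]
        )

    def _get(self, result, feature):
        row = result.loc[result["feature"] == feature].iloc[0]
        return row["fraction"], row["unresolved_fraction"]

    def test_all_species_carry_feature(self):
        res = modification_occurrence(
            self._areas({"HexCer 18:1;O2(d4)/16:0": 10.0,
                         "HexCer 18:2;O2(d4,d8)/24:0": 5.0})
        )
        frac, _ = self._get(res, "d4_double_bond")
        assert frac == 1.0

    def test_abundance_weighted_split(self):
        res = modification_occurrence(
            self._areas({"HexCer 18:1;O2(d4)/16:0": 60.0,
                         "HexCer 18:0;O3(4OH)/16:0": 40.0})
        )
        assert self._get(res, "d4_double_bond")[0] == pytest.approx(0.6)
        assert self._get(res, "c4_hydroxyl")[0] == pytest.approx(0.4)

    def test_vlcfa_boundary_c20(self):
        res = modification_occurrence(
            self._areas({"HexCer 18:1;O2(d4)/20:0": 30.0,
                         "HexCer 18:1;O2(d4)/18:0": 70.0})
        )
        assert self._get(res, "vlcfa")[0] == pytest.approx(0.3)

    def test_unresolved_excluded_from_numerator(self):
        res = modification_occurrence(
            self._areas({"HexCer 18:1;O2(d4)/16:0": 50.0,
                         "HexCer 18:1;O2/16:0": 50.0})  # unannotated
        )
        frac, unresolved = self._get(res, "d4_double_bond")
        assert frac == pytest.approx(0.5)
        assert unresolved == pytest.approx(0.5)

    def test_count_weighting(self):
        res = modification_occurrence(
            self._areas({"HexCer 18:1;O2(d4)/16:0": 90.0,
                         "HexCer 18:0;O3(4OH)/16:0": 10.0}),
            weighting="count",
        )
        assert self._get(res, "d4_double_bond")[0] == pytest.approx(0.5)


class TestConservationAndEquivariance:
    def test_scale_equivariance(self, toy_peaks):
        corrected, _ = correct_areas(toy_peaks)
        areas = sum_transitions(corrected)
        scaled = toy_peaks.copy()
        scaled["area"] *= 3.7
        areas2 = sum_transitions(correct_areas(scaled)[0])
        p1, _ = species_profile(areas)
        p2, _ = species_profile(areas2)
        assert np.allclose(p1["mol_percent"], p2["mol_percent"])
        s1 = saturation_profile(areas)
        s2 = saturation_profile(areas2)
        cols = ["saturated", "monounsaturated", "polyunsaturated"]
        assert np.allclose(s1[cols], s2[cols])
        assert np.allclose(areas2["area"], areas["area"] * 3.7)

    def test_pipeline_on_toy_table_matches_hand_computation(
        self, toy_peaks, toy_sheet
    ):
        corrected, _ = correct_areas(toy_peaks)
        areas = sum_transitions(corrected)
        # species areas: raw species totals x species icf
        for sample in ("A", "B"):
            scale = 1.0 if sample == "A" else 2.0
            for name, raw in [("PC 16:0_16:0", 50.0), ("PC 16:0_18:1", 30.0),
                              ("PC 16:0_18:2", 20.0)]:
                expected = raw * scale * icf(formula_of(parse_species(name)))
                got = areas.loc[
                    (areas.sample_id == sample) & (areas.species == name), "area"
                ].iloc[0]
                assert got == pytest.approx(expected)
        ab = subclass_abundance(areas, toy_sheet).set_index("sample_id")
        assert ab.loc["B", "normalized"] == pytest.approx(2.0)
        profile, _ = species_profile(areas)
        sums = profile.groupby(["sample_id", "subclass"])["mol_percent"].sum()
        assert np.allclose(sums, 100.0, rtol=1e-9)
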