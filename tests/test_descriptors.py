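"""Elemental descriptors, one-hot encoding and combined features."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import nanoqstr as nq
from nanoqstr.descriptors import (
    DescriptorMatrix,
    ELEMENTAL_NAMES,
    active_metal,
    parse_doping,
    parse_formula,
)
from nanoqstr.errors import ElementLookupError, FormulaParseError, SchemaError


@pytest.fixture(scope="module")
def table():
    return nq.ElementTable.load()


class TestElementTable:
    def test_checksum_pins_shipped_table_version(self):
        # update this pin deliberately whenever the constants file changes
        assert nq.ElementTable.checksum() == EXPECTED_TABLE_SHA256

    def test_electron_count_equals_atomic_number(self, table):
        # neutral atoms: the descriptor uses Z as the electron count
        assert (table.frame["atomic_number"] > 0).all()
        assert (table.frame["vdw_radius_pm"] > 0).all()

    def test_unknown_element_raises_lookup_error(self, table):
        with pytest.raises(ElementLookupError):
            table.lookup("Xx")


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("ZnO", {"Zn": 1, "O": 1}),
            ("Fe3O4", {"Fe": 3, "O": 4}),
            ("SiO2", {"Si": 1, "O": 2}),
            ("Ag", {"Ag": 1}),
            ("Al2O3", {"Al": 2, "O": 3}),
        ],
    )
    def test_known_cores(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize("bad", ["", "3Zn", "Zn-O", "zno"])
    def test_bad_formula_raises(self, bad):
        with pytest.raises(FormulaParseError):
            parse_formula(bad)

    def test_doping_labels(self):
        assert parse_doping("ND") == (None, 0.0)
        assert parse_doping("Na (1.5%)") == ("Na", 1.5)
        assert parse_doping("Fe (4%)") == ("Fe", 4.0)


class TestElementalDescriptors:
    def test_zno_undoped(self, table):
        d = nq.elemental_descriptors("ZnO", "ND", table)
        assert d["n_metallic_elements"] == 1
        assert d["active_metal_electrons"] == 30  # Zn, Z = 30
        assert d["n_oxygen_atoms"] == 1
        assert d["doping_percent"] == 0.0

    def test_fe3o4(self, table):
        d = nq.elemental_descriptors("Fe3O4", "ND", table)
        assert d["active_metal_electrons"] == 26  # Fe
        assert d["n_oxygen_atoms"] == 4
        assert d["n_atoms"] == 7

    def test_sio2_with_na_doping_counts_one_metal(self, table):
        # Si is flagged semimetal in the table; Na is the only metal
        d = nq.elemental_descriptors("SiO2", "Na (1.5%)", table)
        assert d["n_metallic_elements"] == 1
        assert d["doping_percent"] == 1.5
        # active metal comes from the core only; SiO2 has none
        assert d["active_metal_electrons"] == 0

    def test_pure_function_of_inputs(self, table):
        a = nq.elemental_descriptors("ZnO", "Cl (3%)", table)
        b = nq.elemental_descriptors("ZnO", "Cl (3%)", table)
        assert a == b
        assert tuple(a) == ELEMENTAL_NAMES

    def test_active_metal_tie_breaks(self, table):
        # larger stoichiometric count wins; ties -> higher atomic number
        assert active_metal({"Fe": 3, "O": 4}, table) == "Fe"
        assert active_metal({"Cu": 1, "Zn": 1}, table) == "Zn"
        assert active_metal({"Na": 2, "Fe": 1}, table) == "Na"


class TestOneHot:
    def test_row_sums_are_one_per_categorical(self, modelling_dataset):
        m, enc = nq.one_hot_encode(modelling_dataset)
        for prefix in ("core_", "dop_", "coat_"):
            cols = [c for c in m.columns if c.startswith(prefix)]
            assert np.allclose(m.frame[cols].sum(axis=1), 1.0)

    def test_argmax_inverts_encoding(self, modelling_dataset):
        m, _ = nq.one_hot_encode(modelling_dataset)
        coat_cols = [c for c in m.columns if c.startswith("coat_")]
        decoded = m.frame[coat_cols].idxmax(axis=1).str.removeprefix("coat_")
        original = [r.coating for r in modelling_dataset]
        assert list(decoded) == original

    def test_doped_row_hits_its_level_column(self, table1_dataset):
        m, _ = nq.one_hot_encode(table1_dataset)
        row7 = m.frame.iloc[6]
        assert row7["dop_Na (1.5%)"] == 1.0
        assert row7["dop_ND"] == 0.0

    def test_unseen_level_errors_by_default(self, table1_dataset):
        _, enc = nq.one_hot_encode(table1_dataset)
        other = nq.ENMDataset(records=(
            nq.ENMRecord(enm_id="q", core="CuO", diameter=10,
                         concentration=1, viability=90),
        ))
        with pytest.raises(Exception):
            enc.transform(other)

    def test_unseen_level_zeros_policy(self, table1_dataset):
        _, enc = nq.one_hot_encode(table1_dataset, unseen="zeros")
        other = nq.ENMDataset(records=(
            nq.ENMRecord(enm_id="q", core="CuO", diameter=10,
                         concentration=1, viability=90),
        ))
        m = enc.transform(other)
        core_cols = [c for c in m.columns if c.startswith("core_")]
        assert m.frame[core_cols].to_numpy().sum() == 0.0

    def test_single_level_categorical_gives_constant_column(self, table1_dataset):
        m, _ = nq.one_hot_encode(table1_dataset, columns=("Surface_Coating",))
        assert m.columns == ["coat_NSC"]
        assert (m.frame["coat_NSC"] == 1.0).all()


class TestCombine:
    def _matrix(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        return DescriptorMatrix(frame=frame, provenance={"x": "raw", "y": "raw"})

    def test_product_values_and_name(self):
        out = nq.combine_descriptors(self._matrix(), operators=("product",))
        assert "x*y" in out.columns
        assert list(out.frame["x*y"]) == [3.0, 8.0]
        assert out.provenance["x*y"] == "combined"
        # parents retained
        assert {"x", "y"} <= set(out.columns)

    def test_product_is_order_insensitive(self):
        m = self._matrix()
        a = nq.combine_descriptors(m, whitelist=[("x", "y", "product")])
        b = nq.combine_descriptors(m, whitelist=[("y", "x", "product")])
        assert np.allclose(a.frame["x*y"], b.frame["y*x"])

    def test_full_product_set_has_p_choose_2_new_columns(self):
        frame = pd.DataFrame({f"c{i}": np.arange(3.0) + i for i in range(5)})
        m = DescriptorMatrix(frame=frame, provenance={c: "raw" for c in frame})
        out = nq.combine_descriptors(m, operators=("product",))
        assert len(out.columns) == 5 + 5 * 4 // 2

    def test_zero_denominator_ratio_skipped_with_warning(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "z": [0.0, 1.0]})
        m = DescriptorMatrix(frame=frame, provenance={"x": "raw", "z": "raw"})
        with pytest.warns(UserWarning, match="zero denominator"):
            out = nq.combine_descriptors(m, whitelist=[("x", "z", "ratio")])
        assert "x/z" not in out.columns

    def test_pmaa_product_skipped_when_no_pmaa_level(self, table1_dataset):
        # no PMAA level in the excerpt -> that combination is skipped
        # with a warning while the diameter ratio is still built
        with pytest.warns(UserWarning, match="parent column missing"):
            m, _ = nq.build_feature_matrix(table1_dataset)
        assert "Concentration_ug_mL*coat_PMAA" not in m.columns
        assert "Concentration_ug_mL/Diameter_nm" in m.columns

    def test_study_matrix_has_both_named_combinations(self, modelling_features):
        cols = modelling_features.columns
        assert "Concentration_ug_mL*coat_PMAA" in cols
        assert "Concentration_ug_mL/Diameter_nm" in cols
        # value check on one row: concentration * PMAA indicator
        f = modelling_features.frame
        manual = f["Concentration_ug_mL"] * f["coat_PMAA"]
        assert np.allclose(f["Concentration_ug_mL*coat_PMAA"], manual)


class TestSphereArea:
    def test_known_values(self):
        assert nq.sphere_surface_area(1.0) == pytest.approx(np.pi)
        assert nq.sphere_surface_area(2.0) == pytest.approx(4 * np.pi)

    def test_doubling_diameter_quadruples_area(self):
        assert nq.sphere_surface_area(10.0) == pytest.approx(4 * nq.sphere_surface_area(5.0))

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValueError):
            nq.sphere_surface_area(0.0)


class TestMatrixIO:
    def test_csv_round_trip_preserves_provenance(self, tmp_path, modelling_features):
        p = tmp_path / "m.csv"
        modelling_features.to_csv(p)
        back = DescriptorMatrix.from_csv(p)
        assert back.columns == modelling_features.columns
        assert back.provenance == modelling_features.provenance
        assert np.allclose(back.values, modelling_features.values)


# frozen pin of the shipped element constants (see TestElementTable)
EXPECTED_TABLE_SHA256 = "5303ca4836fbf213c93ca5af584c6ee1575dc3bfae64e3b77f867641b6f0b095"
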