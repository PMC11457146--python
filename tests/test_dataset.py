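"""Training-table IO, validation, Henry tables and the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from alkatherm.dataset import (
    PROPERTIES,
    HenryTable,
    PlantedModel,
    TrainingTable,
    generate_synthetic_table,
    read_henry_table,
    read_training_table,
    write_training_table,
)
from alkatherm.groups import count_groups
from alkatherm.molecule import MoleculeError


def tiny_frame():
    rows = []
    for iso in ("n-C4", "2-m-C3"):
        for T in (300.0, 400.0):
            rows.append((iso, T, "dHf", -100.0 - T * 0.01))
    return pd.DataFrame(rows, columns=["isomer", "T", "property", "value"])


class TestTrainingTableValidation:
    def test_basic_accessors(self):
        t = TrainingTable(tiny_frame())
        assert t.properties == ["dHf"]
        assert t.isomers() == ["2-m-C3", "n-C4"]
        assert t.temperatures("dHf").tolist() == [300.0, 400.0]
        assert t.value("n-C4", "dHf", 300.0) == -103.0
        assert t.molecule("2-m-C3").n_carbons == 4

    def test_unknown_isomer_name_raises(self):
        frame = tiny_frame()
        frame.loc[0, "isomer"] = "definitely-not-an-alkane"
        with pytest.raises(MoleculeError):
            TrainingTable(frame)

    def test_smiles_identifiers_accepted(self):
        frame = tiny_frame().replace({"n-C4": "CCCC"})
        t = TrainingTable(frame)
        assert t.molecule("CCCC").n_carbons == 4

    def test_unknown_property_raises(self):
        frame = tiny_frame().assign(property="enthalpy-ish")
        with pytest.raises(ValueError, match="unknown properties"):
            TrainingTable(frame)

    def test_inconsistent_temperature_grid_raises(self):
        frame = tiny_frame().drop(index=[1])  # n-C4 loses its 400 K row
        with pytest.raises(ValueError, match="temperature grids"):
            TrainingTable(frame)

    def test_duplicate_cells_raise(self):
        frame = pd.concat([tiny_frame(), tiny_frame().iloc[:1]])
        with pytest.raises(ValueError, match="duplicated"):
            TrainingTable(frame)

    def test_non_finite_values_raise(self):
        frame = tiny_frame()
        frame.loc[0, "value"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            TrainingTable(frame)

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            TrainingTable(pd.DataFrame({"isomer": ["n-C4"]}))


class TestFileIO:
    def test_csv_roundtrip_lossless_to_12_digits(self, tmp_path, synthetic_noiseless):
        table, _ = synthetic_noiseless
        path = tmp_path / "table.csv"
        write_training_table(table, path)
        again = read_training_table(path)
        merged = table.frame.merge(
            again.frame, on=["isomer", "T", "property"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(table.frame)
        np.testing.assert_allclose(
            merged["value_a"], merged["value_b"], rtol=1e-11, atol=0
        )

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("isomer,T,property,value\n")
        with pytest.raises(ValueError):
            read_training_table(path)

    def test_non_numeric_cells_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "isomer,T,property,value\nn-C4,300,dHf,-103\nn-C4,400,dHf,oops\n"
        )
        with pytest.raises(ValueError):
            read_training_table(path)

    def test_xlsx_workbook_roundtrip(self, tmp_path):
        t = TrainingTable(tiny_frame())
        path = tmp_path / "scott.xlsx"
        with pd.ExcelWriter(path) as writer:
            wide = t.frame.pivot(index="isomer", columns="T", values="value")
            wide.reset_index().to_excel(writer, sheet_name="dHf", index=False)
        again = read_training_table(path)
        assert again.value("2-m-C3", "dHf", 400.0) == t.value("2-m-C3", "dHf", 400.0)
        assert again.isomers() == t.isomers()

    def test_xlsx_schema_map_renames_worksheets(self, tmp_path):
        t = TrainingTable(tiny_frame())
        path = tmp_path / "scott.xlsx"
        with pd.ExcelWriter(path) as writer:
            wide = t.frame.pivot(index="isomer", columns="T", values="value")
            wide.reset_index().to_excel(writer, sheet_name="DHf0", index=False)
        with pytest.raises(ValueError, match="no worksheet"):
            read_training_table(path)
        again = read_training_table(path, schema={"DHf0": "dHf"})
        assert again.properties == ["dHf"]

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_training_table(tmp_path / "t.parquet", format="parquet")


class TestHenryTable:
    def test_lookup(self):
        frame = pd.DataFrame(
            {
                "isomer": ["n-C10", "4-m-C9"],
                "zeolite": ["MTW", "MTW"],
                "T": [500.0, 500.0],
                "KH": [1e-6, 3e-6],
            }
        )
        table = HenryTable(frame)
        coeffs = table.coefficients("MTW", 500.0)
        assert coeffs["4-m-C9"] == 3e-6
        with pytest.raises(KeyError):
            table.coefficients("MFI", 500.0)

    def test_nonpositive_rejected(self):
        frame = pd.DataFrame(
            {"isomer": ["a"], "zeolite": ["MTW"], "T": [500.0], "KH": [0.0]}
        )
        with pytest.raises(ValueError):
            HenryTable(frame)

    def test_read_csv(self, tmp_path):
        path = tmp_path / "henry.csv"
        path.write_text("isomer,zeolite,T,KH\nn-C4,MTW,500,1e-6\n")
        assert read_henry_table(path).coefficients("MTW", 500.0)["n-C4"] == 1e-6


class TestSyntheticGenerator:
    def test_values_are_exactly_group_additive(self, synthetic_noiseless):
        table, planted = synthetic_noiseless
        for _, row in table.frame.sample(50, random_state=0).iterrows():
            counts = count_groups(table.molecule(row["isomer"]), "second")
            expected = planted.value(counts, row["property"], row["T"])
            assert row["value"] == pytest.approx(expected, abs=1e-12)

    def test_equal_coefficients_give_linear_in_carbon_count(self):
        keys = None
        # build a planted model with alpha_k = 2.5 for every key, alpha0 = 0
        table0, planted0 = generate_synthetic_table(seed=1, n_max=6)
        coeffs = {
            p: {k: (2.5, 0.0, 0.0) for k in planted0.keys}
            for p in planted0.properties
        }
        planted = PlantedModel(planted0.properties, planted0.keys, coeffs)
        table, _ = generate_synthetic_table(seed=1, n_max=6, planted=planted)
        for _, row in table.frame.iterrows():
            n = table.molecule(row["isomer"]).n_carbons
            assert row["value"] == pytest.approx(2.5 * n, abs=1e-12)

    def test_noise_degrades_recovery_monotonically(self):
        """Prediction error against the planted truth grows with sigma."""
        from alkatherm.regression import fit_property

        errors = {}
        for sigma in (0.05, 0.8):
            residuals = []
            for seed in range(5):
                table, planted = generate_synthetic_table(
                    seed=seed, n_max=6, temperatures=(400.0,), sigma=sigma,
                    properties=("dHf",),
                )
                model = fit_property(table, "dHf")
                for iso in table.isomers("dHf"):
                    counts = count_groups(table.molecule(iso), "second")
                    truth = planted.value(counts, "dHf", 400.0)
                    residuals.append(abs(model.evaluate(counts, 400.0) - truth))
            errors[sigma] = np.mean(residuals)
        assert errors[0.05] < errors[0.8]

    def test_seed_reproducibility(self):
        a, _ = generate_synthetic_table(seed=42, n_max=5, sigma=0.2)
        b, _ = generate_synthetic_table(seed=42, n_max=5, sigma=0.2)
        pd.testing.assert_frame_equal(a.frame, b.frame)
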