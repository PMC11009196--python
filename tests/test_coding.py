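import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frailtykit import (CodingRule, DataDictionary, code_binary, code_matrix,
                        code_normalized, code_ordinal, code_value)
from frailtykit.errors import DictionaryError, SchemaError

BINARY = CodingRule("Albumin", "blood", "blood chemistry", "binary_range",
                    normal_range=(35.0, 50.0))
ORDINAL = CodingRule("grade", "examination", "cardiac", "ordinal",
                     cut_points=(10.0, 20.0), levels=(0.0, 0.5, 1.0))
HIGHER = CodingRule("gait", "examination", "physical performance",
                    "normalized", reference_min=2.0, reference_max=12.0,
                    direction="higher_is_deficit")
LOWER = CodingRule("grip", "examination", "physical performance",
                   "normalized", reference_min=10.0, reference_max=60.0,
                   direction="lower_is_deficit")


class TestScalarCoders:
    @pytest.mark.parametrize("value,expected", [
        (40.0, 0.0), (35.0, 0.0), (50.0, 0.0),  # bounds inclusive
        (55.0, 1.0), (30.0, 1.0),
    ])
    def test_binary_normal_range(self, value, expected):
        assert code_binary(value, BINARY) == expected

    @pytest.mark.parametrize("value,expected", [
        (5.0, 0.0), (15.0, 0.5), (25.0, 1.0),
        (10.0, 0.5), (20.0, 1.0),  # boundary belongs to the higher level
    ])
    def test_ordinal_levels(self, value, expected):
        assert code_ordinal(value, ORDINAL) == expected

    def test_ordinal_boundary_convention_by_exhaustive_scan(self):
        # oracle: explicit interval membership with left-closed intervals
        for value in np.arange(0.0, 30.5, 0.5):
            if value < 10.0:
                expected = 0.0
            elif value < 20.0:
                expected = 0.5
            else:
                expected = 1.0
            assert code_ordinal(float(value), ORDINAL) == expected

    @pytest.mark.parametrize("value,rule,expected", [
        (2.0, HIGHER, 0.0), (12.0, HIGHER, 1.0), (7.0, HIGHER, 0.5),
        (35.0, LOWER, 0.5), (10.0, LOWER, 1.0), (60.0, LOWER, 0.0),
        (-5.0, HIGHER, 0.0), (99.0, HIGHER, 1.0),  # clamped
    ])
    def test_normalized(self, value, rule, expected):
        assert code_normalized(value, rule) == pytest.approx(expected)

    @pytest.mark.parametrize("coder,rule", [
        (code_binary, BINARY), (code_ordinal, ORDINAL),
        (code_normalized, HIGHER),
    ])
    def test_missing_propagates(self, coder, rule):
        assert np.isnan(coder(np.nan, rule))
        assert np.isnan(coder(None, rule))

    def test_kind_mismatch_is_dictionary_error(self):
        with pytest.raises(DictionaryError):
            code_binary(1.0, ORDINAL)
        with pytest.raises(DictionaryError):
            code_ordinal(1.0, HIGHER)
        with pytest.raises(DictionaryError):
            code_normalized(1.0, BINARY)


@st.composite
def rules(draw):
    kind = draw(st.sampled_from(["binary_range", "ordinal", "normalized"]))
    lo = draw(st.floats(-100, 100))
    width = draw(st.floats(0.5, 100))
    if kind == "binary_range":
        return CodingRule("x", "blood", "blood chemistry", kind,
                          normal_range=(lo, lo + width))
    if kind == "normalized":
        direction = draw(st.sampled_from(["higher_is_deficit",
                                          "lower_is_deficit"]))
        return CodingRule("x", "examination", "cardiac", kind,
                          reference_min=lo, reference_max=lo + width,
                          direction=direction)
    n_cuts = draw(st.integers(1, 4))
    cuts = tuple(lo + width * (i + 1) / (n_cuts + 1) for i in range(n_cuts))
    levels = tuple(np.linspace(0, 1, n_cuts + 1))
    return CodingRule("x", "examination", "cardiac", kind,
                      cut_points=cuts, levels=levels)


class TestCodingProperties:
    @settings(derandomize=True, max_examples=200)
    @given(rule=rules(), value=st.floats(-1e4, 1e4))
    def test_coded_values_in_unit_interval(self, rule, value):
        out = code_value(value, rule)
        assert 0.0 <= out <= 1.0

    @settings(derandomize=True, max_examples=100)
    @given(rule=rules(), a=st.floats(-1e4, 1e4), b=st.floats(-1e4, 1e4))
    def test_monotone_in_direction(self, rule, a, b):
        lo, hi = sorted((a, b))
        va, vb = code_value(lo, rule), code_value(hi, rule)
        if rule.kind == "normalized":
            if rule.direction == "higher_is_deficit":
                assert va <= vb
            else:
                assert va >= vb
        elif rule.kind == "ordinal":
            assert va <= vb


class TestCodeMatrix:
    def test_hand_computed_toy_table(self):
        table = pd.DataFrame(
            {"Albumin": [40.0, 55.0], "gait": [7.0, np.nan]},
            index=["P1", "P2"],
        )
        d = DataDictionary([BINARY, HIGHER])
        out = code_matrix(table, d)
        assert out.loc["P1", "Albumin"] == 0.0
        assert out.loc["P2", "Albumin"] == 1.0
        assert out.loc["P1", "gait"] == pytest.approx(0.5)
        assert np.isnan(out.loc["P2", "gait"])

    def test_matrix_equals_scalar_composition(self):
        rng = np.random.default_rng(42)
        d = DataDictionary([BINARY, ORDINAL, HIGHER, LOWER])
        raw = rng.uniform(-50, 100, size=(20, 4))
        raw[rng.random((20, 4)) < 0.3] = np.nan
        table = pd.DataFrame(raw, columns=d.item_names)
        out = code_matrix(table, d)
        for rule in d:
            for i in range(20):
                expect = code_value(table.iloc[i, table.columns.get_loc(rule.item_name)], rule)
                got = out.iloc[i, out.columns.get_loc(rule.item_name)]
                assert (np.isnan(expect) and np.isnan(got)) or expect == got

    def test_missingness_conserved_on_default_dictionary(
            self, default_cohort, default_matrix, dictionary):
        raw = default_cohort[dictionary.item_names]
        assert (default_matrix.isna() == raw.isna()).all().all()
        vals = default_matrix.to_numpy()
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 1)).all()
        assert default_matrix.shape[1] == 70

    def test_all_missing_column(self):
        table = pd.DataFrame({"Albumin": [np.nan, np.nan]})
        out = code_matrix(table, DataDictionary([BINARY]))
        assert out["Albumin"].isna().all()

    def test_absent_column_names_item(self):
        with pytest.raises(SchemaError, match="Albumin"):
            code_matrix(pd.DataFrame({"other": [1.0]}),
                        DataDictionary([BINARY]))

    def test_non_numeric_treated_as_missing_with_warning(self):
        table = pd.DataFrame({"Albumin": [40.0, "not a number"]})
        with pytest.warns(UserWarning, match="non-numeric"):
            out = code_matrix(table, DataDictionary([BINARY]))
        assert out["Albumin"].iloc[0] == 0.0
        assert np.isnan(out["Albumin"].iloc[1])
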