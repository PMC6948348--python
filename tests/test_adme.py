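"""ADME screening: Tanimoto drug-likeness and the OB/DL filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.adme import (
    CompoundRecord,
    ReferenceProfile,
    ScreenCriteria,
    apply_screen,
    assign_dl,
    read_compound_table,
    shared_compounds,
    tanimoto_dl,
    write_compound_table,
)


def tanimoto_scalar(a, b):
    """Independent scalar-by-scalar evaluation of the drug-likeness formula."""
    dot = sum(x * y for x, y in zip(a, b))
    return dot / (sum(x * x for x in a) + sum(y * y for y in b) - dot)


def make(mol_id, ob, dl, herbs=("SMK",), name=None):
    return CompoundRecord(mol_id, name or mol_id.lower(), frozenset(herbs), ob, dl)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((3.0, 1.0, 2.0), (3.0, 1.0, 2.0), 1.0),  # identical vectors
            ((1.0, 0.0), (0.0, 2.0), 0.0),  # orthogonal
            ((1.0, 1.0), (2.0, 2.0), 4.0 / 6.0),  # hand evaluation: 4/(2+8-4)
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert tanimoto_dl(a, b) == pytest.approx(expected, abs=1e-15)
        assert tanimoto_dl(a, b) == pytest.approx(tanimoto_scalar(a, b), abs=1e-12)

    def test_dimension_mismatch_and_degenerate_inputs(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto_dl((1.0, 2.0), (1.0,))
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto_dl((0.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError, match="length"):
            tanimoto_dl((), ())

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=1, max_size=12),
        st.data(),
    )
    def test_bounds_and_symmetry_on_nonnegative_vectors(self, a, data):
        b = data.draw(
            st.lists(st.floats(0.0, 100.0), min_size=len(a), max_size=len(a))
        )
        if not (any(a) or any(b)):
            a = a[:-1] + [1.0]
        t = tanimoto_dl(a, b)
        assert 0.0 <= t <= 1.0
        assert t == pytest.approx(tanimoto_dl(b, a), abs=1e-12)
        assert t == pytest.approx(tanimoto_scalar(a, b), abs=1e-9)


class TestScreen:
    # OB/DL values of two named screen survivors, plus the threshold boundary.
    @pytest.mark.parametrize(
        "ob, dl, retained",
        [
            (36.91, 0.75, True),   # beta-sitosterol
            (45.09, 0.21, True),   # apigenin
            (25.0, 0.18, True),    # exact boundary is inclusive
            (24.99, 0.99, False),  # OB below threshold
            (99.0, 0.179, False),  # DL below threshold
        ],
    )
    def test_default_standard(self, ob, dl, retained):
        recs = [make("MOL001", ob, dl)]
        assert (apply_screen(recs) == recs) is retained

    def test_exclusive_mode_rejects_the_boundary(self):
        rec = make("MOL001", 25.0, 0.18)
        assert apply_screen([rec], ScreenCriteria(inclusive=False)) == []

    def test_order_preserved_input_unmodified_idempotent(self):
        lib = [make(f"MOL{i:03d}", 30.0 - i, 0.5) for i in range(10)]
        before = list(lib)
        out = apply_screen(lib)
        assert lib == before
        assert out == [r for r in lib if r.ob_percent >= 25.0]
        assert apply_screen(out) == out

    def test_missing_dl_is_an_error_naming_the_compound(self):
        with pytest.raises(ValueError, match="MOL077"):
            apply_screen([make("MOL001", 30, 0.5), make("MOL077", 30, None)])

    @given(st.floats(0, 60), st.floats(0, 1))
    def test_raising_thresholds_never_retains_more(self, ob_min, dl_min):
        lib = [
            make(f"MOL{i:03d}", float(ob), float(dl))
            for i, (ob, dl) in enumerate(
                zip(np.linspace(0, 60, 25), np.linspace(0, 1, 25))
            )
        ]
        base = len(apply_screen(lib))
        tighter = ScreenCriteria(ob_min=max(25.0, ob_min), dl_min=max(0.18, dl_min))
        assert len(apply_screen(lib, tighter)) <= base

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            ScreenCriteria(ob_min=-1)
        with pytest.raises(ValueError):
            ScreenCriteria(dl_min=1.5)


class TestSharedCompounds:
    def test_fixture_yields_the_six_multi_herb_compounds(self, fixture_compounds):
        screened = apply_screen(fixture_compounds)
        assert len(screened) == 37
        shared = shared_compounds(screened)
        assert [c.name for c in shared] == [
            "beta-sitosterol", "apigenin", "luteolin",
            "kaempferol", "ursolic acid", "sitogluside_qt",
        ]

    def test_single_herb_library_has_no_shared_compounds(self):
        lib = [make(f"MOL{i:03d}", 30, 0.5, herbs=(h,)) for i, h in enumerate("ABC")]
        assert shared_compounds(lib) == []

    def test_min_herbs_one_is_vacuous_and_zero_is_an_error(self, fixture_compounds):
        assert shared_compounds(fixture_compounds, min_herbs=1) == sorted(
            fixture_compounds, key=lambda r: r.mol_id
        )
        with pytest.raises(ValueError):
            shared_compounds(fixture_compounds, min_herbs=0)


class TestRecordsAndIO:
    def test_qt_suffix_sets_the_aglycone_flag_only(self):
        rec = make("MOL101", 30, 0.5, name="sitogluside_qt")
        assert rec.is_deglycosylated
        assert rec.name.endswith("_qt")  # suffix retained
        assert not make("MOL001", 30, 0.5, name="apigenin").is_deglycosylated

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            CompoundRecord("MOL001", "x", frozenset(), 30, 0.5)
        with pytest.raises(ValueError):
            make("MOL001", -1, 0.5)
        with pytest.raises(ValueError):
            make("MOL001", 30, 1.5)

    def test_supplied_dl_wins_over_descriptors(self, caplog):
        ref = ReferenceProfile((1.0, 1.0))
        rec = CompoundRecord(
            "MOL001", "x", frozenset(["SMK"]), 30, dl=0.4, descriptors=(2.0, 2.0)
        )
        with caplog.at_level("WARNING"):
            out = assign_dl([rec], ref)
        assert out[0].dl == 0.4
        assert "MOL001" in caplog.text

    def test_dl_computed_from_descriptors_when_unset(self):
        ref = ReferenceProfile((2.0, 2.0))
        rec = CompoundRecord(
            "MOL001", "x", frozenset(["SMK"]), 30, dl=None, descriptors=(1.0, 1.0)
        )
        assert assign_dl([rec], ref)[0].dl == pytest.approx(4.0 / 6.0)

    def test_table_round_trip_merges_herb_rows(self, tmp_path, fixture_compounds):
        path = tmp_path / "compounds.tsv"
        write_compound_table(fixture_compounds, path)
        back = read_compound_table(path)
        assert {r.mol_id: r.herb_sources for r in back} == {
            r.mol_id: r.herb_sources for r in fixture_compounds
        }
        assert {r.mol_id: r.dl for r in back} == {
            r.mol_id: r.dl for r in fixture_compounds
        }
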