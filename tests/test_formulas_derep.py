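"""Formula parsing, monoisotopic masses, adduct arithmetic, annotation search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as ptmass

from actinomet.derep import (
    M_MINUS_H,
    M_PLUS_H,
    Adduct,
    adduct_mz,
    annotate,
    hits_frame,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from actinomet.exceptions import ConfigurationError, FormulaError
from actinomet.tabio import CompoundLibrary, CompoundRecord

from conftest import make_feature_table


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C24H32N6O4S2", {"C": 24, "H": 32, "N": 6, "O": 4, "S": 2}),
            ("H", {"H": 1}),
            ("C13H11ClO3", {"C": 13, "H": 11, "Cl": 1, "O": 3}),
            ("CH3CH3", {"C": 2, "H": 6}),  # repeated symbols accumulate
        ],
    )
    def test_parses(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["C0H2", "", "  ", "C24Xx2", "C24h32", "12C"])
    def test_rejects(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected_4dp",
        [
            ("C24H32N6O4S2", 532.1926),
            ("C17H24N2O", 272.1889),
            ("C", 12.0000),
        ],
    )
    def test_reference_masses(self, formula, expected_4dp):
        assert round(monoisotopic_mass(parse_formula(formula)), 4) == expected_4dp

    @pytest.mark.parametrize("formula", ["C16H33N3O9", "C30H40N2O7", "C13H11ClO3"])
    def test_agrees_with_independent_calculator(self, formula):
        ours = monoisotopic_mass(parse_formula(formula))
        theirs = ptmass.calculate_mass(formula=formula)
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_empty_counts_forbidden(self):
        with pytest.raises(FormulaError):
            monoisotopic_mass({})

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.dictionaries(st.sampled_from(["C", "H", "N"]),
                          st.integers(1, 50), min_size=1),
        b=st.dictionaries(st.sampled_from(["O", "S", "Cl"]),
                          st.integers(1, 50), min_size=1),
    )
    def test_additive_over_disjoint_counts(self, a, b):
        merged = {**a, **b}
        assert monoisotopic_mass(merged) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )


class TestAdducts:
    def test_protonated_reference_ions(self):
        mb = monoisotopic_mass(parse_formula("C24H32N6O4S2"))
        assert round(adduct_mz(mb, M_PLUS_H), 4) == 533.1999
        mt = monoisotopic_mass(parse_formula("C17H24N2O"))
        assert round(adduct_mz(mt, M_PLUS_H), 4) == 273.1961

    def test_deprotonation_is_symmetric(self):
        m = 400.123456
        assert adduct_mz(m, M_MINUS_H) == pytest.approx(m - 1.007276)
        assert adduct_mz(m, M_PLUS_H) + adduct_mz(m, M_MINUS_H) == pytest.approx(2 * m)

    def test_charge_zero_rejected(self):
        with pytest.raises(FormulaError):
            Adduct("bad", 1.0, 0)


class TestPpmError:
    def test_zero_for_exact_match(self):
        assert ppm_error(533.1999, 533.1999) == 0.0

    def test_signed_example(self):
        # theoretical [M+H]+ of C17H14O4 is 283.0965
        theo = adduct_mz(monoisotopic_mass(parse_formula("C17H14O4")), M_PLUS_H)
        assert round(theo, 4) == 283.0965
        # direct arithmetic: (283.0961 - 283.096485) / 283.096485 * 1e6
        assert ppm_error(283.0961, theo) == pytest.approx(-1.36, abs=0.05)

    @settings(deadline=None, max_examples=50)
    @given(delta=st.floats(0, 0.01), bigger=st.floats(1e-6, 0.01))
    def test_monotone_in_absolute_deviation(self, delta, bigger):
        theo = 500.0
        assert abs(ppm_error(theo + delta, theo)) <= abs(
            ppm_error(theo + delta + bigger, theo)
        )


def _random_instance(rng, n_features=50, n_compounds=30):
    formulas = []
    for _ in range(n_compounds):
        c = int(rng.integers(5, 40))
        h = int(rng.integers(4, 2 * c))
        o = int(rng.integers(0, 9))
        formulas.append(f"C{c}H{h}" + (f"O{o}" if o else ""))
    lib = CompoundLibrary(
        [CompoundRecord(name=f"cpd{i}", formula=f) for i, f in enumerate(formulas)]
    )
    # half the features sit close to a random compound, half anywhere
    mz = []
    for i in range(n_features):
        if i % 2 == 0:
            rec = lib[int(rng.integers(0, n_compounds))]
            base = adduct_mz(rec.neutral_mass, M_PLUS_H)
            mz.append(base * (1 + rng.uniform(-30, 30) * 1e-6))
        else:
            mz.append(rng.uniform(100, 1400))
    mz = np.clip(mz, 100.0, 1500.0)
    ft = make_feature_table(
        {"S1": list(rng.uniform(1e3, 1e6, n_features))},
        roles={"S1": "g1"},
        mz=mz,
        mode="positive",
        prefix="P_",
    )
    return ft, lib


def _brute_force(ft, lib, tolerance):
    """Independent exhaustive search over features x compounds x adducts."""
    found = set()
    for fid in ft.feature_ids:
        obs = float(ft.mz.loc[fid])
        for rec in lib:
            neutral = ptmass.calculate_mass(formula=rec.formula)
            theo = neutral + 1.007276  # positive mode, [M+H]+
            err = (obs - theo) / theo * 1e6
            if abs(err) <= tolerance:
                found.add((fid, rec.name, "[M+H]+"))
    return found


class TestAnnotate:
    @pytest.mark.parametrize("tolerance", [0.0, 1.0, 5.0, 20.0])
    def test_matches_brute_force_oracle(self, tolerance):
        rng = np.random.default_rng(42)
        for _ in range(3):
            ft, lib = _random_instance(rng)
            ours = {(h.feature_id, h.compound, h.adduct)
                    for h in annotate(ft, lib, tolerance=tolerance)}
            assert ours == _brute_force(ft, lib, tolerance)

    def test_tightening_tolerance_never_adds_hits(self):
        rng = np.random.default_rng(7)
        ft, lib = _random_instance(rng)
        previous = None
        for tol in (20.0, 5.0, 1.0, 0.0):
            hits = {(h.feature_id, h.compound) for h in annotate(ft, lib, tolerance=tol)}
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_reference_feature_hits_and_decoy_misses(self):
        lib_real = CompoundLibrary(
            [CompoundRecord(name="Aerucyclamide B", formula="C24H32N6O4S2")]
        )
        lib_decoy = CompoundLibrary([CompoundRecord(name="far", formula="C10H10")])
        ft = make_feature_table(
            {"S1": [1e5]}, roles={"S1": "g1"}, mz=[533.1999],
            mode="positive", prefix="P_",
        )
        hits = annotate(ft, lib_real, tolerance=5.0)
        assert len(hits) == 1 and abs(hits[0].ppm) < 5
        assert annotate(ft, lib_decoy, tolerance=5.0) == []

    def test_zero_tolerance_requires_exact_equality(self):
        rec = CompoundRecord(name="x", formula="C20H20O4")
        lib = CompoundLibrary([rec])
        exact = adduct_mz(rec.neutral_mass, M_PLUS_H)
        ft = make_feature_table(
            {"S1": [1.0, 1.0]}, roles={"S1": "g1"},
            mz=[exact, exact * (1 + 1e-7)], mode="positive", prefix="P_",
        )
        hits = annotate(ft, lib, tolerance=0.0)
        assert [h.feature_id for h in hits] == ["P_1"]

    def test_ties_broken_by_library_order(self):
        # identical formulas -> identical |ppm|; library order decides
        recs = [CompoundRecord(name=n, formula="C17H14O4") for n in ("zeta", "alpha")]
        lib = CompoundLibrary(recs)
        mz = adduct_mz(recs[0].neutral_mass, M_PLUS_H)
        ft = make_feature_table({"S1": [1.0]}, roles={"S1": "g1"}, mz=[mz],
                                mode="positive", prefix="P_")
        hits = annotate(ft, lib, tolerance=5.0)
        assert [h.compound for h in hits] == ["zeta", "alpha"]

    def test_empty_library_rejected(self):
        ft = make_feature_table({"S1": [1.0]}, roles={"S1": "g1"}, mz=[300.0],
                                mode="positive", prefix="P_")
        with pytest.raises(ConfigurationError):
            annotate(ft, CompoundLibrary([]))

    def test_no_hit_features_reported(self):
        lib = CompoundLibrary([CompoundRecord(name="x", formula="C30H40N2O7")])
        ft = make_feature_table({"S1": [1.0]}, roles={"S1": "g1"}, mz=[200.0],
                                mode="positive", prefix="P_")
        frame = hits_frame(annotate(ft, lib), ft)
        assert frame.loc[frame["feature_id"] == "P_1", "compound"].item() == "no hits"
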