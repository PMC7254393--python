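"""Formula arithmetic: masses, plausibility rules, decomposition,
derivatization, isotope patterns and Kovats indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from hrgcms.chem import (
    ELECTRON_MASS,
    AlkaneLadder,
    DecompositionConstraints,
    Formula,
    decompose_mass,
    derivatize,
    is_subformula,
    isotope_pattern,
    kovats_ri,
    monoisotopic_mass,
    ppm_window,
    rdbe,
    senior_check,
)

from conftest import brute_force_decompose


# ---------------------------------------------------------------------------
# masses


def test_empty_formula_mass_is_zero():
    assert monoisotopic_mass(Formula(), 0) == 0.0


@pytest.mark.parametrize(
    "text, charge, expected, tol",
    [
        ("H2O", 0, 18.010565, 1e-5),
        ("C3H9Si", +1, 73.04680, 1e-4),  # 3*12 + 9*1.00782503 + 27.97692653 - m_e
        ("C6H12O6", 0, 180.06339, 1e-4),
    ],
)
def test_monoisotopic_mass_reference_values(text, charge, expected, tol):
    assert monoisotopic_mass(Formula.from_string(text), charge) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("text", ["C6H12O6", "C22H55NO6Si5", "C5H9NO4", "H3PO4", "C5H11NO2S"])
def test_neutral_mass_matches_pyteomics(text):
    """Independent oracle: pyteomics' NIST-based mass calculator."""
    ours = monoisotopic_mass(Formula.from_string(text))
    theirs = pyteomics_mass.calculate_mass(formula=text)
    assert ours == pytest.approx(theirs, abs=5e-5)


def test_unsupported_element_is_named():
    with pytest.raises(ValueError, match="Fe"):
        Formula.from_string("FeO")


def test_charge_beyond_one_rejected():
    with pytest.raises(ValueError):
        monoisotopic_mass(Formula.from_string("CH4"), 2)


# ---------------------------------------------------------------------------
# ppm windows


def test_ppm_window_examples():
    lo, hi = ppm_window(300.0, 3.0)
    assert (lo, hi) == pytest.approx((299.9991, 300.0009), abs=1e-7)
    m = 123.456
    assert ppm_window(m, 0.0) == (m, m)
    lo, hi = ppm_window(73.04680, 3.0)
    assert hi - lo == pytest.approx(2 * 3e-6 * 73.04680, abs=1e-6)


# ---------------------------------------------------------------------------
# RDBE / SENIOR


@pytest.mark.parametrize(
    "text, expected",
    [("CH4", 0.0), ("C6H6", 4.0), ("C3H9Si", 0.5), ("C6H12O6", 1.0)],
)
def test_rdbe(text, expected):
    assert rdbe(Formula.from_string(text)) == expected


@pytest.mark.parametrize(
    "text, ok", [("H2O", True), ("CH3", False), ("C6H12O6", True)]
)
def test_senior_condition(text, ok):
    assert senior_check(Formula.from_string(text)) is ok


# ---------------------------------------------------------------------------
# decomposition


def test_decompose_tms_fragment_rank_one():
    cons = DecompositionConstraints(
        element_ranges={"C": (0, 10), "H": (0, 20), "Si": (0, 2)}
    )
    cands = decompose_mass(73.04680, cons, as_fragment_ion=True)
    assert cands and cands[0].formula == Formula.from_string("C3H9Si")
    assert abs(cands[0].error_ppm) <= 3.0


def test_decompose_neutral_contains_glucose():
    cons = DecompositionConstraints(
        element_ranges={"C": (0, 15), "H": (0, 30), "O": (0, 10)}
    )
    cands = decompose_mass(180.06339, cons)
    assert Formula.from_string("C6H12O6") in {c.formula for c in cands}


def test_decompose_tight_tolerance_unique_cho_candidate():
    cons = DecompositionConstraints(
        tolerance_ppm=0.1, element_ranges={"C": (0, 15), "H": (0, 30), "O": (0, 10)}
    )
    cands = decompose_mass(180.06339, cons)
    assert [c.formula for c in cands] == [Formula.from_string("C6H12O6")]


def test_decompose_candidates_respect_tolerance():
    cons = DecompositionConstraints(element_ranges={"C": (0, 20), "H": (0, 40), "O": (0, 8)})
    for c in decompose_mass(250.12, cons):
        assert abs(c.error_ppm) <= cons.tolerance_ppm


def test_decompose_huge_lattice_rejected_with_estimate():
    cons = DecompositionConstraints(
        element_ranges={el: (0, 200) for el in ("C", "H", "N", "O", "P", "S", "Si")}
    )
    with pytest.raises(ValueError, match="lattice"):
        decompose_mass(500.0, cons)


def test_decompose_matches_brute_force_enumeration():
    """The pruned lattice search returns exactly the brute-force hit set
    on randomized (mass, constraints) draws."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        cons = DecompositionConstraints(
            tolerance_ppm=float(rng.uniform(1.0, 10.0)),
            element_ranges={
                "C": (0, int(rng.integers(3, 15))),
                "H": (0, int(rng.integers(5, 30))),
                "N": (0, int(rng.integers(0, 4))),
                "O": (0, int(rng.integers(0, 8))),
                "Si": (0, int(rng.integers(0, 3))),
            },
        )
        as_frag = bool(rng.random() < 0.5)
        mass = float(rng.uniform(50.0, 400.0))
        ours = {c.formula for c in decompose_mass(mass, cons, as_fragment_ion=as_frag)}
        assert ours == brute_force_decompose(mass, cons, as_fragment_ion=as_frag)


def test_known_formula_recovered_at_its_own_mass():
    f = Formula.from_string("C8H21NO2Si2")  # 2-TMS glycine
    cons = DecompositionConstraints(
        tolerance_ppm=1.0,
        element_ranges={el: (0, n + 2) for el, n in f.items()},
    )
    cands = decompose_mass(monoisotopic_mass(f), cons)
    assert cands[0].formula == f
    assert abs(cands[0].error_ppm) < 1e-6


# ---------------------------------------------------------------------------
# subformula partial order

formulas = st.builds(
    Formula,
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "Si"]), st.integers(0, 12), max_size=5
    ),
)


@settings(max_examples=100, derandomize=True)
@given(formulas, formulas, formulas)
def test_is_subformula_is_a_partial_order(a, b, c):
    assert is_subformula(a, a)
    if is_subformula(a, b) and is_subformula(b, a):
        assert a == b
    if is_subformula(a, b) and is_subformula(b, c):
        assert is_subformula(a, c)


def test_subformula_examples():
    glc = Formula.from_string("C6H12O6")
    assert is_subformula(Formula.from_string("C2H5O"), glc)
    assert not is_subformula(Formula.from_string("C7H5"), glc)


# ---------------------------------------------------------------------------
# derivatization


def test_derivatize_glucose_5tms_1meox():
    out = derivatize(Formula.from_string("C6H12O6"), 5, 1)
    assert out == Formula.from_string("C22H55NO6Si5")


def test_derivatize_glycine_2tms():
    out = derivatize(Formula.from_string("C2H5NO2"), 2, 0)
    assert out == Formula.from_string("C8H21NO2Si2")


def test_derivatize_identity_and_meox_guard():
    f = Formula.from_string("C5H9NO2")
    assert derivatize(f, 0, 0) == f
    with pytest.raises(ValueError):
        derivatize(Formula.from_string("C4H12N2"), 1, 1)  # no O to oximate


@settings(max_examples=50, derandomize=True)
@given(
    st.dictionaries(st.sampled_from(["C", "H", "N", "O"]), st.integers(1, 10), min_size=1),
    st.integers(0, 6),
    st.integers(0, 1),
)
def test_derivatized_mass_is_exactly_additive(counts, n_tms, n_meox):
    f = Formula(counts)
    if n_meox > f["O"]:
        n_meox = 0
    tms = monoisotopic_mass(Formula.from_string("C3H8Si"))
    meox = monoisotopic_mass(Formula.from_string("CH3N"))
    assert monoisotopic_mass(derivatize(f, n_tms, n_meox)) == pytest.approx(
        monoisotopic_mass(f) + n_tms * tms + n_meox * meox, abs=1e-12
    )


# ---------------------------------------------------------------------------
# isotope patterns


def test_isotope_pattern_carbon():
    pat = dict(isotope_pattern(Formula(C=1), 2))
    assert pat[1] == pytest.approx(0.0108, abs=5e-4)  # 13C/12C


def test_isotope_pattern_silicon():
    pat = dict(isotope_pattern(Formula(Si=1), 3))
    assert pat[1] == pytest.approx(0.0508, abs=1e-3)
    assert pat[2] == pytest.approx(0.0335, abs=1e-3)


def test_isotope_pattern_water_m1_tiny():
    pat = dict(isotope_pattern(Formula.from_string("H2O"), 2))
    assert pat[1] < 0.001


# ---------------------------------------------------------------------------
# Kovats indices


@pytest.fixture
def ladder():
    return AlkaneLadder.from_pairs([(7, 4.0), (10, 10.0), (11, 12.0), (40, 60.0)])


def test_kovats_node_and_midpoint(ladder):
    assert kovats_ri(10.0, ladder) == pytest.approx(1000.0)
    assert kovats_ri(11.0, ladder) == pytest.approx(1050.0)


def test_kovats_rejects_extrapolation(ladder):
    with pytest.raises(ValueError):
        kovats_ri(3.0, ladder)


def test_kovats_strictly_increasing(ladder):
    rts = np.linspace(4.0, 60.0, 80)
    ris = [kovats_ri(rt, ladder) for rt in rts]
    assert all(b > a for a, b in zip(ris, ris[1:]))


def test_invalid_ladder_rejected():
    with pytest.raises(ValueError):
        AlkaneLadder.from_pairs([(10, 5.0), (9, 6.0)])
    with pytest.raises(ValueError):
        AlkaneLadder.from_pairs([(9, 6.0), (10, 5.0)])
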