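"""Elemental-formula arithmetic for derivatized-metabolite GC-MS annotation.

This module is the numerical foundation of the annotation workflow: exact
monoisotopic masses over the {C, H, N, O, P, S, Si} alphabet, ppm mass
windows, rings-plus-double-bond equivalents (RDBE), the SENIOR graph
condition, golden-rules element-ratio plausibility ranges, exhaustive
constrained formula decomposition of an accurate mass, trimethylsilyl /
methoxime derivatization increments, nominal-mass isotope patterns, and
Kovats retention indices on an n-alkane ladder.

Atomic masses and isotope abundances are shipped as a human-readable table
(``data/isotopes.tsv``) so that results are bit-stable across environments.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ISOTOPES",
    "VALENCE",
    "Formula",
    "FormulaCandidate",
    "DecompositionConstraints",
    "AlkaneLadder",
    "monoisotopic_mass",
    "ppm_window",
    "rdbe",
    "senior_check",
    "element_ratio_check",
    "decompose_mass",
    "is_subformula",
    "derivatize",
    "isotope_pattern",
    "kovats_ri",
]

#: CODATA electron mass in Da; included in all ion masses (charge-aware
#: arithmetic), since 0.55 mDa is near the 3 ppm tolerance edge below m/z 200.
ELECTRON_MASS = 0.000548579909

#: Fixed valence per element for RDBE and SENIOR; one valence per element
#: (N 3, P 3, S 2) — multivalent states are not enumerated.
VALENCE = {"C": 4, "Si": 4, "N": 3, "P": 3, "O": 2, "S": 2, "H": 1}

#: Canonical element order for deterministic output (Hill-like: C, H, then
#: alphabetical).
ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S", "Si")


def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = resources.files("hrgcms.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        el, mass_number, mass, abundance = line.split("\t")
        table.setdefault(el, []).append((int(mass_number), float(mass), float(abundance)))
    for el in table:
        table[el].sort()
    return table


#: element -> list of (mass_number, mass, abundance), sorted by mass number.
ISOTOPES = _load_isotope_table()

#: element -> mass of the most abundant isotope.
MONOISOTOPIC_MASS = {
    el: max(rows, key=lambda r: r[2])[1] for el, rows in ISOTOPES.items()
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping):
    """Immutable element -> count map over the supported alphabet.

    Counts are non-negative integers; an absent element is count 0; zero
    counts are dropped so two formulas are equal iff all counts are equal.
    """

    __slots__ = ("_counts", "_key")

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for el, n in source.items():
                if el not in MONOISOTOPIC_MASS:
                    raise ValueError(f"unsupported element symbol: {el!r}")
                if not float(n).is_integer() or n < 0:
                    raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
                merged[el] = merged.get(el, 0) + int(n)
        self._counts = {el: n for el, n in merged.items() if n > 0}
        self._key = tuple(sorted(self._counts.items()))

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a plain formula string such as ``'C22H55NO6Si5'``."""
        counts: dict[str, int] = {}
        pos = 0
        text = text.strip()
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None or m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, digits = m.groups()
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element symbol: {el!r}")
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el: object) -> bool:
        return el in self._counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    # Arithmetic --------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def minus(self, other: "Formula") -> "Formula | None":
        """Elementwise difference, or None if any count would go negative."""
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                return None
        return Formula(counts)

    # Descriptors -------------------------------------------------------
    @property
    def atom_count(self) -> int:
        return sum(self._counts.values())

    @property
    def is_empty(self) -> bool:
        return not self._counts

    def mass(self, charge: int = 0) -> float:
        return monoisotopic_mass(self, charge)

    def nominal_mass(self) -> int:
        """Integer mass using the most abundant isotope's mass number."""
        nominal = {el: max(rows, key=lambda r: r[2])[0] for el, rows in ISOTOPES.items()}
        return sum(n * nominal[el] for el, n in self._counts.items())

    def hill(self) -> str:
        parts = []
        for el in ELEMENT_ORDER:
            n = self._counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    def __str__(self) -> str:
        return self.hill()


#: Net composition increments of the two derivatization reactions.
TMS_INCREMENT = Formula(C=3, H=8, Si=1)   # active H -> O/N-Si(CH3)3
MEOX_INCREMENT = Formula(C=1, H=3, N=1)   # carbonyl O -> C=N-OCH3 (O retained)


def monoisotopic_mass(formula: Formula, charge: int = 0) -> float:
    """Monoisotopic mass in Da; for ions the electron mass is subtracted
    per positive charge (added per negative charge)."""
    if abs(charge) > 1:
        raise ValueError(f"|charge| must be <= 1, got {charge}")
    m = sum(n * MONOISOTOPIC_MASS[el] for el, n in formula.items())
    return m - charge * ELECTRON_MASS


def ppm_window(mass: float, tol_ppm: float) -> tuple[float, float]:
    """Closed mass interval [lo, hi] spanning ±tol_ppm around ``mass``."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be non-negative")
    delta = mass * tol_ppm * 1e-6
    return (mass - delta, mass + delta)


def rdbe(formula: Formula) -> float:
    """Rings-plus-double-bond equivalents, 1 + sum n_i (v_i - 2) / 2.

    Half-integer values flag radical/ion compositions.
    """
    return 1.0 + sum(n * (VALENCE[el] - 2) for el, n in formula.items()) / 2.0


def senior_check(formula: Formula) -> bool:
    """SENIOR necessary condition for a neutral molecule to exist: the
    valence sum is even and at least 2 x (atom count - 1)."""
    if formula.is_empty:
        raise ValueError("senior_check requires a non-empty formula")
    vsum = sum(n * VALENCE[el] for el, n in formula.items())
    return vsum % 2 == 0 and vsum >= 2 * (formula.atom_count - 1)


#: Golden-rules 99.7%-coverage element-ratio ranges; ratios are taken
#: against carbon with Si counted as carbon.
GOLDEN_RATIO_RANGES: dict[str, tuple[float, float]] = {
    "H": (0.2, 3.1),
    "N": (0.0, 1.3),
    "O": (0.0, 1.2),
    "P": (0.0, 0.3),
    "S": (0.0, 0.8),
}


def element_ratio_check(
    formula: Formula,
    ratio_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> bool:
    """Element-ratio plausibility ranges (golden rules, 99.7% coverage).

    Si is treated as carbon for ratio purposes; formulas without a carbon
    skeleton (C + Si = 0) pass vacuously.
    """
    ranges = GOLDEN_RATIO_RANGES if ratio_ranges is None else ratio_ranges
    c_eff = formula["C"] + formula["Si"]
    if c_eff == 0:
        return True
    for el, (lo, hi) in ranges.items():
        ratio = formula[el] / c_eff
        if not (lo <= ratio <= hi):
            return False
    return True


_DEFAULT_ELEMENT_RANGES: dict[str, tuple[int, int]] = {
    "C": (0, 39),
    "H": (0, 72),
    "N": (0, 8),
    "O": (0, 20),
    "P": (0, 3),
    "S": (0, 4),
    "Si": (0, 8),
}

_MAX_LATTICE = 10**8


@dataclass
class DecompositionConstraints:
    """Search constraints for formula decomposition of an accurate mass."""

    tolerance_ppm: float = 3.0
    element_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_ELEMENT_RANGES)
    )
    rdbe_range: tuple[float, float] = (-0.5, 40.0)
    allow_half_integer_rdbe: bool = False
    senior: bool = True
    ratio_check: bool = True
    ratio_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GOLDEN_RATIO_RANGES)
    )

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        for el, (lo, hi) in self.element_ranges.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element symbol: {el!r}")
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid range for {el}: ({lo}, {hi})")
        if self.rdbe_range[0] > self.rdbe_range[1]:
            raise ValueError("invalid rdbe_range")

    def lattice_size(self) -> int:
        size = 1
        for lo, hi in self.element_ranges.values():
            size *= hi - lo + 1
        return size


@dataclass(frozen=True)
class FormulaCandidate:
    """One decomposition result: composition, theoretical mass (ion m/z for
    fragment-ion searches, neutral mass otherwise), signed ppm error, RDBE."""

    formula: Formula
    theoretical_mass: float
    error_ppm: float
    rdbe: float


def _candidate_passes(
    f: Formula, r: float, constraints: DecompositionConstraints, as_fragment_ion: bool
) -> bool:
    lo, hi = constraints.rdbe_range
    if not (lo <= r <= hi):
        return False
    if not (constraints.allow_half_integer_rdbe or as_fragment_ion):
        if (2.0 * r) % 2 != 0:
            return False
    if constraints.senior and not as_fragment_ion and not senior_check(f):
        return False
    if constraints.ratio_check and not element_ratio_check(f, constraints.ratio_ranges):
        return False
    return True


def decompose_mass(
    mass: float,
    constraints: DecompositionConstraints | None = None,
    as_fragment_ion: bool = False,
) -> list[FormulaCandidate]:
    """Exhaustively decompose an accurate mass into elemental formulas.

    The constrained element-count lattice is searched depth-first with
    suffix mass bounds, which prunes it to the thin shell around the target
    mass. For fragment-ion searches (``as_fragment_ion``) the target
    neutral-composition mass is ``mass + m_e`` (singly charged cation), the
    SENIOR check is skipped, and half-integer RDBE is allowed — EI fragments
    are radical/even-electron ions, not molecules.

    Results are sorted by \\|ppm error\\| ascending, ties broken by lower
    RDBE then lexicographic element counts. An empty list is a valid
    outcome.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    cons = constraints if constraints is not None else DecompositionConstraints()
    size = cons.lattice_size()
    if size > _MAX_LATTICE:
        raise ValueError(
            f"element ranges span ~{size:.2e} lattice points (> {_MAX_LATTICE:.0e}); "
            "narrow the ranges"
        )
    tol_da = mass * cons.tolerance_ppm * 1e-6
    target = mass + ELECTRON_MASS if as_fragment_ion else mass

    # Heaviest elements first: the residual mass window then pins the H count.
    elements = sorted(
        (el for el, (lo, hi) in cons.element_ranges.items() if hi > 0 or lo > 0),
        key=lambda el: -MONOISOTOPIC_MASS[el],
    )
    ranges = [cons.element_ranges[el] for el in elements]
    masses = [MONOISOTOPIC_MASS[el] for el in elements]
    n_el = len(elements)
    # suffix_min/max[i]: attainable mass from elements i.. end
    suffix_min = [0.0] * (n_el + 1)
    suffix_max = [0.0] * (n_el + 1)
    for i in range(n_el - 1, -1, -1):
        lo, hi = ranges[i]
        suffix_min[i] = suffix_min[i + 1] + lo * masses[i]
        suffix_max[i] = suffix_max[i + 1] + hi * masses[i]

    out: list[FormulaCandidate] = []
    counts = [0] * n_el

    def recurse(i: int, remaining: float) -> None:
        if i == n_el:
            if abs(remaining) <= tol_da:
                f = Formula({el: c for el, c in zip(elements, counts) if c > 0})
                if f.is_empty:
                    return
                r = rdbe(f)
                if _candidate_passes(f, r, cons, as_fragment_ion):
                    neutral_sum = target - remaining
                    theo = neutral_sum - ELECTRON_MASS if as_fragment_ion else neutral_sum
                    out.append(
                        FormulaCandidate(f, theo, (theo - mass) / mass * 1e6, r)
                    )
            return
        lo, hi = ranges[i]
        m = masses[i]
        for n in range(lo, hi + 1):
            rem = remaining - n * m
            if rem + tol_da < suffix_min[i + 1]:
                break  # already over target; larger n only worse
            if rem - tol_da > suffix_max[i + 1]:
                continue  # cannot reach target yet
            counts[i] = n
            recurse(i + 1, rem)
        counts[i] = 0

    recurse(0, target)

    def sort_key(c: FormulaCandidate):
        return (
            abs(c.error_ppm),
            c.rdbe,
            tuple(c.formula[el] for el in ELEMENT_ORDER),
        )

    out.sort(key=sort_key)
    return out


def is_subformula(part: Formula, whole: Formula) -> bool:
    """True iff every element count of ``part`` is <= that of ``whole``."""
    return all(n <= whole[el] for el, n in part.items())


def derivatize(formula: Formula, n_tms: int = 0, n_meox: int = 0) -> Formula:
    """Apply TMS/MeOX derivatization increments to a neutral formula.

    Each trimethylsilyl group replaces an active hydrogen, net +C3H8Si;
    each methoxime converts a carbonyl, net +CH3N (the carbonyl O is
    retained in the methoxime). The O count is used as a proxy for carbonyl
    availability since structures are unknown at the formula level.
    """
    if n_tms < 0 or n_meox < 0:
        raise ValueError("derivative counts must be non-negative")
    if n_meox > formula["O"]:
        raise ValueError(
            f"{n_meox} MeOX groups requested but formula has only {formula['O']} O"
        )
    return formula + n_tms * TMS_INCREMENT + n_meox * MEOX_INCREMENT


def isotope_pattern(formula: Formula, n_peaks: int = 3) -> list[tuple[int, float]]:
    """Aggregated nominal-mass isotopologue pattern, base peak = 1.

    Returns ``[(0, 1.0), (1, M+1/M), (2, M+2/M), ...]`` computed by
    convolving each element's isotope-abundance vector (indexed by nominal
    offset from the most abundant isotope) ``count`` times.
    """
    if formula.is_empty:
        raise ValueError("isotope_pattern requires a non-empty formula")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    length = n_peaks  # keep offsets 0 .. n_peaks-1; truncate as we go
    vec = np.zeros(length)
    vec[0] = 1.0
    for el, count in formula.items():
        rows = ISOTOPES[el]
        base_number = max(rows, key=lambda r: r[2])[0]
        max_off = max(mn - base_number for mn, _, _ in rows)
        elvec = np.zeros(max(max_off + 1, 1))
        for mn, _, ab in rows:
            off = mn - base_number
            if off >= 0:
                elvec[off] += ab
        for _ in range(count):
            vec = np.convolve(vec, elvec)[:length]
    if vec[0] <= 0:
        raise ValueError("degenerate isotope pattern")
    vec = vec / vec[0]
    return [(k, float(vec[k]) if k < len(vec) else 0.0) for k in range(n_peaks)]


@dataclass(frozen=True)
class AlkaneLadder:
    """n-Alkane retention ladder: ordered (carbon number, retention time)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        carbons = [c for c, _ in self.entries]
        rts = [t for _, t in self.entries]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")

    @classmethod
    def from_pairs(cls, pairs) -> "AlkaneLadder":
        return cls(tuple((int(c), float(t)) for c, t in pairs))

    @property
    def rt_span(self) -> tuple[float, float]:
        return (self.entries[0][1], self.entries[-1][1])


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index under the temperature-programmed linear
    convention: RI = 100 (n + (rt - rt_n)/(rt_{n+1} - rt_n)) between the
    bracketing ladder alkanes. No extrapolation outside the ladder span."""
    lo, hi = ladder.rt_span
    if not (lo <= rt <= hi):
        raise ValueError(f"rt {rt} outside alkane ladder span [{lo}, {hi}]")
    rts = [t for _, t in ladder.entries]
    i = bisect_right(rts, rt) - 1
    if i == len(ladder.entries) - 1:  # exactly the last node
        return 100.0 * ladder.entries[-1][0]
    (c0, t0), (c1, t1) = ladder.entries[i], ladder.entries[i + 1]
    return 100.0 * (c0 + (c1 - c0) * (rt - t0) / (t1 - t0))
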