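"""High-resolution filtering of library annotations.

A proposed annotation (the derivatized sum formula of a library hit) is
confirmed or falsified by decomposing the accurate masses of the most
intense and highest-m/z fragment ions and testing whether each admits an
elemental composition that is the whole or a subset of the proposal. A
single unexplained fragment falsifies the proposal; the operation is
rejected outright on unit-resolution spectra, where it is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (
    DecompositionConstraints,
    Formula,
    FormulaCandidate,
    decompose_mass,
    is_subformula,
)
from .spectra import Spectrum

__all__ = [
    "FragmentAnnotation",
    "HRFilterVerdict",
    "select_fragments",
    "annotate_fragment",
    "hr_filter_verdict",
]


@dataclass
class FragmentAnnotation:
    """Candidate sub-formulas (if any) explaining one accurate fragment m/z."""

    mz: float
    intensity: float
    candidates: list[FormulaCandidate] = field(default_factory=list)

    @property
    def explained(self) -> bool:
        return bool(self.candidates)


@dataclass
class HRFilterVerdict:
    """Outcome of high-resolution filtering for one proposal."""

    proposal: Formula
    fragments: list[FragmentAnnotation]
    verdict: str  # "confirmed" | "falsified" | "inconclusive"

    @property
    def n_checked(self) -> int:
        return len(self.fragments)

    @property
    def n_explained(self) -> int:
        return sum(f.explained for f in self.fragments)


def select_fragments(
    spectrum: Spectrum, n_intense: int = 5, n_highmz: int = 3
) -> list[tuple[float, float]]:
    """Union of the ``n_intense`` most intense and ``n_highmz`` highest-m/z
    peaks, as (mz, intensity) sorted by m/z. Intensity ties break toward
    the higher m/z."""
    if spectrum.n_peaks == 0:
        raise ValueError("cannot select fragments from an empty spectrum")
    order_int = np.lexsort((spectrum.mz, spectrum.intensity))[::-1]  # intensity desc, mz desc on tie
    chosen = set(order_int[: max(n_intense, 0)].tolist())
    order_mz = np.argsort(spectrum.mz)[::-1]
    chosen |= set(order_mz[: max(n_highmz, 0)].tolist())
    idx = sorted(chosen, key=lambda i: spectrum.mz[i])
    return [(float(spectrum.mz[i]), float(spectrum.intensity[i])) for i in idx]


def fragment_constraints(proposal: Formula, tol_ppm: float = 3.0) -> DecompositionConstraints:
    """Decomposition constraints for fragment ions of a given proposal:
    element ranges capped elementwise by the proposal, no SENIOR/ratio
    checks (fragments are radical or even-electron ions, not molecules)."""
    return DecompositionConstraints(
        tolerance_ppm=tol_ppm,
        element_ranges={el: (0, n) for el, n in proposal.items()},
        rdbe_range=(-0.5, 40.0),
        allow_half_integer_rdbe=True,
        senior=False,
        ratio_check=False,
    )


def annotate_fragment(
    mz: float,
    proposal: Formula,
    tol_ppm: float = 3.0,
    intensity: float = 0.0,
) -> FragmentAnnotation:
    """Decompose one fragment m/z within the proposal's element budget.

    Hydrogen (and every other element) is capped at the proposal's count:
    EI rearrangements shuffle internal hydrogens but cannot exceed the
    molecular formula, so candidate compositions are strict subformulas.
    """
    if proposal.is_empty:
        raise ValueError("proposal formula must be non-empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    candidates = decompose_mass(mz, fragment_constraints(proposal, tol_ppm), as_fragment_ion=True)
    candidates = [c for c in candidates if is_subformula(c.formula, proposal)]
    return FragmentAnnotation(mz=mz, intensity=intensity, candidates=candidates)


def hr_filter_verdict(
    spectrum: Spectrum,
    proposal: Formula,
    tol_ppm: float = 3.0,
    min_fragments: int = 3,
    n_intense: int = 5,
    n_highmz: int = 3,
) -> HRFilterVerdict:
    """Confirm, falsify, or abstain on a proposed annotation.

    confirmed: every selected fragment is explained and at least
    ``min_fragments`` were checked. falsified: at least one selected
    fragment admits no sub-formula of the proposal within tolerance.
    inconclusive: fewer than ``min_fragments`` checkable and none failed.
    """
    if spectrum.resolution != "accurate":
        raise ValueError(
            "high-resolution filtering requires an accurate-mass spectrum; "
            "unit-resolution spectra carry no verifiable sum-formula information"
        )
    selected = select_fragments(spectrum, n_intense=n_intense, n_highmz=n_highmz)
    fragments = [annotate_fragment(mz, proposal, tol_ppm, intensity=i) for mz, i in selected]
    if any(not f.explained for f in fragments):
        verdict = "falsified"
    elif len(fragments) >= min_fragments:
        verdict = "confirmed"
    else:
        verdict = "inconclusive"
    return HRFilterVerdict(proposal=proposal, fragments=fragments, verdict=verdict)
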