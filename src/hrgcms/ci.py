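"""Molecular-ion detection in methane chemical-ionization (CI) spectra.

Methane CI of a neutral M produces the co-occurring series [M-CH3]+,
[M+H]+, [M+C2H5]+ and [M+C3H5]+, whose fixed spacings (CH4, C2H4, C)
identify the neutral mass. The detector hypothesizes an M for every peak
in every series role, scores how many series members are present within a
ppm tolerance, and merges duplicate hypotheses. Detected molecular ions
are then linked back to EI compounds by retention-index agreement and
shared fragment m/z values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    DecompositionConstraints,
    FormulaCandidate,
    decompose_mass,
)
from .spectra import Spectrum

__all__ = [
    "ADDUCT_SERIES",
    "AdductSeriesHit",
    "EICILink",
    "adduct_offsets",
    "detect_adduct_series",
    "link_ci_to_ei",
]

_MC = MONOISOTOPIC_MASS["C"]
_MH = MONOISOTOPIC_MASS["H"]

#: Ion m/z offset from the neutral mass M for each series member.
ADDUCT_SERIES: dict[str, float] = {
    "[M-CH3]+": -(_MC + 3 * _MH) - ELECTRON_MASS,
    "[M+H]+": _MH - ELECTRON_MASS,
    "[M+C2H5]+": (2 * _MC + 5 * _MH) - ELECTRON_MASS,
    "[M+C3H5]+": (3 * _MC + 5 * _MH) - ELECTRON_MASS,
}


def adduct_offsets() -> dict[str, float]:
    """The four methane-CI series offsets (Da from neutral M, electron
    mass included). Consecutive spacings are exactly CH4, C2H4 and C."""
    return dict(ADDUCT_SERIES)


@dataclass
class AdductSeriesHit:
    """A neutral-mass hypothesis supported by >= min_support series members."""

    neutral_mass: float
    members: dict[str, tuple[float, float]]  # role -> (observed mz, ppm error)
    total_intensity: float = 0.0

    @property
    def support(self) -> int:
        return len(self.members)


def detect_adduct_series(
    ci_spectrum: Spectrum,
    tol_ppm: float = 3.0,
    min_support: int = 3,
) -> list[AdductSeriesHit]:
    """Find neutral masses supported by the methane-CI adduct series.

    Every peak is tried in every series role; the implied M is then tested
    against all four offsets. Hypotheses with at least ``min_support``
    members survive; near-duplicate M values (within the same ppm
    tolerance) are merged, keeping the better-supported one. Results are
    sorted by support, then summed member intensity, descending.
    """
    if ci_spectrum.mode != "CI":
        raise ValueError("detect_adduct_series expects a CI spectrum")
    if ci_spectrum.resolution != "accurate":
        raise ValueError("adduct-series detection requires accurate masses")
    if not 2 <= min_support <= 4:
        raise ValueError("min_support must be in 2..4")
    mz = ci_spectrum.mz
    intensity = ci_spectrum.intensity
    if mz.size == 0:
        return []

    hits: list[AdductSeriesHit] = []
    for peak_mz in mz:
        for role, offset in ADDUCT_SERIES.items():
            m_hyp = float(peak_mz) - offset
            if m_hyp <= 0:
                continue
            members: dict[str, tuple[float, float]] = {}
            total = 0.0
            for role2, offset2 in ADDUCT_SERIES.items():
                expected = m_hyp + offset2
                tol_da = expected * tol_ppm * 1e-6
                j = int(np.argmin(np.abs(mz - expected)))
                err_da = float(mz[j] - expected)
                if abs(err_da) <= tol_da:
                    members[role2] = (float(mz[j]), err_da / expected * 1e6)
                    total += float(intensity[j])
            if len(members) >= min_support:
                hits.append(AdductSeriesHit(m_hyp, members, total))

    # Merge duplicate hypotheses (M within tolerance).
    hits.sort(key=lambda h: h.neutral_mass)
    merged: list[AdductSeriesHit] = []
    for h in hits:
        if merged and abs(h.neutral_mass - merged[-1].neutral_mass) <= (
            merged[-1].neutral_mass * tol_ppm * 1e-6
        ):
            best = merged[-1]
            if (h.support, h.total_intensity) > (best.support, best.total_intensity):
                merged[-1] = h
        else:
            merged.append(h)
    merged.sort(key=lambda h: (-h.support, -h.total_intensity, h.neutral_mass))
    return merged


@dataclass
class EICILink:
    """A CI molecular-ion hypothesis assigned to an EI compound."""

    ei_id: str
    ci_id: str
    neutral_mass: float
    ri_difference: float
    shared_fragments: int
    formula_candidates: list[FormulaCandidate] = field(default_factory=list)


def link_ci_to_ei(
    ei_compounds: list[Spectrum],
    ci_hits: list[tuple[AdductSeriesHit, Spectrum]],
    ri_tol: float = 5.0,
    frag_tol_ppm: float = 3.0,
    min_shared: int = 2,
    decompose_constraints: DecompositionConstraints | None = None,
    max_candidates: int = 5,
) -> list[EICILink]:
    """Assign each EI compound its best CI molecular-ion hypothesis.

    Candidates must agree in retention index (|dRI| <= ri_tol) and share
    at least ``min_shared`` fragment m/z values within ``frag_tol_ppm``;
    the best link has the greatest shared count, then the smallest |dRI|.
    When ``decompose_constraints`` is given, the recovered neutral mass is
    decomposed into ranked molecular-formula candidates.
    """
    links: list[EICILink] = []
    for ei in ei_compounds:
        if ei.retention_index is None:
            raise ValueError(f"EI compound {ei.identifier!r} lacks a retention index")
        best: EICILink | None = None
        for hit, ci_spec in ci_hits:
            if ci_spec.retention_index is None:
                raise ValueError(f"CI spectrum {ci_spec.identifier!r} lacks a retention index")
            d_ri = abs(ei.retention_index - ci_spec.retention_index)
            if d_ri > ri_tol:
                continue
            shared = 0
            for frag_mz in ei.mz:
                tol_da = frag_mz * frag_tol_ppm * 1e-6
                if np.any(np.abs(ci_spec.mz - frag_mz) <= tol_da):
                    shared += 1
            if shared < min_shared:
                continue
            candidate = EICILink(
                ei_id=ei.identifier,
                ci_id=ci_spec.identifier,
                neutral_mass=hit.neutral_mass,
                ri_difference=d_ri,
                shared_fragments=shared,
            )
            if best is None or (candidate.shared_fragments, -candidate.ri_difference) > (
                best.shared_fragments,
                -best.ri_difference,
            ):
                best = candidate
        if best is not None:
            if decompose_constraints is not None:
                best.formula_candidates = decompose_mass(
                    best.neutral_mass, decompose_constraints, as_fragment_ion=False
                )[:max_candidates]
            links.append(best)
    return links
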