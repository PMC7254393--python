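"""Unit-mass EI library search: weighted dot-product (cosine) scoring plus
the plausibility curation that guards against high scores from sparse
spectra.

The match factor is the cosine of the weighted intensity vectors
``w = mz^a * intensity^b`` over the union of integer m/z bins, scaled to
the conventional 0-999 range. The default weighting (a=0, b=0.5,
square-root intensities) is reproducible and documented; a NIST-like
preset (a=3, b=0.6) is available since the commercial search program's
internal weighting is not public.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, SpectralLibrary

__all__ = ["PRESETS", "MatchHit", "dot_product_score", "search_library", "curate_hit"]

#: (mz_power, intensity_power) weighting presets.
PRESETS: dict[str, tuple[float, float]] = {
    "sqrt": (0.0, 0.5),
    "nist": (3.0, 0.6),
}


@dataclass
class MatchHit:
    """One library hit for a query spectrum."""

    query_id: str
    library_id: str
    score: float                       # 0..999
    n_matched_peaks: int
    plausible: bool | None = None
    reasons: list[str] = field(default_factory=list)


def _weighted(spectrum: Spectrum, mz_power: float, intensity_power: float) -> dict[float, float]:
    w = (spectrum.mz ** mz_power) * (spectrum.intensity ** intensity_power)
    return dict(zip(spectrum.mz.tolist(), w.tolist()))


def dot_product_score(
    query: Spectrum,
    reference: Spectrum,
    mz_power: float = 0.0,
    intensity_power: float = 0.5,
) -> float:
    """Cosine match factor in [0, 999] over the union of m/z bins.

    Symmetric in its arguments and invariant under uniform intensity
    scaling of either spectrum; 999 is attained iff the weighted vectors
    are proportional.
    """
    if query.n_peaks == 0 or reference.n_peaks == 0:
        raise ValueError("cannot score an empty spectrum")
    if query.resolution != reference.resolution:
        raise ValueError(
            f"resolution mismatch: query is {query.resolution!r}, "
            f"reference is {reference.resolution!r}"
        )
    wq = _weighted(query, mz_power, intensity_power)
    wr = _weighted(reference, mz_power, intensity_power)
    bins = set(wq) | set(wr)
    a = np.array([wq.get(b, 0.0) for b in bins])
    b = np.array([wr.get(b, 0.0) for b in bins])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    cos = float(a @ b) / (na * nb)
    cos = min(max(cos, 0.0), 1.0)
    if cos > 1.0 - 1e-12:
        cos = 1.0
    return 999.0 * cos


def matched_peak_count(query: Spectrum, reference: Spectrum) -> int:
    """Number of m/z bins where both spectra have non-zero intensity."""
    q = set(query.mz[query.intensity > 0].tolist())
    r = set(reference.mz[reference.intensity > 0].tolist())
    return len(q & r)


def search_library(
    query: Spectrum,
    library: SpectralLibrary,
    top_k: int = 5,
    mz_power: float = 0.0,
    intensity_power: float = 0.5,
) -> list[MatchHit]:
    """Score a query against every library entry; hits sorted by score
    descending with ties broken by library identifier."""
    if len(library) == 0:
        raise ValueError("library is empty")
    hits = [
        MatchHit(
            query_id=query.identifier,
            library_id=ref.identifier,
            score=dot_product_score(query, ref, mz_power, intensity_power),
            n_matched_peaks=matched_peak_count(query, ref),
        )
        for ref in library
    ]
    hits.sort(key=lambda h: (-h.score, h.library_id))
    return hits[: max(top_k, 0)]


def curate_hit(
    hit: MatchHit,
    query: Spectrum,
    min_score: float = 700.0,
    min_matched_peaks: int = 5,
    min_query_peaks: int = 20,
) -> MatchHit:
    """Flag a hit as plausible or list the failed criteria.

    Extracted spectra with a low number of signals can generate high
    scores even when few peaks match; the ``min_query_peaks`` criterion
    (default 20) encodes that trace-compound failure mode.
    """
    reasons: list[str] = []
    if hit.score < min_score:
        reasons.append("low-score")
    if hit.n_matched_peaks < min_matched_peaks:
        reasons.append("few-matched-peaks")
    if query.n_peaks < min_query_peaks:
        reasons.append("few-signals")
    hit.plausible = not reasons
    hit.reasons = reasons
    return hit
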