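"""Centroided EI/CI spectra, NIST-style MSP text I/O, and resolution
transforms.

The pipeline consumes already-deconvoluted pseudospectra (one centroided
peak list per compound); raw-file parsing and peak picking are out of
scope. MSP reading tolerates the two common pair dialects (one ``mz
intensity`` pair per line, or several ``mz intensity;`` pairs on one line);
writing emits a single canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "MSPError",
    "read_msp",
    "write_msp",
    "to_unit_mass",
    "normalize",
    "abundance_cutoff",
]


class MSPError(ValueError):
    """Malformed MSP record (mismatched peak count, unparseable pair)."""


@dataclass
class Spectrum:
    """A centroided peak list with acquisition metadata.

    m/z values are sorted ascending on construction and exact duplicates
    are merged by summing their intensities.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "EI"                    # "EI" | "CI"
    resolution: str = "accurate"        # "accurate" | "unit"
    identifier: str = ""
    name: str | None = None
    formula: str | None = None
    retention_time: float | None = None
    retention_index: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mode not in ("EI", "CI"):
            raise ValueError(f"mode must be 'EI' or 'CI', got {self.mode!r}")
        if self.resolution not in ("accurate", "unit"):
            raise ValueError(f"resolution must be 'accurate' or 'unit', got {self.resolution!r}")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            intensity = np.bincount(inverse, weights=intensity)
            mz = uniq
        self.mz = mz
        self.intensity = intensity
        if not self.identifier and self.name:
            self.identifier = self.name

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_intensity(self) -> float:
        if self.mz.size == 0:
            raise ValueError("empty spectrum has no base peak")
        return float(self.intensity.max())

    def with_peaks(self, mz, intensity) -> "Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


@dataclass
class SpectralLibrary:
    """Ordered collection of spectra with unique identifiers."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.spectra:
            if s.identifier in seen:
                raise ValueError(f"duplicate identifier in library: {s.identifier!r}")
            seen.add(s.identifier)

    def __iter__(self):
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def get(self, identifier: str) -> Spectrum:
        for s in self.spectra:
            if s.identifier == identifier:
                return s
        raise KeyError(identifier)

    def add(self, spectrum: Spectrum) -> None:
        if any(s.identifier == spectrum.identifier for s in self.spectra):
            raise ValueError(f"duplicate identifier in library: {spectrum.identifier!r}")
        self.spectra.append(spectrum)


def _parse_comments(text: str) -> dict[str, str]:
    out = {}
    for token in text.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k.strip().lower()] = v.strip()
    return out


def read_msp(path) -> SpectralLibrary:
    """Parse a NIST-style MSP file into a library.

    Records are blank-line delimited blocks of ``Key: value`` headers
    followed by ``Num Peaks`` m/z-intensity pairs, either one per line or
    packed with ``;`` separators. The declared peak count must match.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    spectra: list[Spectrum] = []
    record: dict[str, str] = {}
    peaks: list[float] = []
    expecting_peaks = False
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal record, peaks, expecting_peaks
        if not record and not peaks:
            return
        name = record.get("name", "")
        declared = record.get("num peaks")
        if declared is None:
            raise MSPError(f"record {name!r} near line {start_line}: missing 'Num Peaks'")
        n = int(declared)
        if len(peaks) != 2 * n:
            raise MSPError(
                f"record {name!r} near line {start_line}: 'Num Peaks: {n}' but "
                f"{len(peaks) // 2} pairs parsed (line {line_no})"
            )
        meta = _parse_comments(record.get("comments", ""))
        mz = peaks[0::2]
        intensity = peaks[1::2]
        spectra.append(
            Spectrum(
                mz=np.array(mz),
                intensity=np.array(intensity),
                mode=meta.get("mode", record.get("mode", "EI")).upper(),
                resolution=meta.get("resolution", record.get("resolution", "accurate")).lower(),
                identifier=record.get("db#", name),
                name=name or None,
                formula=record.get("formula") or None,
                retention_time=float(record["rt"]) if "rt" in record else None,
                retention_index=float(record["ri"]) if "ri" in record else None,
            )
        )
        record, peaks = {}, []
        expecting_peaks = False

    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            flush(line_no)
            continue
        if not expecting_peaks and ":" in line:
            key, _, value = line.partition(":")
            key_l = key.strip().lower()
            if not record:
                start_line = line_no
            record[key_l] = value.strip()
            if key_l == "num peaks":
                expecting_peaks = True
            continue
        if not expecting_peaks:
            raise MSPError(f"line {line_no}: unexpected content outside a record: {line!r}")
        for token in line.replace(";", " ").replace(",", " ").split():
            try:
                peaks.append(float(token))
            except ValueError as exc:
                raise MSPError(
                    f"record {record.get('name', '')!r}, line {line_no}: "
                    f"unparseable peak token {token!r}"
                ) from exc
    flush(len(lines) + 1)
    return SpectralLibrary(spectra)


def write_msp(library: SpectralLibrary | list[Spectrum], path) -> None:
    """Write spectra in the canonical MSP form: one ``mz intensity`` pair
    per line, m/z to 5 decimals and intensity to 2."""
    spectra = list(library)
    out_lines: list[str] = []
    for s in spectra:
        out_lines.append(f"Name: {s.name or s.identifier}")
        if s.identifier and s.identifier != (s.name or s.identifier):
            out_lines.append(f"DB#: {s.identifier}")
        if s.formula:
            out_lines.append(f"Formula: {s.formula}")
        if s.retention_index is not None:
            out_lines.append(f"RI: {s.retention_index:.1f}")
        if s.retention_time is not None:
            out_lines.append(f"RT: {s.retention_time:.4f}")
        out_lines.append(f"Comments: mode={s.mode} resolution={s.resolution}")
        out_lines.append(f"Num Peaks: {s.n_peaks}")
        for mz, inten in zip(s.mz, s.intensity):
            out_lines.append(f"{mz:.5f} {inten:.2f}")
        out_lines.append("")
    Path(path).write_text("\n".join(out_lines))


def to_unit_mass(spectrum: Spectrum) -> Spectrum:
    """Degrade an accurate-mass spectrum to unit (nominal) resolution.

    m/z is rounded half-away-from-zero to the nearest integer (the
    convention nominal-mass libraries index by); peaks landing in the same
    integer bin are summed, so total intensity is conserved exactly.
    """
    if spectrum.resolution != "accurate":
        raise ValueError("to_unit_mass expects an accurate-mass spectrum")
    binned = np.floor(spectrum.mz + 0.5)  # mz > 0, so this is half-away-from-zero
    return replace(spectrum, mz=binned, intensity=spectrum.intensity.copy(), resolution="unit")


def normalize(spectrum: Spectrum, base: float = 999.0) -> Spectrum:
    """Scale intensities so the base peak equals ``base``."""
    if spectrum.n_peaks == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = spectrum.intensity.max()
    if top <= 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return spectrum.with_peaks(spectrum.mz, spectrum.intensity * (base / top))


def abundance_cutoff(spectrum: Spectrum, fraction: float = 0.05) -> Spectrum:
    """Drop peaks below ``fraction`` of the base peak; peaks exactly at the
    threshold are retained. Scale-invariant, hence idempotent."""
    if spectrum.n_peaks == 0:
        raise ValueError("cannot apply a cutoff to an empty spectrum")
    top = spectrum.intensity.max()
    if top <= 0:
        raise ValueError("cannot apply a cutoff to all-zero intensities")
    keep = spectrum.intensity >= fraction * top
    return spectrum.with_peaks(spectrum.mz[keep], spectrum.intensity[keep])
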