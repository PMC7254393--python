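"""Ground-truthed synthetic data: derivatized-metabolite spectra and paired
high-resolution / unit-mass twin experiments.

The generator emulates the structure a two-platform comparison rests on: a
compound set of TMS/MeOX-derivatized primary metabolites (seeded from real
amino-acid / sugar / organic-acid formulas), EI fragment spectra whose
fragment compositions are genuine subformulas of the derivatized molecule,
methane-CI spectra carrying the [M-CH3]+/[M+H]+/[M+C2H5]+/[M+C3H5]+
series, a two-group (control vs osmotic stress) design with pooled-QC and
media-blank injections, injection-order signal drift, ppm-scale mass
error, and a unit-mass twin channel whose detection limit is raised by a
sensitivity handicap (default 8-fold) so that low-abundance compounds lose
fragments or vanish entirely.

Everything is driven by an integer-seeded numpy Generator: a fixed seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import Formula, derivatize, is_subformula, monoisotopic_mass, rdbe
from .spectra import SpectralLibrary, Spectrum, to_unit_mass
from .ci import ADDUCT_SERIES
from .stats import FeatureTable

__all__ = [
    "CURATED_METABOLITES",
    "CompoundTruth",
    "GroundTruth",
    "ExperimentDesign",
    "EffectModel",
    "NoiseModel",
    "Channel",
    "TwinDataset",
    "generate_compounds",
    "generate_experiment",
    "generate_decoys",
]

#: Curated primary-metabolite formulas (name, formula). Amino acids, sugars,
#: polyols, organic acids and related compounds commonly seen in derivatized
#: GC-MS profiles of microalgae; the analytical-standards panel (glucose,
#: proline, glutamic acid, citric acid, dehydroascorbic acid, ...) seeds it.
CURATED_METABOLITES: tuple[tuple[str, str], ...] = (
    ("alanine", "C3H7NO2"),
    ("glycine", "C2H5NO2"),
    ("serine", "C3H7NO3"),
    ("threonine", "C4H9NO3"),
    ("valine", "C5H11NO2"),
    ("leucine", "C6H13NO2"),
    ("isoleucine", "C6H13NO2"),
    ("proline", "C5H9NO2"),
    ("methionine", "C5H11NO2S"),
    ("cysteine", "C3H7NO2S"),
    ("phenylalanine", "C9H11NO2"),
    ("tyrosine", "C9H11NO3"),
    ("tryptophan", "C11H12N2O2"),
    ("aspartic acid", "C4H7NO4"),
    ("asparagine", "C4H8N2O3"),
    ("glutamic acid", "C5H9NO4"),
    ("glutamine", "C5H10N2O3"),
    ("lysine", "C6H14N2O2"),
    ("arginine", "C6H14N4O2"),
    ("histidine", "C6H9N3O2"),
    ("ornithine", "C5H12N2O2"),
    ("beta-alanine", "C3H7NO2"),
    ("GABA", "C4H9NO2"),
    ("pyroglutamic acid", "C5H7NO3"),
    ("pyrrole-2-carboxylic acid", "C5H5NO2"),
    ("taurine", "C2H7NO3S"),
    ("putrescine", "C4H12N2"),
    ("urea", "CH4N2O"),
    ("glucose", "C6H12O6"),
    ("fructose", "C6H12O6"),
    ("galactose", "C6H12O6"),
    ("mannose", "C6H12O6"),
    ("ribose", "C5H10O5"),
    ("xylose", "C5H10O5"),
    ("arabinose", "C5H10O5"),
    ("sucrose", "C12H22O11"),
    ("trehalose", "C12H22O11"),
    ("maltose", "C12H22O11"),
    ("myo-inositol", "C6H12O6"),
    ("mannitol", "C6H14O6"),
    ("sorbitol", "C6H14O6"),
    ("ribitol", "C5H12O5"),
    ("erythritol", "C4H10O4"),
    ("glycerol", "C3H8O3"),
    ("lactic acid", "C3H6O3"),
    ("pyruvic acid", "C3H4O3"),
    ("glyceric acid", "C3H6O4"),
    ("succinic acid", "C4H6O4"),
    ("fumaric acid", "C4H4O4"),
    ("malic acid", "C4H6O5"),
    ("citric acid", "C6H8O7"),
    ("2-oxoglutaric acid", "C5H6O5"),
    ("shikimic acid", "C7H10O5"),
    ("quinic acid", "C7H12O6"),
    ("ascorbic acid", "C6H8O6"),
    ("dehydroascorbic acid", "C6H6O6"),
    ("threonic acid", "C4H8O5"),
    ("threono-1,4-lactone", "C4H6O4"),
    ("glucose-6-phosphate", "C6H13O9P"),
    ("glycerol-3-phosphate", "C3H9O6P"),
    ("phosphoric acid", "H3PO4"),
    ("nicotinic acid", "C6H5NO2"),
    ("uracil", "C4H4N2O2"),
    ("adenine", "C5H5N5"),
    ("palmitic acid", "C16H32O2"),
    ("stearic acid", "C18H36O2"),
    ("oleic acid", "C18H34O2"),
    ("linoleic acid", "C18H32O2"),
    ("eicosapentaenoic acid", "C20H30O2"),
)

#: Neutral-loss building blocks for EI fragment construction. Losses are
#: subtracted (in random combinations) from the derivatized formula, so
#: every fragment is a subformula of its parent by construction.
_LOSSES: tuple[tuple[str, str], ...] = (
    ("CH3", "CH3"),
    ("H2O", "H2O"),
    ("CO", "CO"),
    ("CO2", "CO2"),
    ("CH4", "CH4"),
    ("C2H4", "C2H4"),
    ("TMSO", "C3H9OSi"),
    ("TMSOH", "C3H10OSi"),
    ("CH3O", "CH3O"),
    ("HCN", "HCN"),
    ("NH3", "NH3"),
)

_TMS_MARKER = Formula(C=3, H=9, Si=1)  # the ubiquitous m/z 73 [Si(CH3)3]+


@dataclass
class CompoundTruth:
    """Everything the generator knows about one synthetic compound."""

    cid: str
    name: str
    base_formula: Formula
    n_tms: int
    n_meox: int
    derivatized: Formula
    retention_index: float
    #: (ion composition, theoretical ion m/z, base-999 intensity)
    fragments: list[tuple[Formula, float, float]]
    in_library: bool = False
    # Filled in by generate_experiment:
    true_mean: float = float("nan")
    fold_change: float = 1.0
    in_blank: bool = False
    blank_mean: float = 0.0

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.derivatized)


@dataclass
class GroundTruth:
    """The generator's record of true compounds, used for recovery scoring."""

    compounds: list[CompoundTruth]

    def __iter__(self):
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def get(self, cid: str) -> CompoundTruth:
        for c in self.compounds:
            if c.cid == cid:
                return c
        raise KeyError(cid)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cid": c.cid,
                "name": c.name,
                "base_formula": c.base_formula.hill(),
                "n_tms": c.n_tms,
                "n_meox": c.n_meox,
                "derivatized_formula": c.derivatized.hill(),
                "neutral_mass": c.neutral_mass,
                "retention_index": c.retention_index,
                "n_fragments": len(c.fragments),
                "in_library": c.in_library,
                "true_mean": c.true_mean,
                "fold_change": c.fold_change,
                "in_blank": c.in_blank,
            }
            for c in self.compounds
        ]
        return pd.DataFrame(rows).set_index("cid")


def _random_plausible_formula(rng: np.random.Generator) -> tuple[str, Formula]:
    """A random CHNO(S) composition passing the SENIOR condition, used to
    extend the compound set beyond the curated list."""
    from .chem import senior_check

    while True:
        c = int(rng.integers(3, 15))
        n = int(rng.integers(0, 3))
        o = int(rng.integers(1, 8))
        s = int(rng.integers(0, 2))
        max_h = 2 * c + n + 2
        h = int(rng.integers(max(1, max_h // 2), max_h + 1))
        f = Formula(C=c, H=h, N=n, O=o, S=s)
        if senior_check(f):
            return (f"random-{f.hill()}", f)


def _build_fragments(
    deriv: Formula, rng: np.random.Generator, n_target: int
) -> list[tuple[Formula, float, float]]:
    """Fragment ions as random neutral-loss combinations from the parent."""
    loss_formulas = [Formula.from_string(s) for _, s in _LOSSES]
    seen: set[Formula] = set()
    frags: list[Formula] = []
    if is_subformula(_TMS_MARKER, deriv):
        frags.append(_TMS_MARKER)
        seen.add(_TMS_MARKER)
    attempts = 0
    while len(frags) < n_target and attempts < 600:
        attempts += 1
        k = int(rng.integers(1, 5))
        total = Formula()
        for idx in rng.integers(0, len(loss_formulas), size=k):
            total = total + loss_formulas[int(idx)]
        frag = deriv.minus(total)
        if frag is None or frag in seen or frag == deriv:
            continue
        if frag["C"] < 1 or frag["H"] < 1:
            continue
        if rdbe(frag) < -0.5:  # no ion composition is more H-rich than CnH2n+3
            continue
        mz = monoisotopic_mass(frag, charge=+1)
        if not (50.0 <= mz <= 600.0):
            continue
        seen.add(frag)
        frags.append(frag)

    intensities = np.clip(rng.gamma(shape=1.2, scale=220.0, size=len(frags)), 5.0, 999.0)
    intensities[int(rng.integers(0, len(frags)))] = 999.0
    if frags and frags[0] == _TMS_MARKER:
        intensities[0] = max(intensities[0], float(rng.uniform(600.0, 999.0)))
    out = [
        (f, monoisotopic_mass(f, charge=+1), float(i))
        for f, i in zip(frags, intensities)
    ]
    # Weak or absent molecular ion: most EI molecular ions are lost.
    if rng.random() < 0.5:
        out.append((deriv, monoisotopic_mass(deriv, charge=+1), float(rng.uniform(1.0, 20.0))))
    out.sort(key=lambda t: t[1])
    return out


def _sample_retention_indices(rng: np.random.Generator, n: int, min_gap: float = 2.0) -> np.ndarray:
    for _ in range(200):
        ri = np.sort(rng.uniform(800.0, 3600.0, size=n))
        if n < 2 or np.min(np.diff(ri)) >= min_gap:
            return ri
    raise RuntimeError("could not place retention indices without collisions")


def generate_compounds(
    n: int = 60,
    seed: int = 0,
    library_fraction: float = 0.8,
) -> tuple[GroundTruth, SpectralLibrary]:
    """Draw a ground-truthed compound set and its unit-mass EI library.

    Formulas come from the curated metabolite list (random plausible
    CHNOS formulas fill in beyond it); TMS counts are drawn 1..6 (bounded
    by derivatizable heteroatoms), MeOX 0..1 (only with O present). The
    library contains the unit-mass-degraded theoretical EI spectra of a
    ``library_fraction`` subset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= library_fraction <= 1.0:
        raise ValueError("library_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    pool = list(CURATED_METABOLITES)
    picks: list[tuple[str, Formula]] = []
    order = rng.permutation(len(pool))
    for i in order[: min(n, len(pool))]:
        name, text = pool[i]
        picks.append((name, Formula.from_string(text)))
    while len(picks) < n:
        picks.append(_random_plausible_formula(rng))

    ris = _sample_retention_indices(rng, n)
    compounds: list[CompoundTruth] = []
    for i, ((name, base), ri) in enumerate(zip(picks, ris)):
        sites = max(1, base["O"] + base["N"])
        n_tms = int(rng.integers(1, min(6, sites) + 1))
        n_meox = int(rng.integers(0, 2)) if base["O"] >= 1 else 0
        deriv = derivatize(base, n_tms, n_meox)
        n_frag = int(rng.integers(10, 41))
        fragments = _build_fragments(deriv, rng, n_frag)
        assert all(is_subformula(f, deriv) for f, _, _ in fragments)
        compounds.append(
            CompoundTruth(
                cid=f"M{i:03d}",
                name=name,
                base_formula=base,
                n_tms=n_tms,
                n_meox=n_meox,
                derivatized=deriv,
                retention_index=float(ri),
                fragments=fragments,
            )
        )

    n_lib = int(round(n * library_fraction))
    lib_idx = set(rng.choice(n, size=n_lib, replace=False).tolist())
    lib_spectra: list[Spectrum] = []
    for i, c in enumerate(compounds):
        if i not in lib_idx:
            continue
        c.in_library = True
        accurate = Spectrum(
            mz=np.array([mz for _, mz, _ in c.fragments]),
            intensity=np.array([inten for _, _, inten in c.fragments]),
            mode="EI",
            resolution="accurate",
            identifier=f"LIB-{c.cid}",
            name=c.name,
            formula=c.derivatized.hill(),
            retention_index=c.retention_index,
        )
        lib_spectra.append(to_unit_mass(accurate))
    return GroundTruth(compounds), SpectralLibrary(lib_spectra)


@dataclass(frozen=True)
class ExperimentDesign:
    n_control: int = 6
    n_stress: int = 6
    n_qc: int = 5
    n_blank: int = 3

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_stress < 2 or self.n_qc < 3 or self.n_blank < 2:
            raise ValueError("design requires >= 2 control, 2 stress, 3 QC, 2 blank samples")


@dataclass(frozen=True)
class EffectModel:
    planted_fraction: float = 0.2
    fc_range: tuple[float, float] = (3.0, 8.0)


@dataclass(frozen=True)
class NoiseModel:
    cv: float = 0.15          # biological + analytical coefficient of variation
    ppm_sigma: float = 1.0    # mass-accuracy jitter of the high-res channel


@dataclass
class Channel:
    """One platform's view of the experiment."""

    ei_spectra: SpectralLibrary
    features: FeatureTable | None = None
    ci_spectra: SpectralLibrary | None = None


@dataclass
class TwinDataset:
    """Paired high-resolution and unit-mass views of one experiment."""

    truth: GroundTruth
    hr: Channel
    unit: Channel
    handicap: float
    lod: float


def _injection_orders(rng: np.random.Generator, design: ExperimentDesign) -> pd.DataFrame:
    """Sample sheet: blanks lead the sequence, QCs are spread evenly across
    it (first and last injections are QCs), experimental samples shuffled."""
    n_exp = design.n_control + design.n_stress
    total = n_exp + design.n_qc + design.n_blank
    ids = (
        [f"ctrl_{i + 1}" for i in range(design.n_control)]
        + [f"stress_{i + 1}" for i in range(design.n_stress)]
        + [f"QC_{i + 1}" for i in range(design.n_qc)]
        + [f"blank_{i + 1}" for i in range(design.n_blank)]
    )
    classes = (
        ["control"] * design.n_control
        + ["stress"] * design.n_stress
        + ["QC"] * design.n_qc
        + ["blank"] * design.n_blank
    )
    qc_slots = list(
        np.unique(np.round(np.linspace(design.n_blank, total - 1, design.n_qc)).astype(int))
    )
    blank_slots = list(range(design.n_blank))
    spare = (i for i in range(design.n_blank, total) if i not in set(qc_slots))
    while len(qc_slots) < design.n_qc:  # rounding collisions on tiny runs
        qc_slots.append(next(spare))
    qc_slots = sorted(qc_slots)
    exp_slots = [i for i in range(total) if i not in set(qc_slots) and i not in blank_slots]
    exp_ids = [i for i, c in enumerate(classes) if c in ("control", "stress")]
    rng.shuffle(exp_ids)
    slot_of = {}
    for sid, slot in zip(exp_ids, exp_slots):
        slot_of[ids[sid]] = slot
    for k, slot in enumerate(qc_slots):
        slot_of[f"QC_{k + 1}"] = slot
    for k, slot in enumerate(blank_slots):
        slot_of[f"blank_{k + 1}"] = slot
    return pd.DataFrame(
        {"cls": classes, "order": [slot_of[i] + 1 for i in ids]}, index=pd.Index(ids, name="sample")
    )


def _observed_spectrum(
    c: CompoundTruth,
    rng: np.random.Generator,
    ppm_sigma: float,
    detection_floor: float,
    mode_label: str,
) -> Spectrum | None:
    """Accurate observed EI spectrum with ppm jitter; fragments whose
    absolute signal (mean area x relative intensity) falls below the
    detection floor are lost."""
    mz, inten = [], []
    for _, theo_mz, rel in c.fragments:
        signal = c.true_mean * rel / 999.0
        if signal < detection_floor:
            continue
        jitter = 1.0 + rng.normal(0.0, ppm_sigma) * 1e-6
        mz.append(theo_mz * jitter)
        inten.append(rel * float(np.exp(rng.normal(0.0, 0.05))))
    if not mz:
        return None
    return Spectrum(
        mz=np.array(mz),
        intensity=np.array(inten),
        mode="EI",
        resolution="accurate",
        identifier=f"{mode_label}-{c.cid}",
        name=c.name,
        retention_index=c.retention_index + float(rng.normal(0.0, 0.5)),
    )


def _ci_spectrum(
    c: CompoundTruth, rng: np.random.Generator, ppm_sigma: float
) -> Spectrum:
    """Methane-CI spectrum: the four-member adduct series of the
    derivatized molecule (members below the m/z 80 scan floor dropped)
    plus a few shared EI fragments."""
    M = c.neutral_mass
    base = {"[M+H]+": 999.0, "[M-CH3]+": 450.0, "[M+C2H5]+": 220.0, "[M+C3H5]+": 120.0}
    mz, inten = [], []
    for role, offset in ADDUCT_SERIES.items():
        ion = M + offset
        if ion < 80.0:
            continue
        mz.append(ion * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6))
        inten.append(base[role] * float(np.exp(rng.normal(0.0, 0.1))))
    shared = [t for t in sorted(c.fragments, key=lambda t: -t[2]) if t[1] >= 80.0][:3]
    for _, theo_mz, rel in shared:
        mz.append(theo_mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6))
        inten.append(max(rel * 0.3, 10.0))
    return Spectrum(
        mz=np.array(mz),
        intensity=np.array(inten),
        mode="CI",
        resolution="accurate",
        identifier=f"CI-{c.cid}",
        name=c.name,
        retention_index=c.retention_index + float(rng.normal(0.0, 0.5)),
    )


def generate_experiment(
    truth: GroundTruth,
    design: ExperimentDesign | None = None,
    effect: EffectModel | None = None,
    noise: NoiseModel | None = None,
    drift_slope: float = 0.3,
    handicap: float = 8.0,
    lod: float = 3e4,
    seed: int = 0,
) -> TwinDataset:
    """Simulate the paired two-platform experiment on a compound set.

    Peak areas are log-normal around the compound's true mean, multiplied
    by the planted fold change in the stress group and by a linear
    injection-order drift; QCs are drawn around the pooled mean, blanks
    carry the in-blank compounds only. The unit-mass channel shares the
    latent biology but its detection limit is ``handicap``-fold higher, so
    low-abundance compounds lose fragments or vanish, and its spectra are
    nominal-mass rounded.
    """
    design = design or ExperimentDesign()
    effect = effect or EffectModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    samples = _injection_orders(rng, design)
    n_total_orders = int(samples["order"].max())
    sigma = float(np.sqrt(np.log(1.0 + noise.cv**2)))

    # Latent compound parameters -------------------------------------
    n = len(truth)
    means = 10.0 ** rng.uniform(4.0, 7.0, size=n)
    planted = rng.random(n) < effect.planted_fraction
    fcs = np.ones(n)
    draw = rng.uniform(effect.fc_range[0], effect.fc_range[1], size=n)
    down = rng.random(n) < 0.5
    fcs[planted] = np.where(down[planted], 1.0 / draw[planted], draw[planted])
    in_blank = rng.random(n) < 0.15
    blank_means = means * rng.uniform(0.02, 0.6, size=n) * in_blank

    compounds = []
    for c, mu, fc, ib, bm in zip(truth, means, fcs, in_blank, blank_means):
        compounds.append(
            replace(c, true_mean=float(mu), fold_change=float(fc), in_blank=bool(ib),
                    blank_mean=float(bm))
        )
    truth_out = GroundTruth(compounds)

    # Latent areas ----------------------------------------------------
    def drift(order: int) -> float:
        return 1.0 + drift_slope * (order - 1) / max(n_total_orders - 1, 1)

    frac_stress = design.n_stress / (design.n_control + design.n_stress)
    latent = pd.DataFrame(
        index=[c.cid for c in compounds], columns=samples.index, dtype=float
    )
    for c in compounds:
        for sid, row in samples.iterrows():
            cls, order = row["cls"], int(row["order"])
            if cls == "control":
                expected = c.true_mean
            elif cls == "stress":
                expected = c.true_mean * c.fold_change
            elif cls == "QC":
                expected = c.true_mean * (1.0 - frac_stress + frac_stress * c.fold_change)
            else:  # blank
                expected = c.blank_mean
            if expected <= 0:
                latent.loc[c.cid, sid] = 0.0
                continue
            latent.loc[c.cid, sid] = (
                expected * drift(order) * float(np.exp(rng.normal(0.0, sigma)))
            )

    def channel_features(floor: float) -> FeatureTable:
        vals = latent.where(latent >= floor)
        return FeatureTable(areas=vals, samples=samples.copy())

    hr_features = channel_features(lod)
    unit_features = channel_features(lod * handicap)

    # Observed spectra ------------------------------------------------
    hr_specs, unit_specs, ci_specs = [], [], []
    for c in compounds:
        hr_spec = _observed_spectrum(c, rng, noise.ppm_sigma, lod, "HR")
        unit_src = _observed_spectrum(c, rng, noise.ppm_sigma, lod * handicap, "UNIT")
        if hr_spec is not None:
            hr_specs.append(hr_spec)
            ci_specs.append(_ci_spectrum(c, rng, noise.ppm_sigma))
        if unit_src is not None:
            unit_specs.append(to_unit_mass(unit_src))

    return TwinDataset(
        truth=truth_out,
        hr=Channel(
            ei_spectra=SpectralLibrary(hr_specs),
            features=hr_features,
            ci_spectra=SpectralLibrary(ci_specs),
        ),
        unit=Channel(ei_spectra=SpectralLibrary(unit_specs), features=unit_features),
        handicap=handicap,
        lod=lod,
    )


#: Nominal-mass-preserving element swaps used to build decoys, as
#: (removed, added) composition pairs.
_DECOY_SWAPS: tuple[tuple[str, str], ...] = (
    ("O", "NH2"),
    ("NH2", "O"),
    ("N", "CH2"),
    ("CH2", "N"),
    ("Si", "C2H4"),
    ("C2H4", "Si"),
    ("S", "O2"),
    ("O2", "S"),
)


def generate_decoys(
    truth: GroundTruth, seed: int = 0, max_decoys: int = 2
) -> dict[str, dict[str, list[Formula] | Formula]]:
    """Per compound: the true derivatized proposal plus decoy formulas at
    the same nominal molecular mass but a different exact mass (> 5 ppm
    away), built by nominal-mass-preserving element swaps."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, list[Formula] | Formula]] = {}
    for c in truth:
        true_f = c.derivatized
        true_mass = monoisotopic_mass(true_f)
        decoys: list[Formula] = []
        swap_order = rng.permutation(len(_DECOY_SWAPS))
        for k in swap_order:
            removed, added = _DECOY_SWAPS[int(k)]
            reduced = true_f.minus(Formula.from_string(removed))
            if reduced is None:
                continue
            decoy = reduced + Formula.from_string(added)
            if decoy == true_f:
                continue
            if decoy.nominal_mass() != true_f.nominal_mass():
                continue
            dppm = abs(monoisotopic_mass(decoy) - true_mass) / true_mass * 1e6
            if dppm <= 5.0:
                continue
            decoys.append(decoy)
            if len(decoys) >= max_decoys:
                break
        assert decoys, f"no decoy constructible for {c.cid} ({true_f.hill()})"
        out[c.cid] = {"true": true_f, "decoys": decoys}
    return out
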