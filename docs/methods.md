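# Methods

This note records the models, conventions and deliberate simplifications
behind `hrgcms`, in the order the pipeline applies them.

## Mass arithmetic

Atomic masses and isotope abundances ship as a versioned text table
(`hrgcms/data/isotopes.tsv`, IUPAC/CODATA values) so results are bit-stable
across environments. Ion masses are charge-aware: the electron mass
(0.000549 Da) is subtracted per positive charge. At 3 ppm tolerance this
matters — below m/z ≈ 180 the electron mass exceeds the tolerance window,
so neglecting it would systematically shift fragment-ion decompositions.

ppm windows are symmetric closed intervals m·(1 ± tol·10⁻⁶).

## Formula decomposition

`decompose_mass` searches the constrained element-count lattice
depth-first, heaviest element first, with suffix mass bounds; the residual
window then pins the hydrogen count, so the effective cost is the product
of the non-hydrogen range widths, further pruned by mass feasibility.
Lattices beyond 10⁸ points are rejected with a size estimate rather than
searched. Candidate filters:

- **RDBE** 1 + Σ nᵢ(vᵢ−2)/2 with one fixed valence per element (C 4, Si 4,
  N 3, P 3, O 2, S 2, H 1). Multivalent states (S⁶⁺, P⁵⁺, N⁵⁺) are not
  enumerated — simplicity over completeness; the curated metabolite panel
  needs none of them.
- **SENIOR** (neutral molecules only): even valence sum and
  Σv ≥ 2(atoms−1).
- **Element ratios** at the 99.7%-coverage golden-rules ranges
  (H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8). Silicon
  is counted as carbon for ratio purposes since TMS groups add a
  C₃H₈Si skeleton; formulas without a C/Si skeleton pass vacuously. The
  ranges live on the constraints object and can be tightened or relaxed.
- An additional per-element probability score is *not* implemented: no
  published functional form is authoritative, and at desk scale the
  ratio + SENIOR + RDBE filters subsume its discriminating role.

Fragment-ion searches (`as_fragment_ion`) target the neutral-composition
mass m + mₑ, skip SENIOR, allow half-integer RDBE down to −0.5 (CnH2n+3⁺ is
the most hydrogen-rich ion composition), and skip ratio checks — EI
fragments are radicals or even-electron ions, not molecules.

Output ordering is deterministic: |ppm error| ascending, ties broken by
lower RDBE, then lexicographic element counts in C,H,N,O,P,S,Si order.

## Derivatization

TMS adds C₃H₈Si (active H replaced by Si(CH₃)₃), MeOX adds CH₃N (the
carbonyl O is retained in the methoxime). Structures are unknown at the
formula level, so the O count serves as the proxy precondition for MeOX;
requesting more methoximes than oxygens is rejected. Mass additivity is
exact by construction.

## Spectra and MSP I/O

Spectra are centroided peak lists sorted ascending with exact-duplicate
m/z merged on construction. MSP reading accepts both common pair dialects
(one pair per line; several `mz int;` pairs per line) and enforces the
declared `Num Peaks`; writing emits one canonical form (m/z to 5 decimals,
intensity to 2) plus a `Comments: mode=… resolution=…` line so acquisition
metadata round-trips. Unit-mass degradation rounds half-away-from-zero to
the nearest integer — the convention nominal-mass libraries index by — and
sums co-binned intensities, conserving total intensity exactly. The 5%
abundance cutoff retains peaks exactly at the boundary (the stated rule
excludes only peaks *below* the cutoff).

## Library matching

The match factor is the cosine of weighted vectors w = mzᵃ·Iᵇ over the
union of integer bins, ×999. The commercial search program's internal
weighting is not public, so the default is the reproducible square-root
cosine (a=0, b=0.5) with a NIST-like preset (a=3, b=0.6) available; both
are config keys, and the intensity-power-1 case is cross-checked against
matchms in the tests. Curation flags a hit implausible with reason codes
when score < 700, matched bins < 5, or the query has fewer than 20 peaks —
the last encodes the trace-compound failure mode where sparse spectra
score high on a handful of matching peaks. Reverse/hybrid scores and
retention-index-penalized scoring are out of scope (identity search plus
manual-style curation is the modelled procedure).

## High-resolution filtering

The most intense (default 5) and highest-m/z (default 3) fragments are
selected (intensity ties resolve toward higher m/z); each is decomposed
with element ranges capped elementwise by the proposal, so every candidate
is a strict subformula — hydrogen rearrangements shuffle internal
hydrogens but cannot exceed the molecular formula. Verdict logic: one
unexplained fragment falsifies; all explained with ≥ 3 checked confirms;
otherwise inconclusive. Unit-resolution input is an error, not an
inconclusive verdict: the operation is meaningless without accurate
masses, and the error encodes that. Chromatographic peak-shape concordance
needs raw data and is out of scope; callers working from raw chromatograms
can pre-filter fragments before building the spectrum.

## CI molecular ions

The methane-CI series offsets are fixed: −CH₃−e, +H−e, +C₂H₅−e, +C₃H₅−e
(consecutive spacings CH₄ = 16.03130, C₂H₄ = 28.03130, C = 12.00000 Da).
No [M+NH₄]⁺ — methane, not ammonia, is the modelled reagent gas. The
detector treats every peak as every possible series member, tests the
implied neutral mass against all four offsets, requires a configurable
minimum support (default 3 of 4: spectra truncated at the m/z 80 scan
floor can lose one member), and merges duplicate hypotheses within the
same ppm tolerance used for detection — one knob, fewer surprises. EI–CI
linking demands retention-index agreement within 5 RI units and ≥ 2 shared
fragment m/z values; "similar sum formulas at the retention index" is not
operationalizable without structures, so shared-fragment matching is the
implemented proxy.

## Feature-table statistics

- **Drift correction**: per compound, areas are divided by a QC-anchored
  trend (linear interpolation of pooled-QC areas over injection order,
  edge-extended flat) and rescaled to the compound's QC median. This is a
  deliberate replacement of random-forest-based QC correction: a
  deterministic, dependency-free scheme keeps tests exact, and drift
  correction is a black-box preprocessing step from the workflow's point
  of view. Compounds with fewer than two usable QC observations pass
  through untouched; a drift-free table is a fixed point.
- **QC RSD filter**: RSD = 100·sd/mean (sample sd) over QCs; > 20% is
  excluded, exactly 20% kept. A compound whose RSD cannot be computed
  (< 2 QC observations) is excluded too — its reproducibility is
  unverifiable, which is what the filter screens for.
- **Blank filter**: compounds detected in media blanks survive only if at
  least one experimental group's mean is ≥ 5× the blank mean (boundary
  inclusive); compounds absent from blanks always survive.
- **Missing-value filter**: present (> 0, non-missing) in ≥ 80% of at
  least one experimental group.
- **Transform**: half-minimum imputation per compound, natural log,
  per-compound centering and unit-variance scaling over experimental
  samples. Zero-variance compounds become zero rows with a warning.
- **Volcano**: fold change on raw-scale group means of observed areas
  (an absent control group gives an +inf sentinel, still classifiable);
  imputation is reserved for the log-scale Welch t-test (the test is
  invariant to the per-compound affine part of the transform, so it is run
  on ln areas). BH-FDR across compounds; raw-p mode is a config switch.
  Dysregulation is two-sided (FC > 2 or FC < 0.5, both strict) — the
  volcano has two wings. The test variant (Welch) is a choice; no
  particular variant is canonical for this filter chain.
- **PCA** on the transformed matrix, samples as observations; the sign of
  each component is fixed by making its largest-magnitude loading
  positive, for deterministic outputs.
- **Platform pairing and overlap**: compounds are paired across platforms
  greedily by unit-mass spectral score (≥ 700) within a 5-RI-unit window;
  overlap percent is 100·shared/union of significant sets, rounded.
  Each missed biomarker gets a cause code: below-LOD (absent from the
  other platform's post-filter table), threshold-fail (present but FC/p
  short), blank-excluded, unmatched (pairing failed). On twin data the
  compound ids are shared, which the cause assignment exploits.

## Synthetic twin generator

What it emulates: a derivatized-metabolite compound set (formulas drawn
from a curated panel of ~70 real amino acids, sugars, polyols and organic
acids; TMS 1–6 bounded by derivatizable heteroatoms, MeOX 0–1 with O
present), EI fragments built by subtracting random neutral-loss
combinations (CH₃, H₂O, CO, CO₂, CH₄, C₂H₄, OTMS, TMSOH, CH₃O, HCN, NH₃)
from the derivatized formula — hence genuine subformulas with exact
theoretical m/z — with the ubiquitous m/z 73 Si(CH₃)₃⁺ marker prominent,
fragment-ion RDBE ≥ −0.5 enforced, and molecular ions weak or absent with
probability 0.5 (ion-trap-accumulation loss of low-abundance ions).
Retention indices are drawn on 800–3600 with ≥ 2-unit spacing. CI spectra
carry the four-member series (members below the m/z 80 scan floor
dropped) plus up to three shared EI fragments.

The experiment layer plants log-normal areas (true means log-uniform
10⁴–10⁷, CV 15% by default), fold changes 3–8× up or down on a 20% planted
fraction, a linear injection-order drift (+30% across the run), pooled-QC
injections spread evenly through the sequence, media blanks carrying 15%
of compounds, and 1 ppm mass jitter. The unit-mass twin shares the latent
biology but its detection floor is raised by the sensitivity handicap
(default 8-fold, the concentration factor needed to equalize total ion
current between platform classes), so low-abundance compounds lose
fragments or disappear; its spectra are then nominal-mass rounded. Decoy
proposals swap compositions of equal nominal but different exact mass
(O↔NH₂, N↔CH₂, Si↔C₂H₄, S↔O₂), each > 5 ppm from the truth.

What it does **not** emulate: chromatographic peak shapes and
deconvolution artifacts, co-elution, isotopologue peaks within spectra,
realistic EI intensity distributions (intensities are generator
conventions; no acceptance check depends on their shape beyond cutoffs),
detector saturation, or retention-time drift. Passing tests therefore
demonstrate the correctness and calibration of the workflow's logic under
its stated assumptions, not instrument-level fidelity on real raw data.

## Problem sizes and determinism

Default runs use 60 compounds, 6+6 experimental samples, 5 QCs, 3 blanks —
sizes chosen so a full twin-platform run completes in seconds while every
stage still has non-trivial counts. The acceptance script uses 100 draws
for the decomposition-oracle comparison, the full ~70-formula curated
panel for rank-1 recovery, 50 compounds for decoy discrimination, 100
molecules for CI recovery, and 200 compounds for volcano calibration. All
randomness flows from integer-seeded numpy Generators; a fixed seed
reproduces every output byte-for-byte, and the full pipeline is a pure
function of (config, seed).

## Known limitations

- One fixed valence per element; no multivalent S/P/N compositions.
- The MeOX precondition uses O count, not carbonyl count.
- The dot-product weighting is not byte-identical to the commercial
  search program's undisclosed scheme; scores are comparable in rank, not
  in absolute value.
- Drift correction is a QC-interpolation scheme, not a re-implementation
  of any published correction package.
- The overlap cause taxonomy relies on shared compound identities across
  platforms, which real cross-instrument studies must first establish by
  matching.
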