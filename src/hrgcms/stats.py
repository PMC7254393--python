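"""Feature-table filtering, drift correction, univariate statistics and
the two-platform biomarker-overlap analysis.

The processing order mirrors standard untargeted GC-MS practice: pooled-QC
anchored signal-drift correction, QC relative-standard-deviation filter
(compounds with QC RSD > 20% excluded), media-blank filter (compounds in
blanks kept only with a >= 5-fold higher mean in at least one experimental
group), missing-value filter, log transform + autoscaling, Welch t-tests
with Benjamini-Hochberg FDR, volcano classification (|FC| > 2 and adjusted
p < 0.05), PCA, and cross-platform compound pairing + overlap accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .matching import dot_product_score
from .spectra import Spectrum

__all__ = [
    "CLASSES",
    "FeatureTable",
    "VolcanoResult",
    "OverlapReport",
    "drift_correct",
    "qc_rsd_filter",
    "blank_filter",
    "missing_value_filter",
    "impute_half_minimum",
    "transform",
    "volcano",
    "pca",
    "match_compounds_across_platforms",
    "overlap_percent",
    "platform_overlap",
]

CLASSES = ("control", "stress", "QC", "blank")


@dataclass
class FeatureTable:
    """Compound x sample peak-area matrix with sample annotations.

    ``areas``: DataFrame, rows = compound ids, columns = sample ids,
    values = peak areas (NaN = missing). ``samples``: DataFrame indexed by
    sample id with columns ``cls`` (control/stress/QC/blank) and ``order``
    (unique positive injection order).
    """

    areas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.areas.columns) <= set(self.samples.index):
            missing = set(self.areas.columns) - set(self.samples.index)
            raise ValueError(f"samples sheet lacks annotations for: {sorted(missing)}")
        bad = set(self.samples["cls"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        orders = self.samples["order"]
        if orders.duplicated().any() or (orders <= 0).any():
            raise ValueError("injection orders must be unique positive integers")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("peak areas must be non-negative")

    def columns_of(self, cls: str) -> list[str]:
        return [s for s in self.areas.columns if self.samples.loc[s, "cls"] == cls]

    @property
    def experimental_columns(self) -> list[str]:
        return [s for s in self.areas.columns if self.samples.loc[s, "cls"] in ("control", "stress")]

    def subset(self, compounds) -> "FeatureTable":
        return replace(self, areas=self.areas.loc[list(compounds)])

    # Delimited-text round trip -----------------------------------------
    def to_files(self, features_path, samples_path) -> None:
        out = self.areas.copy()
        out.index.name = "compound"
        out.to_csv(features_path, sep="\t")
        sheet = self.samples.copy()
        sheet.index.name = "sample"
        sheet.to_csv(samples_path, sep="\t")

    @classmethod
    def from_files(cls, features_path, samples_path) -> "FeatureTable":
        areas = pd.read_csv(features_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples["order"] = samples["order"].astype(int)
        return cls(areas=areas, samples=samples)


def drift_correct(table: FeatureTable) -> FeatureTable:
    """Remove injection-order signal drift using the pooled-QC injections.

    Per compound, areas are divided by a QC-anchored trend (linear
    interpolation of the QC areas over injection order, edge-extended
    flat) and rescaled to the compound's overall QC median. Compounds with
    fewer than two non-missing QC observations pass through untouched.
    """
    qc_cols = table.columns_of("QC")
    if len(qc_cols) < 3:
        raise ValueError("drift correction requires at least 3 QC injections")
    orders = table.samples["order"]
    qc_orders = np.array([orders[s] for s in qc_cols], dtype=float)
    qc_sort = np.argsort(qc_orders)
    qc_orders = qc_orders[qc_sort]
    qc_cols_sorted = [qc_cols[i] for i in qc_sort]
    all_orders = np.array([orders[s] for s in table.areas.columns], dtype=float)

    corrected = table.areas.copy().astype(float)
    for compound, row in table.areas.iterrows():
        qc_vals = row[qc_cols_sorted].to_numpy(dtype=float)
        ok = np.isfinite(qc_vals) & (qc_vals > 0)
        if ok.sum() < 2:
            continue
        trend = np.interp(all_orders, qc_orders[ok], qc_vals[ok])
        anchor = float(np.median(qc_vals[ok]))
        corrected.loc[compound] = row.to_numpy(dtype=float) / trend * anchor
    return replace(table, areas=corrected)


def _split(table: FeatureTable, keep_mask: pd.Series) -> tuple[FeatureTable, FeatureTable]:
    kept = table.areas.index[keep_mask]
    removed = table.areas.index[~keep_mask]
    return table.subset(kept), table.subset(removed)


def qc_rsd_filter(
    table: FeatureTable, threshold_pct: float = 20.0
) -> tuple[FeatureTable, FeatureTable]:
    """Exclude compounds whose QC relative standard deviation exceeds the
    threshold (RSD = 100 sd/mean over QC injections, sample sd). A
    compound whose RSD cannot be computed (fewer than two QC observations)
    is also excluded: its reproducibility is unverifiable. RSD exactly at
    the threshold is kept ('exceeding')."""
    qc = table.areas[table.columns_of("QC")].astype(float)
    n_obs = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    rsd = 100.0 * sd / mean
    keep = (n_obs >= 2) & (mean > 0) & (rsd <= threshold_pct)
    return _split(table, keep)


def blank_filter(table: FeatureTable, fold: float = 5.0) -> tuple[FeatureTable, FeatureTable]:
    """Exclude compounds present in media blanks unless at least one
    experimental group shows a >= ``fold`` higher mean peak area.
    Compounds absent from every blank are always kept."""
    blank_cols = table.columns_of("blank")
    if not blank_cols:
        raise ValueError("blank_filter requires blank samples")
    blank_mean = table.areas[blank_cols].fillna(0.0).mean(axis=1)
    ctrl = table.areas[table.columns_of("control")].fillna(0.0).mean(axis=1)
    strs = table.areas[table.columns_of("stress")].fillna(0.0).mean(axis=1)
    best_group = pd.concat([ctrl, strs], axis=1).max(axis=1)
    keep = (blank_mean <= 0) | (best_group >= fold * blank_mean)
    return _split(table, keep)


def missing_value_filter(
    table: FeatureTable, min_presence: float = 0.8
) -> tuple[FeatureTable, FeatureTable]:
    """Keep compounds observed (non-missing, > 0) in at least
    ``min_presence`` of the samples of at least one experimental group."""
    keep = pd.Series(False, index=table.areas.index)
    for cls in ("control", "stress"):
        cols = table.columns_of(cls)
        if not cols:
            continue
        present = (table.areas[cols].notna() & (table.areas[cols] > 0)).sum(axis=1)
        keep |= present / len(cols) >= min_presence
    return _split(table, keep)


def impute_half_minimum(areas: pd.DataFrame) -> pd.DataFrame:
    """Replace missing/zero areas by half the compound's minimum positive
    value (rows with no positive value are left as zeros)."""
    out = areas.copy().astype(float)
    for compound, row in out.iterrows():
        vals = row.to_numpy(dtype=float)
        positive = vals[np.isfinite(vals) & (vals > 0)]
        fill = positive.min() / 2.0 if positive.size else 0.0
        vals = np.where(np.isfinite(vals) & (vals > 0), vals, fill)
        out.loc[compound] = vals
    return out


def transform(table: FeatureTable) -> pd.DataFrame:
    """Log-transform and autoscale the experimental samples.

    Missing values are imputed as half the compound's minimum positive
    area, areas are natural-log transformed (heteroscedasticity), and each
    compound is centered and scaled to unit sample variance so that only
    relative concentration changes are compared. A zero-variance compound
    becomes an all-zero row (with a warning), not an error.
    """
    cols = table.experimental_columns
    if not cols:
        raise ValueError("no experimental samples to transform")
    imputed = impute_half_minimum(table.areas[cols])
    if (imputed.to_numpy() <= 0).any():
        warnings.warn("compounds with no positive areas are transformed to zero rows")
        imputed = imputed.where(imputed > 0)
    logged = np.log(imputed)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1)
    zero_var = ~(sd > 0)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance compounds scaled to all-zero rows")
        sd = sd.where(~zero_var, 1.0)
    scaled = centered.div(sd, axis=0).fillna(0.0)
    return scaled


@dataclass
class VolcanoResult:
    """Per-compound fold change, p-values and significance calls."""

    table: pd.DataFrame  # columns: fold_change, p_raw, p_adjusted, significant, direction
    fc_threshold: float
    alpha: float

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def volcano(
    table: FeatureTable,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> VolcanoResult:
    """Two-group dysregulation analysis.

    Fold change is the raw-scale stress/control mean ratio (half-minimum
    imputed); p-values come from two-sided Welch t-tests on natural-log
    areas, adjusted across compounds with Benjamini-Hochberg FDR. A
    compound is significantly dysregulated iff its fold change exceeds the
    threshold in either direction (FC > t or FC < 1/t, strict) and its
    adjusted p-value is below ``alpha`` (strict).
    """
    ctrl_cols = table.columns_of("control")
    strs_cols = table.columns_of("stress")
    if len(ctrl_cols) < 2 or len(strs_cols) < 2:
        raise ValueError("volcano requires >= 2 samples per experimental group")
    imputed = impute_half_minimum(table.areas[ctrl_cols + strs_cols])
    ctrl = imputed[ctrl_cols].to_numpy(dtype=float)
    strs = imputed[strs_cols].to_numpy(dtype=float)

    # Fold change on raw-scale group means of observed (positive) areas;
    # imputation is reserved for the log-scale test below. An absent
    # control group yields the +inf sentinel, which is still classifiable.
    def _raw_mean(cols: list[str]) -> np.ndarray:
        raw = table.areas[cols].to_numpy(dtype=float)
        raw = np.where(np.isfinite(raw) & (raw > 0), raw, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nan_to_num(np.nanmean(raw, axis=1), nan=0.0)

    ctrl_mean = _raw_mean(ctrl_cols)
    strs_mean = _raw_mean(strs_cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ctrl_mean > 0, strs_mean / ctrl_mean, np.inf)

    with np.errstate(divide="ignore"):
        log_ctrl = np.log(np.where(ctrl > 0, ctrl, np.nan))
        log_strs = np.log(np.where(strs > 0, strs, np.nan))
    p_raw = np.ones(len(imputed))
    for i in range(len(imputed)):
        a = log_strs[i][np.isfinite(log_strs[i])]
        b = log_ctrl[i][np.isfinite(log_ctrl[i])]
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            p_raw[i] = 1.0
            continue
        p_raw[i] = sps.ttest_ind(a, b, equal_var=False).pvalue
    p_raw = np.nan_to_num(p_raw, nan=1.0)
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if use_fdr else p_raw.copy()

    fc_pass = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    significant = fc_pass & (p_adj < alpha)
    direction = np.where(fc > 1.0, "up", "down")
    frame = pd.DataFrame(
        {
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": significant,
            "direction": direction,
        },
        index=imputed.index,
    )
    return VolcanoResult(table=frame, fc_threshold=fc_threshold, alpha=alpha)


def pca(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a transformed compound x sample matrix.

    Returns (scores: samples x components, explained variance fractions).
    The sign convention is fixed by making each component's
    largest-magnitude loading positive. ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x compounds
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = min(n_components, rank, min(X.shape))
    if k < n_components:
        warnings.warn(f"n_components truncated from {n_components} to rank {k}")
    model = PCA(n_components=k)
    scores = model.fit_transform(X)
    for j in range(k):
        i_max = int(np.argmax(np.abs(model.components_[j])))
        if model.components_[j, i_max] < 0:
            model.components_[j] *= -1.0
            scores[:, j] *= -1.0
    frame = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return frame, model.explained_variance_ratio_


def match_compounds_across_platforms(
    compounds_a: dict[str, Spectrum],
    compounds_b: dict[str, Spectrum],
    ri_tol: float = 5.0,
    spectral_min: float = 700.0,
    mz_power: float = 0.0,
    intensity_power: float = 0.5,
) -> list[tuple[str, str, float]]:
    """Pair compounds of two platforms by unit-mass spectral similarity.

    Candidates must agree in retention index within ``ri_tol`` and score
    at least ``spectral_min``; pairs are assigned greedily best-first so
    each compound joins at most one pair. Spectra must be unit-resolution
    (accurate spectra are degraded by the caller first).
    """
    candidates: list[tuple[float, str, str]] = []
    for id_a, spec_a in compounds_a.items():
        if spec_a.retention_index is None:
            raise ValueError(f"compound {id_a!r} lacks a retention index")
        for id_b, spec_b in compounds_b.items():
            if spec_b.retention_index is None:
                raise ValueError(f"compound {id_b!r} lacks a retention index")
            if abs(spec_a.retention_index - spec_b.retention_index) > ri_tol:
                continue
            score = dot_product_score(spec_a, spec_b, mz_power, intensity_power)
            if score >= spectral_min:
                candidates.append((score, id_a, id_b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    for score, id_a, id_b in candidates:
        if id_a in used_a or id_b in used_b:
            continue
        pairs.append((id_a, id_b, score))
        used_a.add(id_a)
        used_b.add(id_b)
    return pairs


def overlap_percent(shared: int, unique_a: int, unique_b: int) -> int:
    """Overlap of two significant-compound sets as a percentage of their
    union, rounded to the nearest integer."""
    total = shared + unique_a + unique_b
    if total == 0:
        raise ValueError("no significant compounds on either platform")
    return int(round(100.0 * shared / total))


@dataclass
class OverlapReport:
    """Cross-platform biomarker-overlap accounting."""

    shared: int
    unique_a: int
    unique_b: int
    percent: int
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)
    causes_a: dict[str, str] = field(default_factory=dict)  # A-significant, missing from B
    causes_b: dict[str, str] = field(default_factory=dict)  # B-significant, missing from A


def _cause(
    compound: str,
    paired_other: str | None,
    other_significant: set[str],
    other_present: set[str],
    other_blank_removed: set[str],
) -> str:
    # With twin datasets compound ids are shared across platforms, so the
    # id itself can be checked against the other platform's bookkeeping.
    if paired_other is not None and paired_other in other_present:
        return "threshold-fail"
    if compound in other_blank_removed:
        return "blank-excluded"
    if compound in other_present and compound not in other_significant:
        return "threshold-fail"
    if compound not in other_present:
        return "below-LOD"
    return "unmatched"


def platform_overlap(
    significant_a: set[str],
    significant_b: set[str],
    pairing: list[tuple[str, str, float]] | list[tuple[str, str]],
    present_a: set[str],
    present_b: set[str],
    blank_removed_a: set[str] = frozenset(),
    blank_removed_b: set[str] = frozenset(),
) -> OverlapReport:
    """Count shared and platform-unique significant compounds.

    ``pairing`` maps compounds across platforms; a compound pair counts as
    shared when both sides are significant. The overlap percentage uses
    the union of significant compounds as denominator. Every significant
    compound missed by the other platform gets a cause code: below-LOD
    (absent from the other platform's table), threshold-fail (present but
    FC/p short of the cutoffs), blank-excluded, or unmatched.
    """
    a_to_b = {p[0]: p[1] for p in pairing}
    b_to_a = {p[1]: p[0] for p in pairing}
    shared_pairs = [
        (a, a_to_b[a]) for a in sorted(significant_a)
        if a in a_to_b and a_to_b[a] in significant_b
    ]
    shared = len(shared_pairs)
    unique_a = sorted(significant_a - {a for a, _ in shared_pairs})
    unique_b = sorted(significant_b - {b for _, b in shared_pairs})
    causes_a = {
        a: _cause(a, a_to_b.get(a), significant_b, present_b, set(blank_removed_b))
        for a in unique_a
    }
    causes_b = {
        b: _cause(b, b_to_a.get(b), significant_a, present_a, set(blank_removed_a))
        for b in unique_b
    }
    return OverlapReport(
        shared=shared,
        unique_a=len(unique_a),
        unique_b=len(unique_b),
        percent=overlap_percent(shared, len(unique_a), len(unique_b)),
        shared_pairs=shared_pairs,
        causes_a=causes_a,
        causes_b=causes_b,
    )
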