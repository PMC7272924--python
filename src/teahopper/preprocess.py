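"""Preprocessing of raw metabolite peak tables and plate-assay readings.

Turns GC-MS-like peak-area tables into analysis-ready matrices through a
fixed sequence of steps: internal-standard normalisation (relative peak
areas), field-blank subtraction with a detection floor, prevalence
filtering, natural-log transform, multivariate outlier flagging, and
autoscaling (per-compound standardisation). Also provides the
Folin-Ciocalteau gallic-acid-equivalent curve inversion and the
triplicate coefficient-of-variation check used for the total-phenolics
assay.

The pipeline order is fixed::

    rpa -> blank_correct -> prevalence_filter -> ln_transform
        -> flag_multivariate_outliers -> autoscale

and each stage records the row/column counts it saw in a log carried on
the returned objects.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import expon

__all__ = [
    "PeakTable",
    "MetaboliteMatrix",
    "AssayResult",
    "compute_rpa",
    "blank_correct",
    "prevalence_filter",
    "ln_transform",
    "flag_multivariate_outliers",
    "autoscale",
    "folin_gae",
    "cv_check",
    "preprocess_peak_table",
]

#: reserved column name for the internal standard in wide CSV layouts
IS_COLUMN = "IS"
#: reserved sample id for the field blank row
BLANK_ID = "BLANK"


@dataclass
class PeakTable:
    """Raw sample x compound peak areas with internal standard and blank.

    ``areas`` is a samples x compounds DataFrame of detector counts
    (non-negative); ``is_area`` holds the internal-standard peak area per
    sample (positive); ``blank_id`` names the row of ``areas`` that is the
    field blank (or ``None`` if no blank was collected).
    """

    areas: pd.DataFrame
    is_area: pd.Series
    blank_id: str | None = BLANK_ID

    def __post_init__(self) -> None:
        if (self.areas.values < 0).any():
            raise ValueError("peak areas must be non-negative")
        if not self.areas.index.equals(self.is_area.index):
            raise ValueError("areas and is_area must share the sample index")
        if self.blank_id is not None and self.blank_id not in self.areas.index:
            raise ValueError(f"blank row {self.blank_id!r} not present")

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "PeakTable":
        """Read a wide CSV (first column sample id, reserved ``IS`` column,
        reserved ``BLANK`` sample id)."""
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        if IS_COLUMN not in df.columns:
            raise ValueError(f"peak table is missing the {IS_COLUMN!r} column")
        is_area = df[IS_COLUMN]
        areas = df.drop(columns=[IS_COLUMN])
        blank = BLANK_ID if BLANK_ID in df.index else None
        return cls(areas=areas, is_area=is_area, blank_id=blank)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.areas.copy()
        out.insert(0, IS_COLUMN, self.is_area)
        out.to_csv(path, sep=sep, index_label="sample")


@dataclass
class MetaboliteMatrix:
    """Sample x compound value matrix with an explicit scale tag.

    ``scale`` is one of ``rpa`` (internal-standard-normalised peak areas),
    ``ln`` (natural-log RPA), ``autoscaled`` (zero mean, unit sd per
    compound) or ``concentration`` (e.g. mg/g).  ``log`` accumulates a
    human-readable record of what each preprocessing stage did.
    """

    values: pd.DataFrame
    scale: str
    log: list[str] = field(default_factory=list)

    _SCALES = ("rpa", "ln", "autoscaled", "concentration")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("metabolite matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    def _derive(self, values: pd.DataFrame, scale: str, note: str) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            values=values,
            scale=scale,
            log=self.log + [f"{note} [{values.shape[0]} samples x {values.shape[1]} compounds]"],
        )

    @classmethod
    def from_csv(cls, path, scale: str, sep: str = ",") -> "MetaboliteMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        return cls(values=df, scale=scale)

    def to_csv(self, path, sep: str = ",") -> None:
        self.values.to_csv(path, sep=sep, index_label="sample")


@dataclass
class AssayResult:
    """One sample's plate-assay outcome in gallic acid equivalents."""

    sample_id: str
    gae_mg_per_g: float
    cv: float
    qc_flag: bool  # True when CV >= 0.20

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("CV must be non-negative")


def compute_rpa(peaks: PeakTable) -> MetaboliteMatrix:
    """Relative peak areas: each compound's area divided by the
    internal-standard area of the same sample.

    Raises :class:`ValueError` naming the offending sample when an
    internal-standard area is missing or non-positive.
    """
    bad = peaks.is_area.index[~(peaks.is_area > 0) | peaks.is_area.isna()]
    if len(bad):
        raise ValueError(f"non-positive or missing internal standard for sample(s): {list(bad)}")
    values = peaks.areas.div(peaks.is_area, axis=0)
    m = MetaboliteMatrix(values=values, scale="rpa")
    m.log.append(
        f"compute_rpa [{values.shape[0]} samples x {values.shape[1]} compounds]"
    )
    return m


def blank_correct(
    rpa: MetaboliteMatrix,
    blank: pd.Series | None = None,
    is_area: pd.Series | None = None,
    blank_id: str | None = BLANK_ID,
) -> MetaboliteMatrix:
    """Subtract the field blank's RPA and floor non-detections at 100/IS.

    Any corrected value <= 0 (a compound absent relative to the blank) is
    replaced by 100/IS of that sample — a detection-limit placeholder that
    keeps the subsequent log transform defined.  The blank row itself is
    dropped from the output.  If multiple blank rows are supplied via
    ``blank`` they should already be averaged; when ``blank`` is None the
    row named ``blank_id`` is used (zero correction if absent).
    """
    if rpa.scale != "rpa":
        raise ValueError("blank_correct expects an RPA-scale matrix")
    if is_area is None:
        raise ValueError("is_area (per-sample internal-standard areas) is required for the floor")
    values = rpa.values
    if blank is None:
        if blank_id is not None and blank_id in values.index:
            blank = values.loc[blank_id]
            values = values.drop(index=blank_id)
        else:
            blank = pd.Series(0.0, index=values.columns)
    elif blank_id is not None and blank_id in values.index:
        values = values.drop(index=blank_id)
    corrected = values.sub(blank, axis=1)
    floor = (100.0 / is_area.reindex(corrected.index)).astype(float)
    floored = corrected.where(corrected > 0, other=np.nan)
    floored = floored.apply(lambda col: col.fillna(floor))
    out = rpa._derive(floored, "rpa", "blank_correct (floor 100/IS)")
    return out


def prevalence_filter(
    m: MetaboliteMatrix,
    floor_value: pd.Series | float,
    min_detected: int = 6,
) -> MetaboliteMatrix:
    """Drop compounds detected in fewer than ``min_detected`` samples.

    "Detected" means strictly above the 100/IS floor for that sample, i.e.
    not a floor replacement.  With the default ``min_detected=6`` compounds
    seen in 5 or fewer samples are excluded.
    """
    if np.isscalar(floor_value):
        floor = pd.Series(float(floor_value), index=m.values.index)
    else:
        floor = pd.Series(floor_value).reindex(m.values.index)
    detected = m.values.gt(floor, axis=0)
    counts = detected.sum(axis=0)
    keep = counts[counts >= min_detected].index
    out = m._derive(
        m.values[keep],
        m.scale,
        f"prevalence_filter (kept {len(keep)}/{m.n_compounds} compounds detected in >= {min_detected} samples)",
    )
    out.log.append("detection counts: " + ", ".join(f"{c}={counts[c]}" for c in m.values.columns))
    return out


def ln_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Elementwise natural log; requires strictly positive input (which the
    100/IS floor guarantees for RPA data)."""
    if (m.values.values <= 0).any():
        bad = m.values.columns[(m.values <= 0).any(axis=0)]
        raise ValueError(f"ln_transform requires positive values; offending compound(s): {list(bad)}")
    return m._derive(np.log(m.values), "ln", "ln_transform")


def flag_multivariate_outliers(
    m: MetaboliteMatrix, alpha: float = 0.05
) -> tuple[pd.Series, pd.Series]:
    """Nearest-neighbour-distance multivariate outlier flags.

    Columns are standardised, each sample's Euclidean nearest-neighbour
    distance is computed, and an exponential is fitted to the gaps between
    consecutive sorted distances in the upper half.  Scanning the upper-half
    gaps from small to large distances, the first gap exceeding the
    ``1 - alpha`` quantile of the fitted exponential marks a break: every
    sample whose distance lies beyond the break is flagged.

    Returns ``(flags, distances)`` indexed by sample.  Requires at least 5
    samples.
    """
    n = m.n_samples
    if n < 5:
        raise ValueError(f"outlier detection needs >= 5 samples, got {n}")
    X = m.values.values.astype(float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    order = np.argsort(nn)
    d_sorted = nn[order]
    gaps = np.diff(d_sorted)
    start = n // 2  # upper half of the sorted distances
    upper_gaps = gaps[start - 1:]
    flags = np.zeros(n, dtype=bool)
    if upper_gaps.size and upper_gaps.mean() > 0:
        # MLE exponential fit to the upper-tail gaps; the (1 - alpha) tail
        # quantile is Bonferroni-adjusted for the number of gaps examined so
        # the chance of flagging anything in clean data stays near alpha
        threshold = expon.ppf(1 - alpha / upper_gaps.size, scale=upper_gaps.mean())
        exceed = np.nonzero(upper_gaps > threshold)[0]
        if exceed.size:
            cut = start - 1 + exceed[0]  # gap between d_sorted[cut] and [cut+1]
            flags[order[cut + 1:]] = True
    return (
        pd.Series(flags, index=m.values.index, name="outlier"),
        pd.Series(nn, index=m.values.index, name="nn_distance"),
    )


def autoscale(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Per-compound centring and unit-variance scaling (sample sd, n-1)."""
    sd = m.values.std(axis=0, ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise ValueError(f"zero-variance compound(s) cannot be autoscaled: {list(zero)}")
    scaled = (m.values - m.values.mean(axis=0)) / sd
    return m._derive(scaled, "autoscaled", "autoscale")


def preprocess_peak_table(
    peaks: PeakTable,
    alpha_outlier: float = 0.05,
    min_detected: int = 6,
    remove_outliers: bool = True,
) -> tuple[MetaboliteMatrix, MetaboliteMatrix, pd.Series]:
    """Full fixed-order preprocessing of a raw peak table.

    Returns ``(ln_matrix, autoscaled_matrix, outlier_flags)``.  Outliers are
    flagged here and removed (when ``remove_outliers``) before the final
    autoscaling, so the removal is auditable in the log.
    """
    rpa = compute_rpa(peaks)
    is_samples = peaks.is_area.drop(index=peaks.blank_id) if peaks.blank_id else peaks.is_area
    corrected = blank_correct(rpa, is_area=is_samples, blank_id=peaks.blank_id)
    floor = 100.0 / is_samples
    filtered = prevalence_filter(corrected, floor_value=floor, min_detected=min_detected)
    assert (filtered.values.values > 0).all(), "post-floor values must be strictly positive"
    ln_m = ln_transform(filtered)
    # a compound with zero variance carries no multivariate information and
    # cannot be autoscaled; keep it out of the scaled matrix (logged)
    sd = ln_m.values.std(axis=0, ddof=1)
    if (~(sd > 0)).any():
        const = list(sd.index[~(sd > 0)])
        ln_scaled_src = ln_m._derive(
            ln_m.values.drop(columns=const), "ln",
            f"dropped {len(const)} constant compound(s) before autoscaling: {const}",
        )
    else:
        ln_scaled_src = ln_m
    flags, _ = flag_multivariate_outliers(ln_scaled_src, alpha=alpha_outlier)
    if remove_outliers and flags.any():
        ln_m = ln_m._derive(
            ln_m.values.loc[~flags], "ln",
            f"removed {int(flags.sum())} multivariate outlier(s): {list(flags.index[flags])}",
        )
        ln_scaled_src = ln_scaled_src._derive(
            ln_scaled_src.values.loc[~flags], "ln",
            f"removed {int(flags.sum())} multivariate outlier(s): {list(flags.index[flags])}",
        )
    else:
        ln_m.log.append(
            f"flagged {int(flags.sum())} multivariate outlier(s); none removed"
            if not remove_outliers
            else "no multivariate outliers flagged"
        )
    scaled = autoscale(ln_scaled_src)
    return ln_m, scaled, flags


def folin_gae(
    absorbances: Sequence[float],
    standards: Sequence[tuple[float, float]],
    sample_id: str = "sample",
    dilution_factor: float = 1.0,
    extract_volume_ml: float = 1.0,
    mass_g: float = 1.0,
    max_cv: float = 0.20,
) -> AssayResult:
    """Invert a gallic-acid standard curve to a mg/g GAE concentration.

    ``standards`` are (concentration mg/ml, absorbance) pairs; an ordinary
    least-squares line is fitted and each triplicate absorbance mapped back
    to mg/ml, then converted to mg per g dry leaf via
    ``conc * dilution_factor * extract_volume_ml / mass_g``.
    """
    standards = list(standards)
    if len(standards) < 3:
        raise ValueError("need at least 3 standards for the curve")
    conc = np.array([s[0] for s in standards], dtype=float)
    absb = np.array([s[1] for s in standards], dtype=float)
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")
    slope, intercept = np.polyfit(conc, absb, 1)
    if slope <= 0:
        raise ValueError(f"invalid standard curve: slope {slope:.4g} <= 0")
    trip = np.asarray(absorbances, dtype=float)
    conc_mgml = (trip - intercept) / slope
    mg_per_g = conc_mgml * dilution_factor * extract_volume_ml / mass_g
    mean, flag, cv = _cv(mg_per_g, max_cv)
    return AssayResult(sample_id=sample_id, gae_mg_per_g=mean, cv=cv, qc_flag=flag)


def _cv(values: np.ndarray, max_cv: float) -> tuple[float, bool, float]:
    if values.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(values.mean())
    if mean == 0:
        raise ValueError("mean of replicates is zero; CV undefined")
    cv = float(values.std(ddof=1) / abs(mean))
    return mean, cv >= max_cv, cv


def cv_check(triplicates: Sequence[float], max_cv: float = 0.20) -> tuple[float, bool]:
    """Mean of replicates plus a QC flag set when CV = sd/|mean| >= max_cv."""
    mean, flag, _ = _cv(np.asarray(triplicates, dtype=float), max_cv)
    return mean, flag
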