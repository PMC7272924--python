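"""Synthetic herbivory experiment generator with known ground truth.

Emulates a potted-plant leafhopper density experiment: ~19 pots assigned
nominal densities of 0-2 insects per young leaf, visible leaf damage that
stays near a baseline until a density threshold (~0.6 insects/young leaf)
and then rises, and per-compound metabolite responses on the natural-log
scale drawn from four canonical dose-response shapes:

* ``null``   — no response, constant mean
* ``linear`` — mean changes proportionally to density
* ``step``   — flat on both sides of a change point, with a jump
* ``hinge``  — flat below the change point, linear above it

Every generated object carries a truth record so downstream stages
(preprocessing, ordination, shape classification) can be tested for
recovery of known parameters.  The generator also inverts the
preprocessing: :func:`simulate_peak_table` turns a ln-scale matrix back
into raw peak areas with an internal-standard column and a field-blank
row, so the preprocessing chain can be round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk, ellipse

from .preprocess import BLANK_ID, MetaboliteMatrix, PeakTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "LabeledImage",
    "simulate_herbivory",
    "simulate_metabolites",
    "simulate_concentrations",
    "simulate_peak_table",
    "simulate_leaf_image",
]

SHAPES = ("null", "linear", "step", "hinge")

#: mask codes shared with the damage module
BACKGROUND, UNDAMAGED, DAMAGED = 0, 1, 2


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for the synthetic experiment.

    Defaults emulate the experimental design this package targets: 19 pots
    over nominal density treatments 0/0.5/1/1.5/2 insects per young leaf
    with +-0.25 jitter (final densities deviate from nominal because
    insects die or hatch during the run), leaf damage following a hinge on
    the ln scale with threshold 0.6 insects/young leaf, and 35
    volatile-like compounds split 12 step / 11 linear / 12 null.
    """

    n_pots: int = 19
    density_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    density_jitter: float = 0.25  # uniform +-jitter, truncated at 0; 0 disables

    # ln(damage %) = ln(damage_baseline) + damage_slope * max(0, d - tau) + noise
    damage_threshold: float = 0.6
    damage_baseline: float = 2.0  # % leaf area below threshold
    damage_slope: float = 1.2  # per insect/young leaf, ln scale
    damage_sigma: float = 0.35  # ln units
    focal_correlation: float = 0.71  # target Pearson r, mean vs focal damage

    # compound counts per true shape
    n_step: int = 12
    n_linear: int = 11
    n_hinge: int = 0
    n_null: int = 12

    # parameter ranges (drawn uniformly)
    slope_range: tuple[float, float] = (1.5, 4.0)  # linear/hinge slope, ln units per insect/leaf
    delta_intercept_range: tuple[float, float] = (1.6, 7.2)  # step jump, ln units
    changepoint_range: tuple[float, float] = (0.25, 0.77)  # insects/young leaf
    intercept_range: tuple[float, float] = (-3.0, 1.0)  # baseline ln RPA
    noise_sigma: float = 0.5  # per-compound ln-scale sd

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pots < 4:
            raise ValueError("n_pots must be >= 4")
        if self.damage_baseline <= 0:
            raise ValueError("damage_baseline must be positive (ln-damage must be defined)")
        if self.damage_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise sd must be non-negative")
        if any(d < 0 for d in self.density_levels):
            raise ValueError("densities must be non-negative")
        lo, hi = min(self.density_levels), max(self.density_levels)
        if not (lo < self.damage_threshold < hi):
            raise ValueError(
                f"damage_threshold {self.damage_threshold} must lie strictly inside "
                f"the density range ({lo}, {hi})"
            )
        c_lo, c_hi = self.changepoint_range
        if not (lo < c_lo <= c_hi < hi):
            raise ValueError("changepoint_range must lie strictly inside the density range")

    @property
    def n_compounds(self) -> int:
        return self.n_step + self.n_linear + self.n_hinge + self.n_null


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    ``compounds`` has one row per compound: shape, intercept ``alpha``,
    ``slope`` (linear/hinge), ``delta_intercept`` (step), ``changepoint``
    (step/hinge) and noise ``sigma``.  ``pots`` has the noiseless expected
    percent damage per pot.
    """

    compounds: pd.DataFrame = field(default_factory=pd.DataFrame)
    pots: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class LabeledImage:
    """An RGB leaf image and its ground-truth pixel-class mask
    (0=background, 1=undamaged, 2=damaged)."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, uint8

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


def _final_densities(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    levels = np.asarray(config.density_levels, dtype=float)
    nominal = np.tile(levels, int(np.ceil(config.n_pots / levels.size)))[: config.n_pots]
    if config.density_jitter > 0:
        jit = rng.uniform(-config.density_jitter, config.density_jitter, size=config.n_pots)
        return np.clip(nominal + jit, 0.0, None)
    return nominal


def _solve_focal_sigma(m: np.ndarray, target_r: float) -> float:
    """Sd of multiplicative lognormal noise giving expected Pearson r
    ``target_r`` between ``m`` and ``m * exp(eta)`` for the realised sample.

    Uses the closed form of the correlation for independent
    ``eta ~ N(0, s^2)`` with the sample moments of ``m``:
    ``corr(s) = e^{s^2/2} Var(m) / sqrt(Var(m) (e^{2 s^2} E[m^2] - e^{s^2} E[m]^2))``.
    """
    var_m = float(np.var(m))
    if var_m == 0 or target_r >= 1.0:
        return 0.0
    e1, e2 = float(np.mean(m)), float(np.mean(m**2))

    def corr(s: float) -> float:
        v = np.exp(2 * s * s) * e2 - np.exp(s * s) * e1 * e1
        return np.exp(s * s / 2) * var_m / np.sqrt(var_m * v)

    f = lambda s: corr(s) - target_r
    hi = 1.0
    while f(hi) > 0 and hi < 64:
        hi *= 2
    if f(hi) > 0:  # target unreachably low; cap the noise
        return hi
    return float(brentq(f, 1e-12, hi))


def simulate_herbivory(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate per-pot herbivory predictors.

    Returns a DataFrame indexed by pot id with columns ``density``
    (insects/young leaf), ``mean_damage_pct`` and ``focal_damage_pct``
    (% leaf area), plus a :class:`SyntheticTruth` whose ``pots`` table
    carries the noiseless expected damage.  Mean damage follows
    ``ln(D) = ln(baseline) + slope * max(0, density - tau) + eps`` and
    focal-leaf damage is mean damage times lognormal noise calibrated so
    the expected Pearson correlation between the two equals
    ``config.focal_correlation``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d = _final_densities(config, rng)
    hinge = np.maximum(0.0, d - config.damage_threshold)
    ln_expected = np.log(config.damage_baseline) + config.damage_slope * hinge
    ln_mean = ln_expected + rng.normal(0.0, config.damage_sigma, size=config.n_pots)
    mean_damage = np.exp(ln_mean)
    s_eta = _solve_focal_sigma(mean_damage, config.focal_correlation)
    focal = mean_damage * np.exp(rng.normal(0.0, s_eta, size=config.n_pots))
    pots = [f"pot{i + 1:02d}" for i in range(config.n_pots)]
    predictors = pd.DataFrame(
        {"density": d, "mean_damage_pct": mean_damage, "focal_damage_pct": focal},
        index=pd.Index(pots, name="pot_id"),
    )
    truth = SyntheticTruth(
        pots=pd.DataFrame(
            {"density": d, "expected_damage_pct": np.exp(ln_expected)},
            index=predictors.index,
        )
    )
    return predictors, truth


def _shape_mean(shape: str, x: np.ndarray, alpha: float, beta: float, delta: float, e: float) -> np.ndarray:
    if shape == "null":
        return np.full_like(x, alpha, dtype=float)
    if shape == "linear":
        return alpha + beta * x
    if shape == "step":
        return alpha + delta * (x > e)
    if shape == "hinge":
        return alpha + beta * np.maximum(0.0, x - e)
    raise ValueError(f"unknown shape {shape!r}; expected one of {SHAPES}")


def _draw_compounds(
    config: SyntheticConfig, rng: np.random.Generator, prefix: str = "C"
) -> pd.DataFrame:
    rows = []
    shapes = (
        ["step"] * config.n_step
        + ["linear"] * config.n_linear
        + ["hinge"] * config.n_hinge
        + ["null"] * config.n_null
    )
    for j, shape in enumerate(shapes):
        alpha = rng.uniform(*config.intercept_range)
        beta = rng.uniform(*config.slope_range) if shape in ("linear", "hinge") else np.nan
        delta = rng.uniform(*config.delta_intercept_range) if shape == "step" else np.nan
        e = rng.uniform(*config.changepoint_range) if shape in ("step", "hinge") else np.nan
        rows.append((f"{prefix}{j + 1:03d}", shape, alpha, beta, delta, e, config.noise_sigma))
    return pd.DataFrame(
        rows,
        columns=["compound", "shape", "alpha", "slope", "delta_intercept", "changepoint", "sigma"],
    ).set_index("compound")


def simulate_metabolites(
    predictors: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    x_column: str = "density",
    compound_prefix: str = "C",
) -> tuple[MetaboliteMatrix, SyntheticTruth]:
    """Generate a ln-scale sample x compound matrix responding to a predictor.

    Per compound j the ln-value is ``alpha_j + f_j(x) + eps`` with
    ``f`` one of the four canonical shapes and ``eps ~ N(0, sigma_j^2)``.
    """
    if predictors.empty:
        raise ValueError("predictors must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    x = predictors[x_column].to_numpy(dtype=float)
    truth = _draw_compounds(config, rng, prefix=compound_prefix)
    cols = {}
    for cid, row in truth.iterrows():
        mean = _shape_mean(row["shape"], x, row["alpha"], row["slope"], row["delta_intercept"], row["changepoint"])
        cols[cid] = mean + rng.normal(0.0, row["sigma"], size=x.size)
    values = pd.DataFrame(cols, index=predictors.index)
    m = MetaboliteMatrix(values=values, scale="ln")
    m.log.append(f"simulate_metabolites on {x_column} [{values.shape[0]} x {values.shape[1]}]")
    return m, SyntheticTruth(compounds=truth)


def simulate_concentrations(
    predictors: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    x_column: str = "mean_damage_pct",
    log_predictor: bool = True,
    compound_prefix: str = "NV",
) -> tuple[MetaboliteMatrix, SyntheticTruth]:
    """LC-MS-like concentration table: same shape machinery, but the mean
    function applies directly on the concentration scale (mg/g-like units)
    so univariate fits on concentrations have a well-defined truth.  The
    predictor is ln-transformed by default, matching how percent damage is
    analysed."""
    if predictors.empty:
        raise ValueError("predictors must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    x = predictors[x_column].to_numpy(dtype=float)
    if log_predictor:
        if (x <= 0).any():
            raise ValueError("log_predictor requires positive predictor values")
        x = np.log(x)
    truth = _draw_compounds(config, rng, prefix=compound_prefix)
    cols = {}
    for cid, row in truth.iterrows():
        mean = _shape_mean(row["shape"], x, row["alpha"], row["slope"], row["delta_intercept"], row["changepoint"])
        cols[cid] = mean + rng.normal(0.0, row["sigma"], size=x.size)
    values = pd.DataFrame(cols, index=predictors.index)
    m = MetaboliteMatrix(values=values, scale="concentration")
    m.log.append(f"simulate_concentrations on {'ln ' if log_predictor else ''}{x_column} [{values.shape[0]} x {values.shape[1]}]")
    return m, SyntheticTruth(compounds=truth)


def simulate_peak_table(
    metabolites: MetaboliteMatrix,
    is_area: float = 1e6,
    blank_profile: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """Invert preprocessing: raw peak area = exp(ln value) * IS plus the
    blank contribution, with one field-blank row and the internal-standard
    column, so ``preprocess`` recovers the input ln matrix for compounds
    untouched by the floor and prevalence rules."""
    if metabolites.scale != "ln":
        raise ValueError("simulate_peak_table expects a ln-scale matrix")
    if is_area <= 0:
        raise ValueError("is_area must be positive")
    if blank_profile is None:
        blank_profile = pd.Series(0.0, index=metabolites.values.columns)
    blank_profile = blank_profile.reindex(metabolites.values.columns).fillna(0.0)
    areas = (np.exp(metabolites.values) + blank_profile) * is_area
    blank_row = (blank_profile * is_area).rename(BLANK_ID)
    areas = pd.concat([areas, blank_row.to_frame().T])
    areas.index.name = "sample"
    is_series = pd.Series(is_area, index=areas.index, name="IS")
    return PeakTable(areas=areas, is_area=is_series, blank_id=BLANK_ID)


def simulate_leaf_image(
    width: int,
    height: int,
    damage_fraction: float,
    leaf_color: tuple[int, int, int] = (60, 130, 45),
    damage_color: tuple[int, int, int] = (125, 85, 35),
    background_color: tuple[int, int, int] = (235, 235, 235),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LabeledImage:
    """Render an elliptical "leaf" with connected damaged blobs covering
    ``damage_fraction`` of leaf pixels, plus the ground-truth class mask.

    Blobs are random disks clipped to the leaf; the final disk is trimmed
    pixel-by-pixel so the damaged count hits ``round(fraction * leaf
    pixels)`` exactly.  ``noise_sd`` adds i.i.d. Gaussian colour noise (in
    0-255 units).
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    if not (0.0 <= damage_fraction <= 1.0):
        raise ValueError("damage_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=np.uint8)
    rr, cc = ellipse(height / 2, width / 2, height * 0.42, width * 0.42, shape=mask.shape)
    mask[rr, cc] = UNDAMAGED
    leaf_px = int((mask == UNDAMAGED).sum())
    target = int(round(damage_fraction * leaf_px))
    max_r = max(3, min(width, height) // 40)
    damaged = 0
    guard = 0
    while damaged < target and guard < 100_000:
        guard += 1
        i = rng.integers(0, height)
        j = rng.integers(0, width)
        if mask[i, j] == BACKGROUND:
            continue
        r = int(rng.integers(2, max_r + 1))
        di, dj = disk((i, j), r, shape=mask.shape)
        new = (mask[di, dj] == UNDAMAGED)
        need = target - damaged
        if new.sum() <= need:
            mask[di[new], dj[new]] = DAMAGED
            damaged += int(new.sum())
        else:
            # trim the last blob: take the pixels closest to its centre
            order = np.argsort((di[new] - i) ** 2 + (dj[new] - j) ** 2)[:need]
            mask[di[new][order], dj[new][order]] = DAMAGED
            damaged += need
    img = np.empty((height, width, 3), dtype=float)
    for code, color in ((BACKGROUND, background_color), (UNDAMAGED, leaf_color), (DAMAGED, damage_color)):
        img[mask == code] = color
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledImage(image=img, mask=mask)
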