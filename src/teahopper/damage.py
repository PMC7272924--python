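"""Percent damaged leaf area from classified pixel masks.

Masks use three classes: 0 = background, 1 = undamaged leaf,
2 = damaged leaf.  Percent damage is damaged / (damaged + undamaged);
background pixels never enter the ratio, so manually excluded regions
(petioles, shadows) are simply labelled background.  Classifier
agreement against a reference labelling is measured with Cohen's kappa
over the 3-class confusion matrix.

Pixel classification itself is a deliberately transparent
nearest-centroid colour classifier under Mahalanobis distance: class
statistics (mean and covariance of example pixels per class) are
estimated from labelled training regions and each pixel is assigned the
closest class, optionally after Gaussian smoothing of the image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage.filters import gaussian

from .synthetic import BACKGROUND, DAMAGED, UNDAMAGED

__all__ = [
    "fit_class_statistics",
    "classify_pixels",
    "percent_damage",
    "pot_mean_damage",
    "cohens_kappa",
]

logger = logging.getLogger(__name__)

CLASSES = (BACKGROUND, UNDAMAGED, DAMAGED)


def fit_class_statistics(
    image: np.ndarray, mask: np.ndarray, classes: tuple[int, ...] = CLASSES
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-class (mean, covariance) of pixel colours from a labelled image.

    A small ridge is added to each covariance so noiseless training
    regions (zero variance) still yield an invertible matrix.
    """
    stats: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    px = image.reshape(-1, image.shape[-1]).astype(float)
    lab = mask.reshape(-1)
    for c in classes:
        sel = px[lab == c]
        if sel.size == 0:
            raise ValueError(f"no training pixels for class {c}")
        mu = sel.mean(axis=0)
        cov = np.cov(sel, rowvar=False) if sel.shape[0] > 1 else np.zeros((px.shape[1],) * 2)
        cov = np.atleast_2d(cov) + np.eye(px.shape[1]) * 1e-3
        stats[c] = (mu, cov)
    return stats


def classify_pixels(
    image: np.ndarray,
    class_stats: dict[int, tuple[np.ndarray, np.ndarray]],
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Assign each pixel to the nearest class under Mahalanobis distance.

    ``class_stats`` maps class code -> (mean colour, colour covariance),
    e.g. from :func:`fit_class_statistics`.  ``smooth_sigma`` > 0 applies
    channel-wise Gaussian smoothing before classification.  Deterministic
    given its inputs.
    """
    missing = [c for c in CLASSES if c not in class_stats]
    if missing:
        raise ValueError(f"missing class statistics for class(es) {missing}")
    img = image.astype(float)
    if smooth_sigma > 0:
        img = gaussian(img, sigma=smooth_sigma, channel_axis=-1, preserve_range=True)
    px = img.reshape(-1, img.shape[-1])
    codes = sorted(class_stats)
    d2 = np.empty((px.shape[0], len(codes)))
    for k, c in enumerate(codes):
        mu, cov = class_stats[c]
        diff = px - mu
        d2[:, k] = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    out = np.array(codes, dtype=np.uint8)[d2.argmin(axis=1)]
    return out.reshape(image.shape[:2])


def percent_damage(mask: np.ndarray) -> float:
    """Percent damaged leaf area: 100 * damaged / (damaged + undamaged)."""
    damaged = int((mask == DAMAGED).sum())
    undamaged = int((mask == UNDAMAGED).sum())
    if damaged + undamaged == 0:
        raise ValueError("mask contains no leaf pixels")
    return 100.0 * damaged / (damaged + undamaged)


def pot_mean_damage(records: pd.DataFrame) -> pd.DataFrame:
    """Per-pot unweighted mean of leaf-level percent damage.

    ``records`` needs columns ``pot_id``, ``percent_damage`` and a boolean
    ``focal`` column marking the leaf sampled for volatiles.  Returns a
    DataFrame indexed by pot with ``mean_damage_pct`` and
    ``focal_damage_pct`` (NaN when a pot has no focal leaf).
    """
    if records.empty or records["pot_id"].isna().any():
        raise ValueError("every record needs a pot id")
    grouped = records.groupby("pot_id")["percent_damage"]
    mean = grouped.mean().rename("mean_damage_pct")
    if "focal" in records.columns:
        focal = (
            records[records["focal"].astype(bool)]
            .set_index("pot_id")["percent_damage"]
            .rename("focal_damage_pct")
        )
    else:
        focal = pd.Series(np.nan, index=mean.index, name="focal_damage_pct")
    out = pd.concat([mean, focal], axis=1)
    out.index.name = "pot_id"
    return out


def cohens_kappa(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Chance-corrected agreement between two categorical pixel labellings.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and
    chance agreement p_e from the confusion-matrix marginal products.
    When both labellings are a single identical class, p_e = 1 and kappa
    is defined as 1 by convention (logged).
    """
    if predicted.shape != truth.shape:
        raise ValueError("masks must share dimensions")
    a = predicted.reshape(-1)
    b = truth.reshape(-1)
    labels = np.union1d(np.unique(a), np.unique(b))
    k = labels.size
    idx_a = np.searchsorted(labels, a)
    idx_b = np.searchsorted(labels, b)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (idx_a, idx_b), 1)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e == 1.0:
        logger.info("kappa: both masks constant and equal; returning 1 by convention")
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
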