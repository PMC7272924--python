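"""Redundancy analysis with a single continuous constraint.

Redundancy analysis (RDA) projects a multivariate response matrix Y onto
the span of the predictor(s) and decomposes the fitted matrix.  With one
continuous predictor x there is a single constrained axis: the fraction
of Y's total variance captured by the fitted matrix is the variance
explained R^2, and the permutation-test statistic is the pseudo-F

    F = (R^2 / q) / ((1 - R^2) / (n - q - 1)),   q = 1.

Significance is assessed by unrestricted permutation of x; compounds
whose values correlate significantly with the constrained-axis site
scores are reported as biomarkers, ordered by |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MetaboliteMatrix

__all__ = [
    "RdaResult",
    "BiomarkerSet",
    "fit_rda",
    "permutation_test",
    "axis_correlations",
    "select_biomarkers",
]


@dataclass
class RdaResult:
    """Single-constraint RDA summary."""

    r2: float
    pseudo_f: float
    df: tuple[int, int]  # (q, n - q - 1)
    site_scores: pd.Series  # sample coordinates on the constrained axis
    loadings: pd.Series  # compound weights on the constrained axis
    n: int
    p_value: float | None = None
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r2}")


@dataclass
class BiomarkerSet:
    """Ordered biomarker table: compound, r, p, significance flag."""

    table: pd.DataFrame  # columns r, p, p_adjusted, significant; ordered by |r| desc
    alpha: float
    correction: str

    @property
    def compounds(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _as_matrix(Y) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(Y, MetaboliteMatrix):
        df = Y.values
    elif isinstance(Y, pd.DataFrame):
        df = Y
    else:
        arr = np.asarray(Y, dtype=float)
        df = pd.DataFrame(arr)
    return df.to_numpy(dtype=float), df.index, df.columns


def fit_rda(Y, x) -> RdaResult:
    """Fit single-predictor RDA.

    ``Y`` should be autoscaled (any column-centred matrix is accepted; it
    is centred internally for safety), ``x`` a continuous predictor that
    is mean-centred internally (the intercept is always in the model).
    Site scores are the sample coordinates on the single constrained axis
    (the first singular direction of the centred fitted matrix), oriented
    so their correlation with x is positive.
    """
    Ym, samples, compounds = _as_matrix(Y)
    x = np.asarray(x, dtype=float)
    n, p = Ym.shape
    if n < 4:
        raise ValueError(f"RDA needs n >= 4 samples, got {n}")
    if x.shape != (n,):
        raise ValueError("x length must match the number of samples")
    xc = x - x.mean()
    ss_x = float(xc @ xc)
    if ss_x == 0:
        raise ValueError("constant predictor: RDA undefined")
    Yc = Ym - Ym.mean(axis=0)
    slopes = (xc @ Yc) / ss_x  # per-compound regression slope on centred x
    fitted = np.outer(xc, slopes)  # centred fitted matrix, rank 1
    ss_tot = float((Yc**2).sum())
    ss_fit = float((fitted**2).sum())
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    df = (1, n - 2)
    pseudo_f = (ss_fit / 1) / (ss_res / (n - 2)) if ss_res > 0 else np.inf
    # rank-1 SVD in closed form: u = xc/||xc||, singular value ||xc|| * ||slopes||
    norm_b = float(np.linalg.norm(slopes))
    if norm_b == 0:
        scores = np.zeros(n)
        loadings = np.zeros(p)
    else:
        scores = xc * norm_b  # u * sigma = xc/||xc|| * ||xc|| ||b||
        loadings = slopes / norm_b
    # orientation: site scores correlate positively with x (already true since
    # scores are a positive multiple of centred x)
    return RdaResult(
        r2=r2,
        pseudo_f=pseudo_f,
        df=df,
        site_scores=pd.Series(scores, index=samples, name="axis1"),
        loadings=pd.Series(loadings, index=compounds, name="axis1"),
        n=n,
    )


def _pseudo_f_many(Yc: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of X (a set of predictor vectors) against the
    column-centred response Yc.  Vectorised over permutations."""
    Xc = X - X.mean(axis=1, keepdims=True)
    ss_x = (Xc**2).sum(axis=1)
    cross = Xc @ Yc  # B x p
    ss_fit = (cross**2).sum(axis=1) / ss_x
    ss_tot = float((Yc**2).sum())
    n = Yc.shape[0]
    ss_res = ss_tot - ss_fit
    with np.errstate(divide="ignore"):
        return np.where(ss_res > 0, ss_fit / (ss_res / (n - 2)), np.inf)


def permutation_test(
    Y,
    x,
    B: int = 999,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RdaResult:
    """Permutation test of the RDA constraint.

    Permutes the entries of x uniformly at random B times, recomputes the
    pseudo-F for each, and returns the fitted :class:`RdaResult` with
    ``p = (1 + #{F_perm >= F_obs}) / (1 + B)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    result = fit_rda(Y, x)
    Ym, _, _ = _as_matrix(Y)
    Yc = Ym - Ym.mean(axis=0)
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    # canonical sample order (sorted by x) so the realised permutation set —
    # and hence p — is invariant to joint relabeling of samples (up to ties)
    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Yc[order]
    perms = np.stack([rng.permutation(xs) for _ in range(B)])
    f_perm = _pseudo_f_many(Ys, perms)
    f_obs = result.pseudo_f
    result.p_value = float((1 + int((f_perm >= f_obs).sum())) / (1 + B))
    result.n_permutations = B
    return result


def axis_correlations(Y, site_scores: pd.Series) -> pd.DataFrame:
    """Pearson correlation of every compound with the constrained-axis site
    scores, with two-sided p-values from the t distribution on n-2 df."""
    Ym, samples, compounds = _as_matrix(Y)
    s = np.asarray(site_scores, dtype=float)
    n = Ym.shape[0]
    if s.shape != (n,):
        raise ValueError("site scores must match the number of samples")
    sc = s - s.mean()
    ss_s = float(sc @ sc)
    Yc = Ym - Ym.mean(axis=0)
    ss_y = (Yc**2).sum(axis=0)
    if (ss_y == 0).any():
        bad = list(compounds[ss_y == 0])
        raise ValueError(f"zero-variance compound(s): {bad}")
    r = (sc @ Yc) / np.sqrt(ss_s * ss_y)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return pd.DataFrame({"r": r, "p": p}, index=compounds)


def select_biomarkers(
    correlations: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
) -> BiomarkerSet:
    """Flag compounds significantly correlated with the constrained axis.

    ``correction`` is ``"none"`` (raw p < alpha, the default) or ``"BH"``
    (Benjamini-Hochberg FDR).  Output is ordered by |r| descending, ties
    broken by compound id.
    """
    tab = correlations.copy()
    if correction == "BH":
        rejected, p_adj, *_ = multipletests(tab["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        tab["p_adjusted"] = p_adj
        tab["significant"] = rejected
    elif correction == "none":
        tab["p_adjusted"] = tab["p"]
        tab["significant"] = tab["p"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    if alpha <= 0:
        tab["significant"] = False
    # order by |r| descending; ties broken by compound id (lexicographic)
    idx_name = tab.index.name or "compound"
    tab.index.name = idx_name
    tab = (
        tab.assign(_absr=tab["r"].abs())
        .reset_index()
        .sort_values(by=["_absr", idx_name], ascending=[False, True], kind="mergesort")
        .set_index(idx_name)
        .drop(columns="_absr")
    )
    return BiomarkerSet(table=tab, alpha=alpha, correction=correction)
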