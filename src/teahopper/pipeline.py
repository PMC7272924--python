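"""End-to-end orchestration: simulate -> preprocess -> damage QC -> RDA per
predictor -> biomarker dose-response -> report tables.

The analysis mirrors a two-block design: a volatile (GC-MS-like) block
analysed against insect density, ln mean leaf damage and ln focal-leaf
damage, and a non-volatile (LC-MS-like) block plus a total-polyphenols
scalar analysed against density and ln mean damage.  Multivariate
outliers are removed from the volatile block only; the non-volatile
block keeps all pots.  Every table carries provenance (seed, n,
version) in '#' header comments when written.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .damage import classify_pixels, cohens_kappa, fit_class_statistics, percent_damage
from .doseresponse import CompetitionResult, analyze_scalar_response, compete
from .preprocess import MetaboliteMatrix, autoscale, preprocess_peak_table
from .rda import BiomarkerSet, RdaResult, axis_correlations, permutation_test, select_biomarkers
from .synthetic import (
    SyntheticConfig,
    simulate_concentrations,
    simulate_herbivory,
    simulate_leaf_image,
    simulate_metabolites,
    simulate_peak_table,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "predictor_transform", "make_biomarker_table"]

#: predictors used per data block
VOLATILE_PREDICTORS = ("density", "ln_mean_damage", "ln_focal_damage")
NONVOLATILE_PREDICTORS = ("density", "ln_mean_damage")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alpha: float = 0.05
    correction: str = "none"  # biomarker p-value correction: none | BH
    B_perm: int = 999
    B_boot: int = 500
    seed: int = 0
    outdir: Path | None = None
    exclude_pots: tuple[str, ...] = ()  # input-data exclusions (judgment calls)
    simulate_images: bool = False  # run the image->classifier->damage QC stage
    image_size: int = 192
    # nonvolatile block design: counts + noise on the concentration scale
    nv_config: SyntheticConfig | None = None

    def default_nv_config(self) -> SyntheticConfig:
        # 12 LC-MS-like compounds (catechins, methylxanthines, theanine):
        # 4 linear responders to ln damage, 8 unresponsive
        return dataclasses.replace(
            self.synthetic,
            n_step=0,
            n_linear=4,
            n_hinge=0,
            n_null=8,
            slope_range=(-12.0, -4.0),  # concentrations fall with damage
            intercept_range=(40.0, 160.0),  # mg/g-like baselines
            noise_sigma=3.0,
        )


@dataclass
class ReportBundle:
    """All tables produced by one run."""

    predictors: pd.DataFrame
    rda_summary: pd.DataFrame  # block x predictor: R2, F, df, p, B
    biomarker_tables: dict[tuple[str, str], pd.DataFrame]  # (block, predictor) -> table
    polyphenol_table: pd.DataFrame
    damage_qc: pd.DataFrame | None
    truth: dict[str, pd.DataFrame]
    log: list[str]
    seed: int

    def checksum(self) -> str:
        """Stable digest of all report tables (determinism contract)."""
        h = hashlib.sha256()
        for name, df in self._tables():
            h.update(name.encode())
            h.update(df.to_csv(float_format="%.12g").encode())
        return h.hexdigest()

    def _tables(self):
        yield "predictors", self.predictors
        yield "rda_summary", self.rda_summary
        for key in sorted(self.biomarker_tables):
            yield f"biomarkers_{key[0]}_{key[1]}", self.biomarker_tables[key]
        yield "polyphenols", self.polyphenol_table
        if self.damage_qc is not None:
            yield "damage_qc", self.damage_qc

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# teahopper {__version__} | seed {self.seed}\n"
        for name, df in self._tables():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                fh.write(f"# n = {len(df)}\n")
                df.to_csv(fh, sep="\t")
        with open(outdir / "run.log", "w") as fh:
            fh.write(header)
            fh.write("\n".join(self.log) + "\n")


def predictor_transform(predictors: pd.DataFrame) -> pd.DataFrame:
    """Analysis-scale predictors: density untransformed, both damage
    measures natural-log transformed (damage must be positive)."""
    for col in ("mean_damage_pct", "focal_damage_pct"):
        bad = predictors.index[predictors[col] <= 0]
        if len(bad):
            raise ValueError(f"non-positive {col} for pot(s) {list(bad)}; ln transform undefined")
    return pd.DataFrame(
        {
            "density": predictors["density"],
            "ln_mean_damage": np.log(predictors["mean_damage_pct"]),
            "ln_focal_damage": np.log(predictors["focal_damage_pct"]),
        },
        index=predictors.index,
    )


def _dose_response_table(
    values: pd.DataFrame,
    x: pd.Series,
    biomarkers: BiomarkerSet,
    B_boot: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One row per compound, ordered by |r| (compounds absent from the
    ordination — e.g. constant columns — follow with r = NaN), with the
    winning shape and its parameters."""
    rows = []
    xv = x.to_numpy(dtype=float)
    extra = [c for c in values.columns if c not in biomarkers.table.index]
    for cid in list(biomarkers.table.index) + extra:
        in_ord = cid in biomarkers.table.index
        res = compete(xv, values[cid].to_numpy(dtype=float), B=B_boot, rng=rng)
        w = res.winner
        rows.append(
            {
                "compound": cid,
                "r": biomarkers.table.loc[cid, "r"] if in_ord else np.nan,
                "p_axis": biomarkers.table.loc[cid, "p"] if in_ord else np.nan,
                "biomarker": bool(biomarkers.table.loc[cid, "significant"]) if in_ord else False,
                "response_type": w.kind,
                "linear_slope": w.beta if w.kind in ("linear", "hinge") else np.nan,
                "change_point": w.changepoint if w.kind in ("step", "hinge") else np.nan,
                "delta_intercept": w.delta_intercept if w.kind == "step" else np.nan,
                "aic_null": res.fits["null"].aic,
                "aic_linear": res.fits["linear"].aic,
                "aic_step": res.fits["step"].aic,
                "aic_hinge": res.fits["hinge"].aic,
                "ci_low": res.ci.e_low if res.ci else np.nan,
                "ci_high": res.ci.e_high if res.ci else np.nan,
                "significant": res.significant,
                "demoted_from": ";".join(res.demoted_from) or "",
                "linear_p": res.linear_p if res.linear_p is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("compound")


def make_biomarker_table(dose_table: pd.DataFrame) -> pd.DataFrame:
    """Presentation table in the style of a biomarker results table: only
    significant biomarkers, ordered by |r|, dashes for inapplicable
    parameters."""
    tab = dose_table[dose_table["biomarker"]].copy()
    out = pd.DataFrame(index=tab.index)
    out["response_type"] = tab["response_type"].str.capitalize()
    fmt = lambda v: "-" if pd.isna(v) else f"{v:.3f}"
    out["linear_slope"] = [
        fmt(v) if k == "linear" else "-" for k, v in zip(tab["response_type"], tab["linear_slope"])
    ]
    out["change_point"] = tab["change_point"].map(fmt)
    out["delta_intercept"] = tab["delta_intercept"].map(fmt)
    out["r"] = tab["r"].map(lambda v: f"{v:.3f}")
    return out


def _analyze_block(
    name: str,
    scaled: MetaboliteMatrix,
    raw_for_fits: pd.DataFrame,
    predictors: pd.DataFrame,
    predictor_names: tuple[str, ...],
    cfg: RunConfig,
    rng: np.random.Generator,
    log: list[str],
):
    rda_rows = []
    dose_tables = {}
    for pred in predictor_names:
        x = predictors.loc[scaled.values.index, pred]
        res = permutation_test(scaled, x, B=cfg.B_perm, rng=rng)
        corr = axis_correlations(scaled, res.site_scores)
        bset = select_biomarkers(corr, alpha=cfg.alpha, correction=cfg.correction)
        rda_rows.append(
            {
                "block": name,
                "predictor": pred,
                "n": res.n,
                "r2": res.r2,
                "variance_explained_pct": 100 * res.r2,
                "pseudo_F": res.pseudo_f,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p_value,
                "B": res.n_permutations,
                "n_biomarkers": len(bset.compounds),
            }
        )
        dose_tables[(name, pred)] = _dose_response_table(
            raw_for_fits.loc[scaled.values.index], x, bset, cfg.B_boot, rng
        )
        log.append(
            f"{name}/{pred}: n={res.n}, R2={res.r2:.4f}, F={res.pseudo_f:.3f}, "
            f"p={res.p_value:.4g}, biomarkers={len(bset.compounds)}"
        )
    return rda_rows, dose_tables


def _damage_qc(predictors: pd.DataFrame, cfg: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Image pathway QC: render one focal-leaf image per pot at the pot's
    focal damage fraction, classify it with statistics trained on the
    first pot's truth mask, and compare recovered damage and agreement."""
    size = cfg.image_size
    rows = []
    stats = None
    for pot, row in predictors.iterrows():
        frac = min(row["focal_damage_pct"] / 100.0, 1.0)
        li = simulate_leaf_image(size, size, frac, noise_sd=5.0, rng=rng)
        if stats is None:
            stats = fit_class_statistics(li.image, li.mask)
        pred_mask = classify_pixels(li.image, stats, smooth_sigma=0.8)
        rows.append(
            {
                "pot_id": pot,
                "true_damage_pct": percent_damage(li.mask),
                "recovered_damage_pct": percent_damage(pred_mask),
                "kappa": cohens_kappa(pred_mask, li.mask),
            }
        )
    return pd.DataFrame(rows).set_index("pot_id")


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full synthetic analysis; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    log: list[str] = [f"seed {cfg.seed}"]

    # --- simulate -----------------------------------------------------
    predictors, herb_truth = simulate_herbivory(cfg.synthetic, rng)
    if cfg.exclude_pots:
        predictors = predictors.drop(index=list(cfg.exclude_pots))
        log.append(f"excluded pots (input-data decision): {list(cfg.exclude_pots)}")
    vol_ln, vol_truth = simulate_metabolites(predictors, cfg.synthetic, rng, x_column="density")
    nv_cfg = cfg.nv_config or cfg.default_nv_config()
    nv_conc, nv_truth = simulate_concentrations(predictors, nv_cfg, rng, x_column="mean_damage_pct")
    peaks = simulate_peak_table(vol_ln, rng=rng)
    log.append(f"simulated {len(predictors)} pots, {vol_ln.n_compounds} volatile and {nv_conc.n_compounds} non-volatile compounds")

    # --- preprocess (volatile block) ---------------------------------
    ln_m, scaled_vol, flags = preprocess_peak_table(peaks, alpha_outlier=cfg.alpha)
    log.extend(scaled_vol.log)
    log.append(
        f"volatile block: {len(predictors)} pots -> {ln_m.n_samples} after removing "
        f"{int(flags.sum())} multivariate outlier(s)"
    )

    # --- damage QC stage (optional) ----------------------------------
    damage_qc = _damage_qc(predictors, cfg, rng) if cfg.simulate_images else None

    # --- predictors on the analysis scale ----------------------------
    analysis_pred = predictor_transform(predictors)

    # --- RDA + dose-response per block -------------------------------
    rda_rows, dose_tables = [], {}
    r1, t1 = _analyze_block("volatiles", scaled_vol, ln_m.values, analysis_pred, VOLATILE_PREDICTORS, cfg, rng, log)
    rda_rows += r1
    dose_tables.update(t1)
    nv_sd = nv_conc.values.std(axis=0, ddof=1)
    if (~(nv_sd > 0)).any():
        const = list(nv_sd.index[~(nv_sd > 0)])
        log.append(f"nonvolatiles: dropped {len(const)} constant compound(s) from ordination: {const}")
        scaled_nv = autoscale(nv_conc._derive(nv_conc.values.drop(columns=const), nv_conc.scale, "drop constants"))
    else:
        scaled_nv = autoscale(nv_conc)
    r2, t2 = _analyze_block("nonvolatiles", scaled_nv, nv_conc.values, analysis_pred, NONVOLATILE_PREDICTORS, cfg, rng, log)
    rda_rows += r2
    dose_tables.update(t2)

    # --- total polyphenols (scalar, mg/g GAE-like) --------------------
    tp_truth_slope = -8.0
    tp = 180.0 + tp_truth_slope * analysis_pred["ln_mean_damage"] + rng.normal(0, 6.0, len(predictors))
    tp_rows = []
    for pred in NONVOLATILE_PREDICTORS:
        res = analyze_scalar_response(
            analysis_pred[pred].to_numpy(), tp.to_numpy(), B=cfg.B_boot, rng=rng
        )
        tp_rows.append(
            {
                "predictor": pred,
                "winner": res.winner.kind,
                "slope": res.winner.beta if res.winner.kind == "linear" else np.nan,
                "delta_aic_runner_up": res.delta_aic_runner_up,
                "linear_p": res.linear_p if res.linear_p is not None else np.nan,
                **{f"aic_{k}": f.aic for k, f in res.fits.items()},
            }
        )
        log.append(f"total_polyphenols/{pred}: winner={res.winner.kind}, dAIC={res.delta_aic_runner_up:.2f}")
    polyphenol_table = pd.DataFrame(tp_rows).set_index("predictor")

    return ReportBundle(
        predictors=predictors,
        rda_summary=pd.DataFrame(rda_rows).set_index(["block", "predictor"]),
        biomarker_tables=dose_tables,
        polyphenol_table=polyphenol_table,
        damage_qc=damage_qc,
        truth={
            "pots": herb_truth.pots,
            "volatile_compounds": vol_truth.compounds,
            "nonvolatile_compounds": nv_truth.compounds,
        },
        log=log,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# configuration files (flat key-value with sections)

def default_config_text() -> str:
    cp = configparser.ConfigParser()
    syn = SyntheticConfig()
    cp["synthetic"] = {
        "n_pots": syn.n_pots,
        "density_levels": ",".join(str(v) for v in syn.density_levels),
        "density_jitter": syn.density_jitter,
        "damage_threshold": syn.damage_threshold,
        "damage_baseline": syn.damage_baseline,
        "damage_slope": syn.damage_slope,
        "damage_sigma": syn.damage_sigma,
        "focal_correlation": syn.focal_correlation,
        "n_step": syn.n_step,
        "n_linear": syn.n_linear,
        "n_hinge": syn.n_hinge,
        "n_null": syn.n_null,
        "noise_sigma": syn.noise_sigma,
    }
    cp["analysis"] = {
        "alpha": 0.05,
        "correction": "none",
        "B_perm": 999,
        "B_boot": 500,
        "exclude_pots": "",
        "simulate_images": "false",
    }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def load_config(path: Path | str, seed: int = 0, outdir: Path | None = None) -> RunConfig:
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    s = cp["synthetic"] if "synthetic" in cp else {}
    syn_kwargs = {}
    int_keys = ("n_pots", "n_step", "n_linear", "n_hinge", "n_null")
    float_keys = (
        "density_jitter", "damage_threshold", "damage_baseline", "damage_slope",
        "damage_sigma", "focal_correlation", "noise_sigma",
    )
    for key in int_keys:
        if key in s:
            syn_kwargs[key] = int(s[key])
    for key in float_keys:
        if key in s:
            syn_kwargs[key] = float(s[key])
    if "density_levels" in s:
        syn_kwargs["density_levels"] = tuple(float(v) for v in s["density_levels"].split(","))
    syn = SyntheticConfig(seed=seed, **syn_kwargs)
    a = cp["analysis"] if "analysis" in cp else {}
    excl = tuple(p.strip() for p in a.get("exclude_pots", "").split(",") if p.strip())
    return RunConfig(
        synthetic=syn,
        alpha=float(a.get("alpha", 0.05)),
        correction=a.get("correction", "none"),
        B_perm=int(a.get("B_perm", 999)),
        B_boot=int(a.get("B_boot", 500)),
        seed=seed,
        outdir=outdir,
        exclude_pots=excl,
        simulate_images=a.get("simulate_images", "false").lower() in ("1", "true", "yes"),
    )
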