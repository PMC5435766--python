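"""Phenotypic data analyses: outlier screening, adjusted entry means within
and across environments, the one-step combining-ability variance model, and
broad-sense heritability.

The one-step model decomposes entry performance into a group effect (lines vs
hybrids), line genetic effects, hybrid GCA/SCA effects, their environment
interactions, environment main effects and plot residuals; all genetic terms
are random, estimated by REML.  Replicates are absorbed exactly for balanced
data: the plot-error variance comes from the within-cell replicate stratum
and the remaining components are fit on cell means with a known residual
offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CrossingDesign,
    DataError,
    GROUP_HYBRID,
    GROUP_INBRED,
    PhenotypeTable,
    STAGE_ACROSS,
    STAGE_PLOT,
    STAGE_WITHIN,
)
from .mixedlm import ai_reml, lrt_variance_component

DEFAULT_PREMIUM = 1.0 / 250.0  # expected rejections per observation under normality


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------


def detect_outliers(
    plots: PhenotypeTable, premium: float = DEFAULT_PREMIUM
) -> tuple:
    """Flag plots with extreme studentized residuals from the per-environment
    genotype-means model.

    The rejection bound is the two-sided Student quantile at the configured
    premium (default: ~one rejection per 250 observations under normality)
    with the environment's residual degrees of freedom.
    """
    if plots.stage != STAGE_PLOT:
        raise DataError("outlier detection expects plot-stage data")
    df = plots.records.copy()
    removed_rows = []
    keep_mask = np.ones(len(df), dtype=bool)
    for env, sub in df.groupby("environment", sort=False):
        if len(sub) < 3:
            warnings.warn(f"environment {env!r}: fewer than 3 observations, skipped")
            continue
        cell_means = sub.groupby("genotype_id")["value"].transform("mean")
        cell_sizes = sub.groupby("genotype_id")["value"].transform("size")
        resid = sub["value"] - cell_means
        nu = int(len(sub) - sub["genotype_id"].nunique())
        if nu <= 0:
            continue
        s2 = float((resid**2).sum()) / nu
        if s2 <= 0:
            continue
        h = 1.0 / cell_sizes.to_numpy(dtype=float)
        denom = np.sqrt(s2 * np.maximum(1.0 - h, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, resid.to_numpy() / denom, 0.0)
        bound = stats.t.isf(premium / 2.0, nu)
        bad = np.abs(r) > bound
        for pos, is_bad in zip(sub.index, bad):
            if is_bad:
                keep_mask[df.index.get_loc(pos)] = False
                removed_rows.append(
                    {
                        "genotype_id": df.loc[pos, "genotype_id"],
                        "environment": env,
                        "replicate": df.loc[pos, "replicate"],
                        "value": df.loc[pos, "value"],
                        "statistic": float(r[list(sub.index).index(pos)]),
                    }
                )
    cleaned = PhenotypeTable(df[keep_mask].reset_index(drop=True), stage=STAGE_PLOT)
    return cleaned, removed_rows


# ---------------------------------------------------------------------------
# Adjusted means
# ---------------------------------------------------------------------------


def adjust_means_within_env(plots: PhenotypeTable) -> PhenotypeTable:
    """Least-squares genotype means per environment (genotype fixed, residual
    random): with any replicate pattern these are the arithmetic cell means."""
    if plots.stage != STAGE_PLOT:
        raise DataError("expects plot-stage data")
    g = (
        plots.records.groupby(["genotype_id", "environment"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    g["replicate"] = 1
    return PhenotypeTable(
        g[["genotype_id", "environment", "replicate", "value"]], stage=STAGE_WITHIN
    )


def adjust_means_across_env(within: PhenotypeTable) -> PhenotypeTable:
    """Across-environment adjusted means: genotype fixed, environment and
    residual random, fit by REML/GLS on the within-environment means."""
    if within.stage != STAGE_WITHIN:
        raise DataError("expects within-environment means")
    df = within.records
    counts = df.groupby("genotype_id", sort=False)["value"].size()
    dropped = counts[counts == 0].index.tolist()
    gids = pd.unique(df["genotype_id"])
    envs = pd.unique(df["environment"])
    gi = pd.Categorical(df["genotype_id"], categories=gids).codes
    ei = pd.Categorical(df["environment"], categories=envs).codes
    n = len(df)
    y = df["value"].to_numpy(dtype=float)
    X = np.zeros((n, len(gids)))
    X[np.arange(n), gi] = 1.0
    if len(envs) > 1:
        Zl = np.zeros((n, len(envs)))
        Zl[np.arange(n), ei] = 1.0
        fit = ai_reml(y, X, [Zl @ Zl.T])
        beta = fit.beta
    else:
        beta = y.copy() if n == len(gids) else np.linalg.lstsq(X, y, rcond=None)[0]
    out = pd.DataFrame(
        {
            "genotype_id": gids,
            "environment": "ALL",
            "replicate": 1,
            "value": beta[: len(gids)],
        }
    )
    return PhenotypeTable(out, stage=STAGE_ACROSS)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML variance components of the one-step combining-ability model.

    GCA-type components are reported on the hybrid scale (the summed
    contribution of both parents), so sigma2_genotype = sigma2_gca +
    sigma2_sca for hybrids, mirroring the usual decomposition.
    """

    sigma2_genotype: float
    sigma2_gca: float
    sigma2_sca: float
    sigma2_gxe: float
    sigma2_env_x_gca: float
    sigma2_env_x_sca: float
    sigma2_residual: float
    n_env: int
    n_rep: float
    heritability: float = float("nan")
    sigma2_genotype_parents: float = float("nan")
    sigma2_gxe_parents: float = float("nan")
    sigma2_env: float = float("nan")
    heritability_parents: float = float("nan")
    significance: dict = field(default_factory=dict)
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        for name in (
            "sigma2_genotype",
            "sigma2_gca",
            "sigma2_sca",
            "sigma2_gxe",
            "sigma2_env_x_gca",
            "sigma2_env_x_sca",
            "sigma2_residual",
        ):
            if getattr(self, name) < 0:
                raise DataError(f"negative variance component {name}")
        if np.isnan(self.heritability):
            self.heritability = heritability(self)

    def to_dict(self) -> dict:
        d = {
            k: (v if not isinstance(v, float) or np.isfinite(v) else None)
            for k, v in self.__dict__.items()
        }
        return d


def heritability(
    vc: "VarianceComponents | None" = None,
    sigma2_g: float | None = None,
    sigma2_gxe: float | None = None,
    sigma2_resid: float | None = None,
    n_env: int | None = None,
    n_rep: float | None = None,
) -> float:
    """Broad-sense heritability on an entry-mean basis:

    H2 = s2G / (s2G + s2GxE / NE + s2E / (NE * NR)).
    """
    if vc is not None:
        sigma2_g = vc.sigma2_genotype
        sigma2_gxe = vc.sigma2_gxe
        sigma2_resid = vc.sigma2_residual
        n_env = vc.n_env
        n_rep = vc.n_rep
    denom = sigma2_g + sigma2_gxe / n_env + sigma2_resid / (n_env * n_rep)
    if denom <= 0:
        raise DataError("zero phenotypic variance in heritability denominator")
    h2 = sigma2_g / denom
    if not (0.0 <= h2 <= 1.0 + 1e-12):
        raise DataError(f"heritability {h2} outside [0, 1]")
    return float(min(h2, 1.0))


def _one_step_components(plots: PhenotypeTable, pedigree: CrossingDesign, groups: dict):
    """Assemble cell means, the known residual offset, and all covariance
    component matrices of the one-step model."""
    df = plots.records
    # plot-error variance from the within-cell replicate stratum
    grp = df.groupby(["genotype_id", "environment"], sort=False)["value"]
    cell = grp.agg(["mean", "count"]).reset_index()
    sse = float(((df["value"] - grp.transform("mean")) ** 2).sum())
    df_err = int((cell["count"] - 1).sum())
    if df_err <= 0:
        raise DataError("need replicated cells to separate the plot error")
    sigma2_e = sse / df_err

    gids = cell["genotype_id"].to_numpy()
    envs_all = pd.unique(cell["environment"])
    y = cell["mean"].to_numpy(dtype=float)
    n = len(cell)
    group = np.array([groups[g] for g in gids], dtype=object)
    is_hyb = group == GROUP_HYBRID
    is_line = ~is_hyb
    parents = pedigree.parents_of() if pedigree is not None else {}
    for g in gids[is_hyb]:
        if g not in parents:
            raise DataError(f"hybrid {g!r} missing from pedigree")

    def onehot(labels, cats=None):
        cats = pd.unique(labels) if cats is None else cats
        codes = pd.Categorical(labels, categories=cats).codes
        Z = np.zeros((n, len(cats)))
        ok = codes >= 0
        Z[np.where(ok)[0], codes[ok]] = 1.0
        return Z

    env_lab = cell["environment"].to_numpy()
    Z_env = onehot(env_lab, envs_all)
    # line genetic and line x env (line cells only)
    line_ids = pd.unique(gids[is_line])
    lab_line = np.where(is_line, gids, "~")
    Z_p = onehot(lab_line, line_ids)
    G_pl = np.diag(is_line.astype(float))  # one (line, env) draw per cell
    # hybrid GCA: both parents, one shared variance
    parent_ids = pd.unique(
        np.array([p for g in gids[is_hyb] for p in parents[g]], dtype=object)
    )
    lab_m = np.array([parents[g][0] if h else "~" for g, h in zip(gids, is_hyb)], dtype=object)
    lab_f = np.array([parents[g][1] if h else "~" for g, h in zip(gids, is_hyb)], dtype=object)
    # one GCA effect per line, contributed in either parental slot: a hybrid
    # receives the sum of its two parents' effects, so Z counts appearances
    Z_gca = onehot(lab_m, parent_ids) + onehot(lab_f, parent_ids)
    G_gca = Z_gca @ Z_gca.T
    # SCA: hybrid identity
    hyb_ids = pd.unique(gids[is_hyb])
    Z_s = onehot(np.where(is_hyb, gids, "~"), hyb_ids)
    G_sca = Z_s @ Z_s.T
    # GCA x env
    lab_ml = np.array([f"{m}|{e}" if h else "~" for m, e, h in zip(lab_m, env_lab, is_hyb)], dtype=object)
    lab_fl = np.array([f"{f}|{e}" if h else "~" for f, e, h in zip(lab_f, env_lab, is_hyb)], dtype=object)
    ml_ids = pd.unique(np.concatenate([lab_ml[is_hyb], lab_fl[is_hyb]])) if is_hyb.any() else np.array([])
    Z_gcae = onehot(lab_ml, ml_ids) + onehot(lab_fl, ml_ids)
    G_gcae = Z_gcae @ Z_gcae.T
    # SCA x env: one draw per hybrid cell
    G_scae = np.diag(is_hyb.astype(float))

    X = np.column_stack([np.ones(n), is_hyb.astype(float)])
    R0 = np.diag(sigma2_e / cell["count"].to_numpy(dtype=float))
    comps = {
        "env": Z_env @ Z_env.T,
        "line": Z_p @ Z_p.T,
        "line_x_env": G_pl,
        "gca": G_gca,
        "sca": G_sca,
        "gca_x_env": G_gcae,
        "sca_x_env": G_scae,
    }
    n_rep = float(cell["count"].mean())
    return y, X, comps, R0, sigma2_e, len(envs_all), n_rep


def fit_gca_sca(
    plots: PhenotypeTable,
    pedigree: CrossingDesign,
    groups: dict,
    significance: tuple = (),
) -> VarianceComponents:
    """REML fit of the one-step combining-ability model on plot data.

    ``groups`` maps genotype_id -> "inbred"/"hybrid".  ``significance`` lists
    component names ("gca", "sca", ...) to test by a boundary likelihood-ratio
    test against the component-dropped model.
    """
    if plots.stage != STAGE_PLOT:
        raise DataError("expects plot-stage data")
    y, X, comps, R0, sigma2_e, n_env, n_rep = _one_step_components(plots, pedigree, groups)
    names = list(comps)
    Ks = [comps[k] for k in names]
    fit = ai_reml(y, X, Ks, R0=R0, include_residual=False)
    theta = dict(zip(names, fit.variances))
    sig = {}
    for comp in significance:
        if comp not in comps:
            raise DataError(f"unknown component {comp!r}")
        reduced = [comps[k] for k in names if k != comp]
        fit0 = ai_reml(y, X, reduced, R0=R0, include_residual=False)
        sig[comp] = lrt_variance_component(fit.loglik, fit0.loglik)
    vc = VarianceComponents(
        sigma2_genotype=2.0 * theta["gca"] + theta["sca"],
        sigma2_gca=2.0 * theta["gca"],
        sigma2_sca=theta["sca"],
        sigma2_gxe=2.0 * theta["gca_x_env"] + theta["sca_x_env"],
        sigma2_env_x_gca=2.0 * theta["gca_x_env"],
        sigma2_env_x_sca=theta["sca_x_env"],
        sigma2_residual=sigma2_e,
        n_env=n_env,
        n_rep=n_rep,
        sigma2_genotype_parents=theta["line"],
        sigma2_gxe_parents=theta["line_x_env"],
        sigma2_env=theta["env"],
        significance=sig,
        loglik=fit.loglik,
    )
    try:
        vc.heritability_parents = heritability(
            sigma2_g=theta["line"],
            sigma2_gxe=theta["line_x_env"],
            sigma2_resid=sigma2_e,
            n_env=n_env,
            n_rep=n_rep,
        )
    except DataError:
        pass
    return vc
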