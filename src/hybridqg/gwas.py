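"""Kinship-corrected genome scans.

Single-marker scans test additive and dominance terms jointly in the mixed
model Y = X beta + S s + Z u + e with a kinship covariance for u; the
two-dimensional scan adds the four digenic interaction terms (AxA, AxD, DxA,
DxD).  Null variance components are estimated once by spectral REML and
reused across markers (P3D); an exact per-marker mode is available for
oracle comparisons.  Multiplicity is controlled by Bonferroni-Holm for main
effects and by permutation for interactions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DataError,
    DesignMatrices,
    GROUP_HYBRID,
    PhenotypeTable,
    RelationshipMatrix,
    STAGE_ACROSS,
    STAGE_WITHIN,
)
from .mixedlm import SpectralNull, spectral_reml, wald_fixed_effects

EPI_TERMS = ("i11", "i12", "i21", "i22")


@dataclass
class ScanResult:
    table: pd.DataFrame
    sigma2_u: float
    sigma2_e: float
    mode: str = "per_marker"  # or "pairs"
    skipped: list = field(default_factory=list)

    def significant(self, columns: tuple, thresholds) -> pd.DataFrame:
        out = self.table.copy()
        for c, t in zip(columns, np.atleast_1d(thresholds)):
            out[f"sig_{c}"] = out[c] <= t
        return out


@dataclass
class ExplainedVariance:
    per_qtl: pd.DataFrame  # qtl label, sequential adjusted-R2 increment
    total_r2: float
    pg: float
    capped: bool


# ---------------------------------------------------------------------------
# Stacking means over environments
# ---------------------------------------------------------------------------


def stack_observations(means: PhenotypeTable, design: DesignMatrices, kinship: RelationshipMatrix):
    """Expand genotype-level designs/kinship to the stacked observation level
    (one row per genotype x environment) and build the fixed covariates
    (intercept + environment contrasts)."""
    if means.stage not in (STAGE_WITHIN, STAGE_ACROSS):
        raise DataError("scan expects adjusted means")
    df = means.records
    gids = pd.unique(df["genotype_id"])
    lookup = {g: i for i, g in enumerate(design.individual_ids)}
    try:
        gidx = np.array([lookup[g] for g in df["genotype_id"]])
    except KeyError as e:
        raise DataError(f"genotype {e.args[0]!r} missing from design")
    K = kinship.reindex(list(design.individual_ids)).values
    K_obs = K[np.ix_(gidx, gidx)]
    y = df["value"].to_numpy(dtype=float)
    envs = pd.unique(df["environment"])
    X0 = [np.ones(len(df))]
    for e in envs[1:]:
        X0.append((df["environment"] == e).to_numpy(dtype=float))
    X0 = np.column_stack(X0)
    A_obs = design.A[gidx]
    D_obs = design.D[gidx]
    return y, X0, A_obs, D_obs, K_obs, gidx


def _marker_terms(a_col: np.ndarray, d_col: np.ndarray):
    """Columns to test for a marker; the dominance term is dropped when it is
    constant (e.g. an all-inbred panel)."""
    cols, labels = [], []
    if np.nanstd(a_col) > 0:
        cols.append(a_col)
        labels.append("a")
    if np.nanstd(d_col) > 0:
        cols.append(d_col)
        labels.append("d")
    return cols, labels


def main_effect_scan(
    means: PhenotypeTable,
    design: DesignMatrices,
    kinship: RelationshipMatrix,
    mode: str = "p3d",
) -> ScanResult:
    """Joint additive+dominance single-marker scan with polygenic control.

    ``mode="p3d"`` reuses the null variance components for every marker;
    ``mode="exact"`` re-estimates them per marker.  Markers with missing
    genotypes are refit on complete cases in the unrotated model.
    """
    y, X0, A_obs, D_obs, K_obs, _ = stack_observations(means, design, kinship)
    null = spectral_reml(y, X0, K=K_obs)
    yw = null.whiten(y)
    X0w = null.whiten(X0)
    p0 = X0.shape[1]
    rows = []
    m = design.n_markers
    missing_any = np.isnan(A_obs).any(axis=0)
    Aw = null.whiten(np.nan_to_num(A_obs))
    Dw = null.whiten(D_obs)
    for j in range(m):
        rec = {
            "marker_id": design.map.marker_id[j],
            "chromosome": design.map.chromosome[j],
            "cM": design.map.position_cm[j],
            "beta_a": np.nan,
            "se_a": np.nan,
            "p_a": 1.0,
            "beta_d": np.nan,
            "se_d": np.nan,
            "p_d": 1.0,
            "flag": "",
        }
        a_col, d_col = A_obs[:, j], D_obs[:, j]
        if missing_any[j]:
            ok = ~np.isnan(a_col)
            cols, labels = _marker_terms(a_col[ok], d_col[ok])
            if not cols:
                rec["flag"] = "constant"
                rows.append(rec)
                continue
            sub_null = spectral_reml(y[ok], X0[ok], K=K_obs[np.ix_(ok, ok)]) if mode == "exact" else None
            if sub_null is None:
                # P3D on the subset: reuse lambda, re-decompose the subset kernel
                w, U = np.linalg.eigh((K_obs[np.ix_(ok, ok)] + K_obs[np.ix_(ok, ok)].T) / 2)
                w = np.maximum(w, 0.0)
                wts = np.sqrt(null.lam * w + 1.0)
                yws = (U.T @ y[ok]) / wts
                Xws = np.column_stack([U.T @ X0[ok]] + [U.T @ c for c in cols]) / wts[:, None]
            else:
                yws = sub_null.whiten(y[ok])
                Xws = np.column_stack(
                    [sub_null.whiten(X0[ok])] + [sub_null.whiten(c) for c in cols]
                )
            beta, se, pv, _, _ = wald_fixed_effects(yws, Xws)
        else:
            cols, labels = _marker_terms(a_col, d_col)
            if not cols:
                rec["flag"] = "constant"
                rows.append(rec)
                continue
            if mode == "exact":
                mk = spectral_reml(
                    y, np.column_stack([X0] + cols), eig=(null.eigvals, null.U)
                )
                Xw_full = mk.whiten(np.column_stack([X0] + cols))
                beta, se, pv, _, _ = wald_fixed_effects(mk.whiten(y), Xw_full)
            else:
                wcols = [Aw[:, j] if lab == "a" else Dw[:, j] for lab in labels]
                Xw = np.column_stack([X0w] + wcols)
                beta, se, pv, _, _ = wald_fixed_effects(yw, Xw)
        for k, lab in enumerate(labels):
            rec[f"beta_{lab}"] = beta[p0 + k]
            rec[f"se_{lab}"] = se[p0 + k]
            rec[f"p_{lab}"] = pv[p0 + k]
        if "d" not in labels:
            rec["flag"] = (rec["flag"] + ";no_dominance_term").strip(";")
        rows.append(rec)
    return ScanResult(
        table=pd.DataFrame(rows),
        sigma2_u=null.sigma2_u,
        sigma2_e=null.sigma2_e,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------


def holm_correct(p_values, alpha: float = 0.1) -> np.ndarray:
    """Step-down Bonferroni-Holm rejection flags at family level alpha."""
    p = np.asarray(p_values, dtype=float)
    if not np.all(np.isfinite(p)):
        raise DataError("non-finite p-values")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


# ---------------------------------------------------------------------------
# Two-dimensional epistasis scan
# ---------------------------------------------------------------------------


def candidate_pairs(
    design: DesignMatrices,
    max_r2: float = 0.9,
    min_cm: float = 5.0,
    marker_idx: np.ndarray | None = None,
):
    """Marker pairs for the 2D scan, excluding near-collinear pairs
    (within-pair r^2 > max_r2) and close linkage (< min_cm on one
    chromosome).  Returns (pairs, skipped with reasons)."""
    idx = np.arange(design.n_markers) if marker_idx is None else np.asarray(marker_idx)
    A = design.A[:, idx]
    sd = A.std(axis=0)
    Ac = A - A.mean(axis=0)
    pairs, skipped = [], []
    chrom = design.map.chromosome[idx]
    cm = design.map.position_cm[idx]
    n = A.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sd > 0, Ac / (sd * np.sqrt(n)), 0.0)
    corr = norm.T @ norm
    for a, b in itertools.combinations(range(len(idx)), 2):
        if chrom[a] == chrom[b] and abs(cm[a] - cm[b]) < min_cm:
            skipped.append((int(idx[a]), int(idx[b]), "linked"))
            continue
        if corr[a, b] ** 2 > max_r2:
            skipped.append((int(idx[a]), int(idx[b]), "collinear"))
            continue
        pairs.append((int(idx[a]), int(idx[b])))
    return pairs, skipped


def _pair_columns(A_obs, D_obs, i, j):
    a1, a2 = A_obs[:, i], A_obs[:, j]
    d1, d2 = D_obs[:, i], D_obs[:, j]
    return np.column_stack([a1, a2, d1, d2, a1 * a2, a1 * d2, a2 * d1, d1 * d2])


def _fit_pairs(yw, X0w, whiten, A_obs, D_obs, pairs, map_meta):
    """Fit the 8-term model for each pair on whitened data."""
    p0 = X0w.shape[1]
    term_names = ["a1", "a2", "d1", "d2", "i11", "i12", "i21", "i22"]
    rows = []
    skipped = []
    for (i, j) in pairs:
        M = _pair_columns(A_obs, D_obs, i, j)
        keep = M.std(axis=0) > 0
        Xw = np.column_stack([X0w, whiten(M[:, keep])])
        if not keep[4:].any():
            skipped.append((i, j, "no_interaction_columns"))
            continue
        beta, se, pv, df, rank = wald_fixed_effects(yw, Xw)
        if rank < Xw.shape[1]:
            skipped.append((i, j, "rank_deficient"))
            continue
        rec = {
            "marker_1": map_meta.marker_id[i],
            "marker_2": map_meta.marker_id[j],
            "chrom_1": map_meta.chromosome[i],
            "chrom_2": map_meta.chromosome[j],
        }
        col = p0
        for t, k in zip(term_names, range(8)):
            if keep[k]:
                rec[f"beta_{t}"] = beta[col]
                rec[f"p_{t}"] = pv[col]
                col += 1
            else:
                rec[f"beta_{t}"] = np.nan
                rec[f"p_{t}"] = np.nan
        rows.append(rec)
    return rows, skipped


def epistasis_scan_2d(
    means: PhenotypeTable,
    design: DesignMatrices,
    kinship: RelationshipMatrix,
    max_r2: float = 0.9,
    min_cm: float = 5.0,
    marker_idx: np.ndarray | None = None,
    mode: str = "p3d",
) -> ScanResult:
    """Full two-dimensional scan: for each retained pair the additive,
    dominance and four interaction terms enter as fixed effects on the
    null-whitened data; Wald P-values per interaction term."""
    if np.isnan(design.A).any():
        raise DataError("2D scan requires complete (imputed) design matrices")
    y, X0, A_obs, D_obs, K_obs, _ = stack_observations(means, design, kinship)
    null = spectral_reml(y, X0, K=K_obs)
    pairs, pre_skipped = candidate_pairs(design, max_r2, min_cm, marker_idx)
    if mode == "exact":
        rows, skipped = [], []
        for (i, j) in pairs:
            M = _pair_columns(A_obs, D_obs, i, j)
            keep = M.std(axis=0) > 0
            fit = spectral_reml(y, np.column_stack([X0, M[:, keep]]), eig=(null.eigvals, null.U))
            r, s = _fit_pairs(
                fit.whiten(y), fit.whiten(X0), fit.whiten, A_obs, D_obs, [(i, j)], design.map
            )
            rows.extend(r)
            skipped.extend(s)
    else:
        yw = null.whiten(y)
        X0w = null.whiten(X0)
        rows, skipped = _fit_pairs(yw, X0w, null.whiten, A_obs, D_obs, pairs, design.map)
    return ScanResult(
        table=pd.DataFrame(rows),
        sigma2_u=null.sigma2_u,
        sigma2_e=null.sigma2_e,
        mode="pairs",
        skipped=pre_skipped + skipped,
    )


def _min_p_per_term(table: pd.DataFrame) -> dict:
    return {
        t: float(np.nanmin(table[f"p_{t}"])) if f"p_{t}" in table and len(table) else 1.0
        for t in EPI_TERMS
    }


def permute_within_groups(
    gids: np.ndarray, groups: dict, rng: np.random.Generator
) -> dict:
    """Permutation of genotype labels within group; the full multi-environment
    phenotype vector of a genotype moves as one unit."""
    gids = np.asarray(gids)
    mapping = {}
    labels = np.array([groups[g] for g in gids], dtype=object)
    for lab in pd.unique(labels):
        members = gids[labels == lab]
        perm = members[rng.permutation(len(members))]
        mapping.update(dict(zip(members, perm)))
    return mapping


def permutation_threshold(
    means: PhenotypeTable,
    design: DesignMatrices,
    kinship: RelationshipMatrix,
    groups: dict,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_r2: float = 0.9,
    min_cm: float = 5.0,
    marker_idx: np.ndarray | None = None,
) -> dict:
    """Permutation thresholds for the 2D scan: per interaction term, the
    empirical alpha-quantile (the ceil(alpha * n_perm)-th smallest) of the
    genome-wide minimum P over permuted genotype-phenotype assignments."""
    if n_perm < 50:
        raise DataError("n_perm must be >= 50")
    if alpha * n_perm < 1:
        raise DataError("n_perm too small for the requested alpha")
    rng = np.random.default_rng(seed)
    df = means.records
    minima = {t: [] for t in EPI_TERMS}
    for _ in range(n_perm):
        mapping = permute_within_groups(pd.unique(df["genotype_id"]), groups, rng)
        perm_records = df.copy()
        perm_records["genotype_id"] = [mapping[g] for g in df["genotype_id"]]
        perm_means = PhenotypeTable(perm_records, stage=means.stage)
        res = epistasis_scan_2d(
            perm_means, design, kinship, max_r2=max_r2, min_cm=min_cm, marker_idx=marker_idx
        )
        mp = _min_p_per_term(res.table)
        for t in EPI_TERMS:
            minima[t].append(mp[t])
    k = int(np.ceil(alpha * n_perm))
    return {t: float(np.sort(minima[t])[k - 1]) for t in EPI_TERMS}


# ---------------------------------------------------------------------------
# Explained variance
# ---------------------------------------------------------------------------


def _adjusted_r2(y, X) -> float:
    n = len(y)
    Xc = np.column_stack([np.ones(n), X]) if X is not None else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    r2 = 1.0 - float(resid @ resid) / float(np.sum((y - y.mean()) ** 2))
    k = rank - 1
    if n - k - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def explained_variance(
    means: PhenotypeTable,
    qtl_columns: list,
    p_values,
    h2: float,
    labels: list | None = None,
) -> ExplainedVariance:
    """Sequential explained variance: QTL design columns enter a multiple
    regression in increasing-P order; increments of the adjusted R^2 sum to
    the full-model adjusted R^2.  pG = total R^2 / H^2, capped at 1.
    ``qtl_columns`` are genotype-aligned design columns (one per QTL term).
    """
    if len(qtl_columns) == 0:
        raise DataError("no detected QTL")
    df = means.records
    y = df["value"].to_numpy(dtype=float)
    order = np.argsort(np.asarray(p_values), kind="stable")
    labels = labels or [f"qtl_{i}" for i in range(len(qtl_columns))]
    rows = []
    X = None
    prev = 0.0
    rank_prev = 1  # intercept
    for o in order:
        col = np.asarray(qtl_columns[o], dtype=float).reshape(-1, 1)
        Xn = col if X is None else np.column_stack([X, col])
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xn]))
        if rank == rank_prev:
            warnings.warn(f"QTL {labels[o]} collinear with earlier QTL, dropped")
            rows.append({"qtl": labels[o], "r2_increment": 0.0, "p": float(p_values[o])})
            continue
        X = Xn
        rank_prev = rank
        r2 = _adjusted_r2(y, X)
        rows.append({"qtl": labels[o], "r2_increment": r2 - prev, "p": float(p_values[o])})
        prev = r2
    total = prev
    pg = total / h2
    capped = pg > 1.0
    if capped:
        warnings.warn(f"explained genotypic proportion {pg:.3f} > 1, capped")
        pg = 1.0
    return ExplainedVariance(
        per_qtl=pd.DataFrame(rows), total_r2=total, pg=float(pg), capped=capped
    )


# ---------------------------------------------------------------------------
# Cross-validated mapping accuracy
# ---------------------------------------------------------------------------


def hybrid_folds(hybrid_ids: np.ndarray, folds: int, rng: np.random.Generator) -> list:
    ids = np.asarray(hybrid_ids)
    perm = rng.permutation(len(ids))
    return [sorted(ids[perm[f::folds]].tolist()) for f in range(folds)]


def cv_mapping_accuracy(
    means_stacked: PhenotypeTable,
    means_across: PhenotypeTable,
    design: DesignMatrices,
    markers_for_kinship,
    groups: dict,
    h2: float,
    folds: int = 5,
    alpha: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """QTL-based prediction accuracy under the estimation/test split: all
    inbreds plus 80% of hybrids detect QTL and estimate their effects; the
    held-out hybrids are predicted from those effects.  Accuracy is the
    Pearson correlation standardized by sqrt(H2).  Kinship is recomputed on
    each estimation set."""
    from .kernels import rogers_kinship

    rng = np.random.default_rng(seed)
    gids = np.asarray(list(groups))
    hybrids = np.array([g for g in gids if groups[g] == GROUP_HYBRID])
    fold_sets = hybrid_folds(hybrids, folds, rng)
    across = means_across.records.set_index("genotype_id")["value"]
    out = []
    for f, test_ids in enumerate(fold_sets):
        test = set(test_ids)
        est_mask_stacked = ~means_stacked.records["genotype_id"].isin(test)
        est_stacked = PhenotypeTable(
            means_stacked.records[est_mask_stacked].reset_index(drop=True),
            stage=means_stacked.stage,
        )
        est_ids = [g for g in design.individual_ids if g not in test]
        sub_design = design.reindex(est_ids)
        sub_markers = markers_for_kinship.subset_individuals(
            np.array([i for i, g in enumerate(markers_for_kinship.individual_ids) if g not in test])
        )
        kin = rogers_kinship(sub_markers)
        scan = main_effect_scan(est_stacked, sub_design, kin)
        p_all = np.concatenate([scan.table["p_a"].to_numpy(), scan.table["p_d"].to_numpy()])
        flags = holm_correct(p_all, alpha)
        m = len(scan.table)
        det_a = np.where(flags[:m])[0]
        det_d = np.where(flags[m:])[0]
        if len(det_a) + len(det_d) == 0:
            out.append({"fold": f, "accuracy": 0.0, "n_qtl": 0, "flag": "no_qtl"})
            continue
        # effect estimation: multiple regression of across-env means on QTL columns
        lookup = {g: i for i, g in enumerate(design.individual_ids)}
        est_rows = np.array([lookup[g] for g in est_ids])
        test_order = [g for g in design.individual_ids if g in test]
        test_rows = np.array([lookup[g] for g in test_order])
        cols_est = [design.A[est_rows, j] for j in det_a] + [design.D[est_rows, j] for j in det_d]
        cols_test = [design.A[test_rows, j] for j in det_a] + [design.D[test_rows, j] for j in det_d]
        X_est = np.column_stack([np.ones(len(est_rows))] + cols_est)
        X_test = np.column_stack([np.ones(len(test_rows))] + cols_test)
        y_est = across.loc[est_ids].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X_est, y_est, rcond=None)
        pred = X_test @ beta
        obs = across.loc[test_order].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            acc = 0.0
        else:
            acc = float(np.corrcoef(pred, obs)[0, 1]) / np.sqrt(h2)
        out.append({"fold": f, "accuracy": acc, "n_qtl": len(det_a) + len(det_d), "flag": ""})
    return pd.DataFrame(out)
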