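"""Multi-kernel GBLUP, hybrid prediction, cross-validation and Bayesian
variance partitioning.

All kernel models (additive; additive+dominance; additive+dominance+Gaussian
epistasis) are fit by REML for determinism; the Bayesian machinery is
confined to :func:`bayesian_variance_partition`, a Gibbs sampler over
ridge-type priors per effect class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DataError,
    DesignMatrices,
    GROUP_HYBRID,
    MarkerMatrix,
    PhenotypeTable,
    RelationshipMatrix,
)
from .kernels import (
    RIDGE,
    additive_relationship,
    dominance_relationship,
    gaussian_kernel,
    realized_bandwidth,
)
from .genotype import f_infinity_design
from .mixedlm import ai_reml

MODELS = ("A", "AD", "ADE")


@dataclass
class GblupFit:
    mu: float
    variances: dict  # kernel name -> variance, plus "residual"
    blups: dict  # kernel name -> per-individual BLUPs
    kernels: dict  # kernel name -> RelationshipMatrix
    individual_ids: np.ndarray
    log_likelihood: float

    def fitted(self) -> np.ndarray:
        g = np.zeros(len(self.individual_ids))
        for v in self.blups.values():
            g = g + v
        return self.mu + g


def fit_gblup(means: PhenotypeTable, kernels: dict) -> GblupFit:
    """REML fit of y = 1 mu + sum_k g_k + e with g_k ~ N(0, K_k s2_k).

    ``kernels`` maps name -> RelationshipMatrix; all are reindexed to the
    phenotyped individuals.
    """
    if not kernels:
        raise DataError("at least one kernel required")
    ids = means.genotype_ids
    y = means.values_for(ids)
    Ks = {name: K.reindex(list(ids)).values for name, K in kernels.items()}
    names = list(Ks)
    X = np.ones((len(y), 1))
    fit = ai_reml(y, X, [Ks[n] for n in names])
    variances = dict(zip(names, fit.variances[:-1]))
    variances["residual"] = float(fit.variances[-1])
    blups = {n: fit.blup(Ks[n], variances[n]) for n in names}
    return GblupFit(
        mu=float(fit.beta[0]),
        variances=variances,
        blups=blups,
        kernels=dict(kernels),
        individual_ids=np.asarray(ids, dtype=object),
        log_likelihood=fit.loglik,
    )


def predict_new(fit: GblupFit, cross_kernels: dict) -> np.ndarray:
    """Conditional-expectation prediction for new individuals.

    ``cross_kernels`` maps kernel name -> (n_new x n_train) block computed on
    the same marker set and parameters as the training kernels.
    """
    if set(cross_kernels) != set(fit.blups):
        raise DataError("cross-kernel blocks do not match the fitted kernels")
    n_train = len(fit.individual_ids)
    pred = None
    for name, K_nt in cross_kernels.items():
        K_nt = np.atleast_2d(np.asarray(K_nt, dtype=float))
        if K_nt.shape[1] != n_train:
            raise DataError(f"cross kernel {name!r} has wrong training dimension")
        K_tt = fit.kernels[name].reindex(list(fit.individual_ids)).values
        K_reg = K_tt + np.eye(n_train) * RIDGE
        contrib = K_nt @ np.linalg.solve(K_reg, fit.blups[name])
        pred = contrib if pred is None else pred + contrib
    return fit.mu + pred


# ---------------------------------------------------------------------------
# Model kernels
# ---------------------------------------------------------------------------


def build_model_kernels(
    markers: MarkerMatrix, shrink: bool = True, bandwidth: float | str = "median"
) -> dict:
    """The three relationship matrices used by the A / AD / ADE models."""
    design = f_infinity_design(markers, impute=True)
    ka = additive_relationship(design, shrink=shrink)
    kd = dominance_relationship(design, shrink=shrink)
    kg = gaussian_kernel(design, bandwidth=bandwidth)
    return {"additive": ka, "dominance": kd, "gaussian": kg}


def model_kernel_subset(all_kernels: dict, model: str) -> dict:
    if model == "A":
        return {"additive": all_kernels["additive"]}
    if model == "AD":
        return {k: all_kernels[k] for k in ("additive", "dominance")}
    if model == "ADE":
        return {k: all_kernels[k] for k in ("additive", "dominance", "gaussian")}
    raise DataError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    results: pd.DataFrame  # repeat, fold, model, accuracy, n_test
    folds: list  # per repeat: list of test-id lists
    seed: int

    def summary(self) -> pd.DataFrame:
        return (
            self.results.groupby("model")["accuracy"].agg(["mean", "std"]).reset_index()
        )


def crossvalidate(
    means: PhenotypeTable,
    kernels: dict,
    groups: dict,
    h2: float,
    folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    models: tuple = MODELS,
) -> CVReport:
    """Five-fold cross-validation over hybrids: every estimation set keeps
    100% of inbreds and 80% of hybrids; accuracy = Pearson r / sqrt(H2).

    Kernels are computed once on all individuals (marker profiles of unstested
    hybrids are known before phenotyping); only phenotypes are masked.
    """
    from .gwas import hybrid_folds

    ids = list(means.genotype_ids)
    hybrids = np.array([g for g in ids if groups.get(g) == GROUP_HYBRID], dtype=object)
    if len(hybrids) < folds:
        raise DataError("fewer hybrids than folds")
    rng = np.random.default_rng(seed)
    rows = []
    all_folds = []
    for rep in range(n_repeats):
        fold_sets = hybrid_folds(hybrids, folds, rng)
        all_folds.append(fold_sets)
        for f, test_ids in enumerate(fold_sets):
            if len(test_ids) < 3:
                raise DataError("fold smaller than 3")
            test = set(test_ids)
            train_ids = [g for g in ids if g not in test]
            train_means = PhenotypeTable(
                means.records[means.records["genotype_id"].isin(train_ids)].reset_index(
                    drop=True
                ),
                stage=means.stage,
            )
            obs = means.values_for(test_ids)
            for model in models:
                mk = model_kernel_subset(kernels, model)
                fit = fit_gblup(train_means, mk)
                cross = {
                    name: K.reindex(list(test_ids) + train_ids).values[
                        : len(test_ids), len(test_ids):
                    ]
                    for name, K in mk.items()
                }
                pred = predict_new(fit, cross)
                if np.std(pred) == 0 or np.std(obs) == 0:
                    acc = 0.0
                else:
                    acc = float(np.corrcoef(pred, obs)[0, 1]) / np.sqrt(h2)
                rows.append(
                    {
                        "repeat": rep,
                        "fold": f,
                        "model": model,
                        "accuracy": acc,
                        "n_test": len(test_ids),
                    }
                )
    return CVReport(results=pd.DataFrame(rows), folds=all_folds, seed=seed)


def independent_validate(
    train_markers: MarkerMatrix,
    train_means: PhenotypeTable,
    val_markers: MarkerMatrix,
    val_means: PhenotypeTable,
    h2: float,
    models: tuple = MODELS,
    shrink: bool = True,
) -> dict:
    """Fit each model on the training set and predict an independent set of
    hybrids genotyped on the same marker panel; accuracy uses the training
    H2 for standardization."""
    if val_markers.n_individuals == 0:
        raise DataError("empty validation set")
    if not np.array_equal(train_markers.map.marker_id, val_markers.map.marker_id):
        raise DataError("validation marker panel differs from training panel")
    combined = train_markers.concat(val_markers)
    kernels = build_model_kernels(combined, shrink=shrink)
    val_ids = list(val_markers.individual_ids)
    train_ids = list(train_means.genotype_ids)
    obs = val_means.values_for(val_ids)
    out = {}
    for model in models:
        mk_all = model_kernel_subset(kernels, model)
        mk_train = {n: K.reindex(train_ids) for n, K in mk_all.items()}
        fit = fit_gblup(train_means, mk_train)
        cross = {
            n: K.reindex(val_ids + train_ids).values[: len(val_ids), len(val_ids):]
            for n, K in mk_all.items()
        }
        pred = predict_new(fit, cross)
        if np.std(pred) == 0 or np.std(obs) == 0:
            acc = 0.0
        else:
            acc = float(np.corrcoef(pred, obs)[0, 1]) / np.sqrt(h2)
        out[model] = acc
    return out


# ---------------------------------------------------------------------------
# Bayesian variance partition
# ---------------------------------------------------------------------------


def epistasis_design(
    design: DesignMatrices,
    max_pairs: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """All digenic interaction columns (AxA, AxD, DxA, DxD) over marker pairs,
    optionally subsampling pairs to bound memory."""
    m = design.n_markers
    pairs = list(itertools.combinations(range(m), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    cols = []
    A, D = design.A, design.D
    for (i, j) in pairs:
        cols.extend([A[:, i] * A[:, j], A[:, i] * D[:, j], D[:, i] * A[:, j], D[:, i] * D[:, j]])
    X = np.array(cols).T if cols else np.zeros((design.n_individuals, 0))
    keep = X.std(axis=0) > 0
    return X[:, keep]


def _sample_class_effects(rng, Xc, XtX, XXt, r, sigma2_b, sigma2_e):
    """Draw beta_c | rest ~ N(C^-1 X'r / s2e, C^-1), C = X'X/s2e + I/s2b.

    For wide blocks (m > n) the draw uses the Bhattacharya-Dunson identity,
    which only factorizes an n x n system.
    """
    n, m = Xc.shape
    if m <= n:
        C = XtX / sigma2_e + np.eye(m) / sigma2_b
        L = np.linalg.cholesky(C)
        mean = np.linalg.solve(C, Xc.T @ r / sigma2_e)
        z = rng.standard_normal(m)
        return mean + np.linalg.solve(L.T, z)
    u = rng.normal(0.0, np.sqrt(sigma2_b), size=m)
    d = rng.standard_normal(n)
    v = Xc @ u / np.sqrt(sigma2_e) + d
    M = XXt * (sigma2_b / sigma2_e) + np.eye(n)
    w = np.linalg.solve(M, r / np.sqrt(sigma2_e) - v)
    return u + (sigma2_b / np.sqrt(sigma2_e)) * (Xc.T @ w)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over chains x draws."""
    c, n = chains.shape
    half = n // 2
    parts = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    m, n2 = parts.shape
    means = parts.mean(axis=1)
    W = float(np.mean(parts.var(axis=1, ddof=1)))
    B = n2 * float(np.var(means, ddof=1))
    if W <= 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


@dataclass
class VariancePartition:
    shares: dict  # additive, dominance, epistasis -> posterior mean share
    rhat: dict
    warning: str = ""


def bayesian_variance_partition(
    means: PhenotypeTable,
    design: DesignMatrices,
    max_pairs: int | None = 2000,
    n_iter: int = 3000,
    burn: int = 1000,
    thin: int = 2,
    chains: int = 2,
    seed: int = 0,
) -> VariancePartition:
    """Gibbs sampler for y = 1 mu + Xa ba + Xd bd + Xe be + e with ridge-type
    normal priors per effect class; reports the posterior mean of each
    class's share of the genetic variance (shares sum to 1)."""
    ids = means.genotype_ids
    y = means.values_for(ids)
    d = design.reindex(list(ids))
    Xa = d.A - d.A.mean(axis=0)
    Xd = d.D - d.D.mean(axis=0)
    Xe = epistasis_design(d, max_pairs=max_pairs, seed=seed)
    Xe = Xe - Xe.mean(axis=0)
    blocks = {"additive": Xa, "dominance": Xd, "epistasis": Xe}
    blocks = {k: v for k, v in blocks.items() if v.shape[1] > 0}
    XtXs = {k: (v.T @ v if v.shape[1] <= v.shape[0] else None) for k, v in blocks.items()}
    XXts = {k: (v @ v.T if v.shape[1] > v.shape[0] else None) for k, v in blocks.items()}
    n = len(y)
    vy = float(np.var(y))
    nu0, s0 = 4.0, vy / 2.0
    keep_draws = {k: [] for k in blocks}
    for chain in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(chain,)))
        betas = {k: np.zeros(v.shape[1]) for k, v in blocks.items()}
        s2b = {k: vy / max(v.shape[1], 1) for k, v in blocks.items()}
        s2e = vy / 2.0
        mu = float(np.mean(y))
        draws = {k: [] for k in blocks}
        for it in range(n_iter):
            gvals = {k: blocks[k] @ betas[k] for k in blocks}
            g_all = sum(gvals.values())
            # mu | rest
            mu = rng.normal(float(np.mean(y - g_all)), np.sqrt(s2e / n))
            for k in blocks:
                r = y - mu - (g_all - gvals[k])
                betas[k] = _sample_class_effects(
                    rng, blocks[k], XtXs[k], XXts[k], r, s2b[k], s2e
                )
                gvals[k] = blocks[k] @ betas[k]
                g_all = sum(gvals.values())
                mk = blocks[k].shape[1]
                s2b[k] = (nu0 * s0 / mk + float(betas[k] @ betas[k])) / rng.chisquare(nu0 + mk)
            resid = y - mu - g_all
            s2e = (nu0 * s0 + float(resid @ resid)) / rng.chisquare(nu0 + n)
            if it >= burn and (it - burn) % thin == 0:
                total = sum(float(np.var(gvals[k])) for k in blocks)
                for k in blocks:
                    draws[k].append(float(np.var(gvals[k])) / max(total, 1e-300))
        for k in blocks:
            keep_draws[k].append(draws[k])
    shares = {}
    rhat = {}
    for k in blocks:
        arr = np.array(keep_draws[k])
        shares[k] = float(arr.mean())
        rhat[k] = _split_rhat(arr) if chains > 1 else 1.0
    for k in ("additive", "dominance", "epistasis"):
        shares.setdefault(k, 0.0)
        rhat.setdefault(k, 1.0)
    total = sum(shares.values())
    shares = {k: v / total for k, v in shares.items()}
    warning = ""
    if any(r > 1.1 for r in rhat.values()):
        warning = f"chains may not have mixed: split-Rhat {rhat}"
        warnings.warn(warning)
    return VariancePartition(shares=shares, rhat=rhat, warning=warning)
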