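"""Relationship and similarity matrices.

Four kinds are supported: kinship as one minus Rogers' distance, additive and
dominance relationship matrices from centered F-infinity design columns
(optionally with linear shrinkage toward their diagonal), and a Gaussian
kernel on the stacked additive+dominance codes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import (
    DataError,
    DesignMatrices,
    KIND_ADDITIVE,
    KIND_DOMINANCE,
    KIND_GAUSSIAN,
    KIND_KINSHIP,
    MarkerMatrix,
    RelationshipMatrix,
)

RIDGE = 1e-6  # stabilizer used by solvers at factorization time, not stored


def rogers_kinship(markers: MarkerMatrix) -> RelationshipMatrix:
    """K = 1 - Rogers' distance.

    Per locus, individuals are summarized by allele frequencies (homozygote
    (1,0) or (0,1), heterozygote (1/2,1/2)); the per-locus distance is
    sqrt(0.5 * sum_alleles (p_i - p_j)^2) and distances average over loci.
    With codes c in {-1,0,1}, p(+allele) = (c+1)/2 and the per-locus distance
    reduces to |c_i - c_j| / 2.
    """
    if markers.n_markers == 0:
        raise DataError("zero markers")
    codes = markers.codes
    if np.isnan(codes).any():
        from .genotype import impute_marker_means

        codes = impute_marker_means(markers).codes
    # mean over loci of |ci - cj| / 2
    D = squareform(pdist(codes, metric="cityblock")) / (2.0 * markers.n_markers)
    K = 1.0 - D
    return RelationshipMatrix(K, KIND_KINSHIP, markers.individual_ids)


def _shrinkage_delta(Xc: np.ndarray, S: np.ndarray) -> float:
    """Closed-form linear-shrinkage intensity toward the diagonal target.

    delta* = sum_ij Var(S_ij) / sum_{i!=j} S_ij^2, clipped to [0, 1]; the
    sampling variance of each crossproduct entry is estimated from the
    per-marker products (Ledoit-Wolf style, markers as the sampling units).
    """
    n, m = Xc.shape
    if m < 2:
        return 0.0
    # S = Xc Xc' / m ; entry (i,j) is the mean over markers of x_im x_jm
    # var-hat of the mean = var over markers / m
    sq = (Xc**2) @ (Xc**2).T / m  # mean of (x_im x_jm)^2
    var_hat = (sq - S**2) / m
    off = ~np.eye(n, dtype=bool)
    num = float(np.sum(var_hat[off]))
    den = float(np.sum(S[off] ** 2))
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def _crossproduct_relationship(
    X: np.ndarray,
    ids: np.ndarray,
    kind: str,
    shrink: bool,
    delta: float | None = None,
) -> RelationshipMatrix:
    n, m = X.shape
    if n < 2:
        raise DataError("fewer than 2 individuals")
    Xc = X - X.mean(axis=0, keepdims=True)
    S = Xc @ Xc.T / max(m, 1)
    if shrink:
        d = _shrinkage_delta(Xc, S) if delta is None else float(np.clip(delta, 0.0, 1.0))
        target = np.diag(np.diag(S))
        S = (1.0 - d) * S + d * target
    c = np.trace(S) / n
    if c <= 0:
        raise DataError(f"no {kind} variation")
    return RelationshipMatrix(S / c, kind, ids)


def additive_relationship(
    design: DesignMatrices, shrink: bool = True, delta: float | None = None
) -> RelationshipMatrix:
    """G_a from centered additive codes, normalized to mean diagonal 1."""
    return _crossproduct_relationship(design.A, design.individual_ids, KIND_ADDITIVE, shrink, delta)


def dominance_relationship(
    design: DesignMatrices, shrink: bool = True, delta: float | None = None
) -> RelationshipMatrix:
    """G_d from centered dominance indicators, normalized to mean diagonal 1."""
    if np.allclose(design.D, design.D.mean(axis=0, keepdims=True)):
        raise DataError("no dominance variation")
    return _crossproduct_relationship(design.D, design.individual_ids, KIND_DOMINANCE, shrink, delta)


def gaussian_kernel(
    design: DesignMatrices, bandwidth: float | str = "median"
) -> RelationshipMatrix:
    """K(i,j) = exp(-d^2_ij / q), squared Euclidean distance on the stacked
    (A, D) codes; bandwidth "median" sets q to the median off-diagonal d^2."""
    X = np.hstack([design.A, design.D])
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    if isinstance(bandwidth, str):
        if bandwidth != "median":
            raise DataError(f"unknown bandwidth rule {bandwidth!r}")
        offd = d2[~np.eye(len(d2), dtype=bool)]
        q = float(np.median(offd))
        if q <= 0:
            raise DataError("degenerate bandwidth: all individuals identical")
    else:
        q = float(bandwidth)
        if q <= 0:
            raise DataError("bandwidth must be positive")
    K = np.exp(-d2 / q)
    return RelationshipMatrix(K, KIND_GAUSSIAN, design.individual_ids)


def cross_gaussian(
    design_new: DesignMatrices, design_train: DesignMatrices, bandwidth: float
) -> np.ndarray:
    """Gaussian cross-kernel rows linking new to training individuals (the
    bandwidth must be the training kernel's realized q)."""
    Xn = np.hstack([design_new.A, design_new.D])
    Xt = np.hstack([design_train.A, design_train.D])
    d2 = (
        np.sum(Xn**2, axis=1)[:, None]
        + np.sum(Xt**2, axis=1)[None, :]
        - 2.0 * Xn @ Xt.T
    )
    return np.exp(-np.maximum(d2, 0.0) / bandwidth)


def realized_bandwidth(design: DesignMatrices) -> float:
    """The q chosen by the "median" rule for this design."""
    X = np.hstack([design.A, design.D])
    d2 = pdist(X, metric="sqeuclidean")
    q = float(np.median(d2))
    if q <= 0:
        raise DataError("degenerate bandwidth: all individuals identical")
    return q
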