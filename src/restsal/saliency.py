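"""Gradient saliencies and their propagation to derived measures.

The saliency of a session is the gradient of the model's scalar output with
respect to the input series, with per-region standardization kept inside the
differentiable graph. Propagating through standardization projects out the
mean and the component along the data, so per region the saliency sums to
zero over time and is orthogonal to the standardized series — average
saliency is uninformative by construction, and model reliance is summarized
by the *temporal variance* of saliency, sum_t s_t^2 / (T-1).

Three downstream constructions are provided:

* saliency-defined networks: for each distinct resting-state-network size M,
  the top-M regions by training-fold mean saliency temporal variance (nested
  by construction); these are the sets ablated on validation data;
* connectivity perturbation: moving the data along the saliency direction,
  X -> X + eta D, changes the correlation matrix C = X^T X/(T-1) to first
  order by delta C = eta (D^T X + X^T D)/(T-1); the eta-free direction is
  reported, aggregated across subjects/sessions, and its strongest effects
  are categorized by the sign of the underlying correlation and of the
  change (IMPC/DMPC/DMNC/IMNC);
* whitened-innovation saliency: under X = Z W with Z = U V^T from the SVD of
  X (zero-phase component analysis) and W = V diag(s) V^T, the directional
  derivative dZ along the saliency is computed through the matrix-square-root
  differential, separating reliance on instantaneous innovations from
  reliance mediated by functional connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import RegionTimeseries
from .rnn import EnsembleParams, input_gradients

__all__ = [
    "SaliencyTensor",
    "FCSaliency",
    "ZCAFactorization",
    "input_saliency",
    "saliency_temporal_variance",
    "build_saliency_networks",
    "fc_saliency",
    "aggregate_fc_saliency",
    "zca",
    "zca_saliency",
]


@dataclass
class SaliencyTensor:
    """T x R gradient of the scalar output w.r.t. the pre-standardization
    input; per region it sums to zero over time and is orthogonal to the
    standardized series."""

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    provenance: str = ""

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


def _through_standardization(G: np.ndarray, z: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Chain rule through per-column standardization.

    G is the gradient w.r.t. the standardized series z; returns the gradient
    w.r.t. the raw series. Per column: (G - mean(G) - z <G,z>/(T-1)) / sd.
    """
    T = z.shape[0]
    proj = (G * z).sum(axis=0) / (T - 1)
    return (G - G.mean(axis=0) - z * proj) / sd


def input_saliency(
    params: EnsembleParams,
    session: RegionTimeseries | np.ndarray,
    standardized: bool = False,
    member: int | None = None,
    ddof: int = 1,
) -> SaliencyTensor:
    """Exact gradient of the session's scalar output w.r.t. the raw series.

    ``session`` is either the decimated-but-raw series (``standardized=False``;
    standardization is applied internally and differentiated through) or an
    already standardized one (``standardized=True``; the projection is still
    applied, with unit scale). The ensemble saliency is the mean of member
    saliencies (the ensemble output is the mean of member outputs); pass
    ``member`` for a single member's tensor.
    """
    if isinstance(session, RegionTimeseries):
        X = session.values
        region_ids = list(session.region_ids)
    else:
        X = np.asarray(session, dtype=float)
        region_ids = [f"r{i:03d}" for i in range(X.shape[1])]
    if standardized:
        z = X
        sd = np.ones(X.shape[1])
    else:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=ddof)
        if np.any(sd == 0):
            bad = region_ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"zero-variance region: {bad}")
        z = (X - mean) / sd
    p = params if member is None else params.members(member)
    G = input_gradients(p.astype(np.float64), z[None].astype(np.float64))
    G = G.mean(axis=0)[0]  # ensemble saliency = mean member saliency
    vals = _through_standardization(G, z, sd)
    who = "ensemble" if member is None else f"member {member}"
    return SaliencyTensor(values=vals, region_ids=region_ids, provenance=who)


def mean_saliency_variance(
    params: EnsembleParams, X: np.ndarray, chunk: int = 128
) -> np.ndarray:
    """Mean per-region saliency temporal variance over standardized sessions.

    X holds standardized sessions, shape (N, T, R). For each session the
    ensemble saliency (mean member input gradient, projected through
    standardization) is reduced to its temporal variance; the mean map over
    sessions is returned. Processing is chunked to bound memory.
    """
    X = np.asarray(X)
    N, T, R = X.shape
    acc = np.zeros(R)
    for start in range(0, N, chunk):
        Z = X[start : start + chunk]
        G = input_gradients(params, Z).mean(axis=0)  # ensemble mean, (B,T,R)
        Z = np.asarray(Z, dtype=G.dtype)
        proj = (G * Z).sum(axis=1, keepdims=True) / (T - 1)
        sal = G - G.mean(axis=1, keepdims=True) - Z * proj
        acc += (sal**2).sum(axis=(0, 1)) / (T - 1)
    return acc / N


def saliency_temporal_variance(sal: SaliencyTensor | np.ndarray) -> np.ndarray:
    """Per-region temporal variance of saliency: sum_t s_t^2 / (T-1).

    The temporal mean of a saliency column is zero by construction, so this
    equals the sample variance with divisor T-1.
    """
    vals = sal.values if isinstance(sal, SaliencyTensor) else np.asarray(sal)
    T = vals.shape[0]
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    return (vals**2).sum(axis=0) / (T - 1)


def build_saliency_networks(
    variance_map: np.ndarray,
    sizes,
    region_ids: list[str] | None = None,
) -> dict[int, list]:
    """Top-M regions by mean saliency temporal variance, per unique size.

    ``sizes`` are the resting-state-network sizes of the partition (an
    iterable of ints, or a NetworkPartition); duplicate sizes collapse, so 14
    networks with two repeated sizes yield 12 saliency-defined sets. Smaller
    sets are subsets of bigger ones by construction. Ties are broken by
    region order (stable sort, variance descending).
    """
    var = np.asarray(variance_map, dtype=float)
    if hasattr(sizes, "sizes"):
        sizes = list(sizes.sizes().values())
    uniq = sorted(set(int(m) for m in sizes))
    if uniq and uniq[-1] > var.size:
        raise ValueError("a requested size exceeds the number of regions")
    if uniq and uniq[0] < 1:
        raise ValueError("sizes must be positive")
    order = np.lexsort((np.arange(var.size), -var))
    out: dict[int, list] = {}
    for m in uniq:
        top = order[:m]
        out[m] = [region_ids[i] for i in top] if region_ids else [int(i) for i in top]
    return out


@dataclass
class FCSaliency:
    """Aggregated connectivity-perturbation direction across samples."""

    mean: np.ndarray  # R x R mean delta-C direction
    sd: np.ndarray  # R x R standard deviation across samples
    mean_c: np.ndarray  # R x R mean correlation
    categories: pd.DataFrame  # top-effect pairs with category labels


def fc_saliency(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    """First-order connectivity change direction (D^T X + X^T D)/(T-1).

    X is one standardized session, D its saliency tensor. The result is the
    eta-free direction of the correlation-matrix perturbation induced by
    moving the data along the saliency; it is symmetric and linear in D.
    """
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    if X.shape != D.shape:
        raise ValueError("X and D must have the same shape")
    T = X.shape[0]
    return (D.T @ X + X.T @ D) / (T - 1)


_CATEGORY = {
    (1, 1): "IMPC",  # positive correlation, increasing magnitude
    (1, -1): "DMPC",  # positive correlation, decreasing magnitude
    (-1, 1): "DMNC",  # negative correlation, decreasing magnitude
    (-1, -1): "IMNC",  # negative correlation, increasing magnitude
}


def aggregate_fc_saliency(
    samples,
    region_ids: list[str] | None = None,
    top_fraction: float = 0.05,
) -> FCSaliency:
    """Aggregate per-sample (X, D) pairs into mean/SD delta-C and categories.

    ``samples`` yields (X, D) pairs (standardized session, saliency tensor).
    Pairs in the top ``top_fraction`` of |mean/SD| are categorized by the
    signs of the mean correlation and of the mean connectivity change:
    IMPC/DMPC for positive correlations whose magnitude increases/decreases
    with the trait estimate, IMNC/DMNC likewise for negative correlations.
    """
    dcs, cs = [], []
    for X, D in samples:
        X = np.asarray(X, dtype=float)
        dcs.append(fc_saliency(X, D))
        cs.append((X.T @ X) / (X.shape[0] - 1))
    dC = np.stack(dcs)
    mean = dC.mean(axis=0)
    sd = dC.std(axis=0, ddof=1) if dC.shape[0] > 1 else np.ones_like(mean)
    mean_c = np.stack(cs).mean(axis=0)
    R = mean.shape[0]
    iu = np.triu_indices(R, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs(mean[iu]) / np.where(sd[iu] > 0, sd[iu], np.inf)
    n_top = max(1, int(np.ceil(top_fraction * score.size)))
    top = np.argsort(-score, kind="stable")[:n_top]
    rows = []
    ids = region_ids or [f"r{i:03d}" for i in range(R)]
    for t in top:
        i, j = int(iu[0][t]), int(iu[1][t])
        cat = _CATEGORY.get(
            (int(np.sign(mean_c[i, j])) or 1, int(np.sign(mean[i, j])) or 1), "none"
        )
        rows.append(
            {
                "region_i": ids[i],
                "region_j": ids[j],
                "mean": mean[i, j],
                "sd": sd[i, j],
                "mean_c": mean_c[i, j],
                "category": cat,
            }
        )
    return FCSaliency(
        mean=mean, sd=sd, mean_c=mean_c, categories=pd.DataFrame(rows)
    )


@dataclass
class ZCAFactorization:
    """Thin SVD X = U diag(s) V^T with Z = U V^T and W = V diag(s) V^T.

    Z has orthonormal columns scaled so Z^T Z = I; X = Z W reconstructs the
    data; W is the symmetric PSD square root of X^T X, i.e. sqrt(T-1) times
    the square root of the correlation matrix of a standardized session.
    """

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray
    Z: np.ndarray
    W: np.ndarray


def zca(X: np.ndarray) -> ZCAFactorization:
    """Zero-phase component analysis of one standardized session.

    Sign convention: each column of V is flipped so its largest-magnitude
    entry is positive, making Z deterministic across platforms.
    """
    X = np.asarray(X, dtype=float)
    T, R = X.shape
    if T <= R:
        raise ValueError("need more timepoints than regions (T > R)")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] <= 1e-10 * s[0]:
        raise np.linalg.LinAlgError(
            f"rank-deficient input: smallest singular value {s[-1]:.3e}"
        )
    V = Vt.T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(R)])
    flip[flip == 0] = 1.0
    U = U * flip
    V = V * flip
    Z = U @ V.T
    W = (V * s) @ V.T
    return ZCAFactorization(U=U, s=s, V=V, Z=Z, W=W)


def zca_saliency(
    X: np.ndarray, D: np.ndarray, gap_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Directional derivative of Z(X) along the saliency D, plus its
    per-region temporal variance sum_t dZ^2 / (T-1).

    Writing A = (X^T X)^{1/2} (so Z = X A^{-1}), dA solves the Sylvester
    equation dA A + A dA = D^T X + X^T D, diagonal in the right singular
    basis; then dZ = D A^{-1} - Z dA A^{-1}. When consecutive singular values
    are closer than ``gap_tol * s_max`` a warning is issued and a central
    finite difference is used instead.
    """
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    if X.shape != D.shape:
        raise ValueError("X and D must have the same shape")
    f = zca(X)
    s, V = f.s, f.V
    T = X.shape[0]
    if np.diff(s).size and np.min(np.abs(np.diff(s))) < gap_tol * s[0]:
        warnings.warn(
            "nearly-degenerate singular values; using finite differences",
            RuntimeWarning,
            stacklevel=2,
        )
        eta = 1e-6 * s[0] / max(np.abs(D).max(), 1e-30)
        dZ = (zca(X + eta * D).Z - zca(X - eta * D).Z) / (2 * eta)
    else:
        dM = D.T @ X + X.T @ D
        B = V.T @ dM @ V
        dA = V @ (B / (s[:, None] + s[None, :])) @ V.T
        Ainv = (V / s) @ V.T
        dZ = D @ Ainv - f.Z @ dA @ Ainv
    var = (dZ**2).sum(axis=0) / (T - 1)
    return dZ, var
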