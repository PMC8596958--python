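"""Elastic-net prediction of the trait from session-averaged connectivity.

The comparison model: Pearson-correlation functional connectivity is computed
per session, the upper triangle (row-major, i < j) is vectorized and averaged
across sessions, features are filtered univariately on training data (two-
sided correlation test, configurable p threshold), and an elastic net with
the L1/L2 balance fixed near the ridge end (l1_ratio = 0.05) is fitted over a
50-point penalty grid selected by inner 3-fold cross-validation on training
data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

__all__ = [
    "RSFCFeatures",
    "BaselineModel",
    "compute_rsfc",
    "fit_baseline",
    "predict_baseline",
]


@dataclass
class RSFCFeatures:
    """Vectorized upper-triangle correlations, averaged across sessions."""

    values: np.ndarray  # (R(R-1)/2,)
    pairs: np.ndarray  # (R(R-1)/2, 2) region index pairs, i < j
    region_ids: list[str]


def compute_rsfc(sessions, region_ids=None) -> RSFCFeatures:
    """Session-mean Pearson-correlation features.

    ``sessions`` is an iterable of (T, R) arrays (standardized or not;
    correlation is scale-free). Raises if any region has zero variance.
    """
    sessions = [np.asarray(s, dtype=float) for s in sessions]
    if not sessions:
        raise ValueError("need at least one session")
    R = sessions[0].shape[1]
    iu = np.triu_indices(R, k=1)
    acc = np.zeros(iu[0].size)
    for s in sessions:
        sd = s.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            name = region_ids[bad] if region_ids else f"column {bad}"
            raise ValueError(f"zero-variance region: {name}")
        acc += np.corrcoef(s, rowvar=False)[iu]
    if region_ids is None:
        region_ids = [f"r{i:03d}" for i in range(R)]
    return RSFCFeatures(
        values=acc / len(sessions),
        pairs=np.column_stack(iu),
        region_ids=list(region_ids),
    )


@dataclass
class BaselineModel:
    selected: np.ndarray  # boolean mask over features
    estimator: ElasticNet
    filter_p: float
    alpha_: float
    alphas: np.ndarray
    inner_mse: np.ndarray  # mean inner-CV MSE per penalty


def _univariate_filter(F: np.ndarray, y: np.ndarray, p_threshold: float) -> np.ndarray:
    n = y.size
    yc = y - y.mean()
    Fc = F - F.mean(axis=0)
    denom = np.sqrt((Fc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Fc.T @ yc / denom, 0.0)
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p < p_threshold


def fit_baseline(
    features: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.05,
    n_lambda: int = 50,
    inner_k: int = 3,
    filter_p: float = 0.01,
    seed: int = 0,
) -> BaselineModel:
    """Fit the filtered elastic net on training data only.

    The penalty grid is log-spaced over four decades down from lambda_max
    (the smallest penalty zeroing every coefficient at the given l1_ratio).
    The inner CV re-applies the univariate filter inside every inner training
    split before scoring the penalty, so the penalty choice is never informed
    by inner-validation rows (a filter fitted once on the whole training fold
    would leak its spurious selections into the inner score and systematically
    favour light penalties). Ties in inner MSE go to the heavier penalty.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if F.ndim != 2 or F.shape[0] != y.size:
        raise ValueError("features must be (n_subjects, n_features) matching y")
    mask = _univariate_filter(F, y, filter_p)
    if not mask.any():
        raise ValueError(
            f"no features pass the univariate filter at p<{filter_p}; "
            "raise filter_p"
        )
    n = y.size
    yc = y - y.mean()
    lam_max = np.abs(F[:, mask].T @ yc).max() / (n * max(l1_ratio, 1e-2))
    alphas = np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, n_lambda)
    ratio = max(l1_ratio, 1e-9)

    kf = KFold(n_splits=inner_k, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    mse = np.zeros(n_lambda)
    for tr, va in kf.split(F):
        m_tr = _univariate_filter(F[tr], y[tr], filter_p)
        y_mean = y[tr].mean()
        if not m_tr.any():
            mse += np.mean((y[va] - y_mean) ** 2)
            continue
        Xtr = F[np.ix_(tr, np.flatnonzero(m_tr))]
        x_mean = Xtr.mean(axis=0)
        _, coefs, _ = enet_path(
            Xtr - x_mean, y[tr] - y_mean, l1_ratio=ratio, alphas=alphas,
            max_iter=5000,
        )
        Xva = F[np.ix_(va, np.flatnonzero(m_tr))] - x_mean
        preds = Xva @ coefs + y_mean  # (n_va, n_lambda)
        mse += ((preds - y[va][:, None]) ** 2).mean(axis=0)
    mse /= inner_k
    # alphas are descending; argmin takes the first (heaviest) tie
    best = float(alphas[int(np.argmin(mse))])
    est = ElasticNet(alpha=best, l1_ratio=ratio, max_iter=5000)
    est.fit(F[:, mask], y)
    return BaselineModel(
        selected=mask,
        estimator=est,
        filter_p=filter_p,
        alpha_=best,
        alphas=alphas,
        inner_mse=mse,
    )


def predict_baseline(model: BaselineModel, features: np.ndarray) -> np.ndarray:
    F = np.asarray(features, dtype=float)
    return model.estimator.predict(F[:, model.selected])
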