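"""Region-set ablation with a size-matched resampling null.

Ablation zero-fills the chosen regions' standardized columns (zero is the
post-standardization mean, so this removes the regions' information with
minimal distribution shift) on *validation* data and measures the paired-T
degradation of the cross-validated metric across folds. Because region sets
differ in size, an observed statistic is referred to a null distribution of
statistics from ablating random sets of the same cardinality; empirical
p-values use the +1 correction p = (1 + #{t_null >= t_obs}) / (n_iter + 1),
one-sided in the degradation direction. Multiple comparisons across the sets
tested in one analysis are corrected by FDR — Benjamini-Yekutieli by default,
Benjamini-Hochberg available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cv import CVResult, evaluate, predict_subjects
from .preprocess import RegionTimeseries

__all__ = [
    "AblationResult",
    "NullDistribution",
    "ablate_regions",
    "ablation_test",
    "resample_null",
    "calibration_pvalues",
    "empirical_p",
    "fdr_adjust",
]

T_CAP = 1e6  # reported in place of an infinite paired-T (zero-variance deltas)


def ablate_regions(series: RegionTimeseries, region_set) -> RegionTimeseries:
    """Zero-fill the listed regions' columns of a standardized session."""
    ids = list(series.region_ids)
    idx = []
    for r in region_set:
        if r not in ids:
            raise KeyError(f"unknown region label: {r}")
        idx.append(ids.index(r))
    out = series.values.copy()
    out[:, idx] = 0.0
    return RegionTimeseries(
        out, tr=series.tr, region_ids=ids, duration=series.duration
    )


@dataclass
class AblationResult:
    region_sets: list[list[int]]  # per fold, region column indices
    per_fold_baseline: np.ndarray
    per_fold_ablated: np.ndarray
    t_stat: float
    flag: str = ""
    p_empirical: float | None = None
    q_fdr: float | None = None

    @property
    def deltas(self) -> np.ndarray:
        return self.per_fold_baseline - self.per_fold_ablated


@dataclass
class NullDistribution:
    set_size: int
    n_iter: int
    t_values: np.ndarray
    seed: int


def _paired_t(deltas: np.ndarray) -> tuple[float, str]:
    k = deltas.size
    mean = deltas.mean()
    sd = deltas.std(ddof=1)
    scale = max(np.abs(deltas).max(), 1.0)
    if np.abs(deltas).max() < 1e-14:
        return 0.0, "no_effect"
    if sd < 1e-14 * scale:
        return float(np.sign(mean) * T_CAP), "degenerate_variance"
    return float(mean / (sd / np.sqrt(k))), ""


def _normalize_sets(cv_result: CVResult, region_sets) -> list[list[int]]:
    """Accept one set (shared by folds) or one per fold; labels or indices."""
    region_ids = None
    for s in cv_result.subjects:
        region_ids = getattr(s, "region_ids", None)
        break
    k = len(cv_result.folds)

    def to_idx(one_set) -> list[int]:
        out = []
        for r in one_set:
            if isinstance(r, (int, np.integer)):
                out.append(int(r))
            else:
                if region_ids is None:
                    raise KeyError(f"region labels unavailable; pass indices ({r})")
                out.append(region_ids.index(r))
        return out

    if len(region_sets) == k and region_sets and isinstance(
        region_sets[0], (list, tuple, np.ndarray)
    ):
        return [to_idx(s) for s in region_sets]
    return [to_idx(region_sets)] * k


def ablation_test(
    cv_result: CVResult, region_sets, metric: str = "r2"
) -> AblationResult:
    """Paired-T degradation from ablating a region set on validation folds.

    ``region_sets`` is either a single set of region column indices (or
    labels) applied in every fold, or a list with one set per fold (the
    cross-validated, saliency-defined case). Positive t means degradation.
    """
    folds = cv_result.folds
    if len(folds) < 3:
        raise ValueError("need at least 3 folds for a paired T statistic")
    sets = _normalize_sets(cv_result, region_sets)
    base = np.array([getattr(f.metrics, metric) for f in folds])
    abl = np.empty(len(folds))
    for i, (fr, one_set) in enumerate(zip(folds, sets)):
        if one_set:
            yhat = predict_subjects(
                fr.members, cv_result.subjects, fr.val_idx, ablate_idx=one_set
            )
            abl[i] = getattr(evaluate(fr.y_val, yhat), metric)
        else:
            abl[i] = base[i]
    t, flag = _paired_t(base - abl)
    return AblationResult(
        region_sets=sets,
        per_fold_baseline=base,
        per_fold_ablated=abl,
        t_stat=t,
        flag=flag,
    )


def resample_null(
    cv_result: CVResult,
    set_size: int,
    n_iter: int = 300,
    seed: int = 0,
    metric: str = "r2",
) -> NullDistribution:
    """Null distribution of paired-T statistics from random same-size sets."""
    n_regions = cv_result.subjects[0].sessions.shape[-1]
    if not 1 <= set_size <= n_regions:
        raise ValueError("set_size must lie in [1, n_regions]")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    ts = np.empty(n_iter)
    for it in range(n_iter):
        subset = rng.choice(n_regions, size=set_size, replace=False)
        ts[it] = ablation_test(cv_result, list(subset), metric=metric).t_stat
    return NullDistribution(set_size=set_size, n_iter=n_iter, t_values=ts, seed=seed)


def calibration_pvalues(
    cv_result: CVResult,
    set_size: int,
    n_draws: int = 200,
    n_iter: int = 50,
    seed: int = 0,
    metric: str = "r2",
) -> np.ndarray:
    """Empirical p-values for randomly drawn ablation sets, each referred to
    its own freshly resampled size-matched null.

    This is the calibration experiment: on a model trained against targets
    that carry no signal, the observed set is exchangeable with its null
    sets, so the returned p-values are discrete-uniform on {1,..,n_iter+1}/
    (n_iter+1). Sharing one null pool across draws would bias every p-value
    coherently by the pool's sampling error, so each draw gets its own pool;
    to make that affordable all folds are evaluated in a single stacked
    forward pass, which requires a balanced design (equal validation counts
    and session counts across folds).
    """
    folds = cv_result.folds
    subjects = cv_result.subjects
    k = len(folds)
    m_per = folds[0].members.n_members
    val_counts = {len(f.val_idx) for f in folds}
    sess_counts = {
        subjects[i].sessions.shape[0] for f in folds for i in f.val_idx
    }
    if len(val_counts) != 1 or len(sess_counts) != 1:
        raise ValueError("calibration requires a balanced fold/session design")
    n_sess = sess_counts.pop()
    from .rnn import EnsembleParams, forward_batch

    stacked = EnsembleParams.stack([f.members for f in folds])
    # per-fold session tensors, repeated so each member sees its own fold
    fold_x = [
        np.concatenate([subjects[i].sessions for i in f.val_idx]) for f in folds
    ]
    Xmem = np.stack([fold_x[f] for f in range(k) for _ in range(m_per)])
    Xmem = Xmem.astype(stacked.arrays["head_w"].dtype)
    base = np.array([getattr(f.metrics, metric) for f in folds])
    y_val = [f.y_val for f in folds]
    n_regions = Xmem.shape[-1]

    def t_for(region_idx: np.ndarray) -> float:
        Xa = Xmem.copy()
        Xa[..., region_idx] = 0.0
        preds, _ = forward_batch(stacked, Xa)  # (k*m_per, B)
        deltas = np.empty(k)
        for f in range(k):
            per_sess = preds[f * m_per : (f + 1) * m_per].mean(axis=0)
            yhat = per_sess.reshape(-1, n_sess).mean(axis=1)
            deltas[f] = base[f] - getattr(evaluate(y_val[f], yhat), metric)
        return _paired_t(deltas)[0]

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 37])
    pvals = np.empty(n_draws)
    for d in range(n_draws):
        t_obs = t_for(rng.choice(n_regions, size=set_size, replace=False))
        exceed = 0
        for _ in range(n_iter):
            if t_for(rng.choice(n_regions, size=set_size, replace=False)) >= t_obs:
                exceed += 1
        pvals[d] = (1 + exceed) / (n_iter + 1)
    return pvals


def empirical_p(t_obs: float, null: NullDistribution) -> float:
    """One-sided (degradation direction) resampling p with +1 correction."""
    if null.t_values.size == 0:
        raise ValueError("empty null distribution")
    return float(
        (1 + np.count_nonzero(null.t_values >= t_obs)) / (null.t_values.size + 1)
    )


def fdr_adjust(p_list, method: str = "by") -> np.ndarray:
    """FDR-adjusted q-values; method 'by' (Benjamini-Yekutieli, the Methods
    default here) or 'bh' (Benjamini-Hochberg)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    key = {"by": "fdr_by", "bh": "fdr_bh"}.get(method.lower())
    if key is None:
        raise ValueError("method must be 'by' or 'bh'")
    _, q, _, _ = multipletests(p, method=key)
    return q
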