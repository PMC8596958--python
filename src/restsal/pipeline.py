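"""End-to-end orchestration helpers.

Glue between the generator, preprocessing and the cross-validation engine:
`prepare_cohort` turns a simulated (or loaded) cohort into standardized,
decimated session tensors; `desk_study` runs the full desk-scale study —
cohort generation, preprocessing, family-stratified folds and per-fold
ensemble training — with one seed controlling everything; the saliency
helpers produce cross-validated saliency maps and the saliency-defined
network ablation comparison against size-matched random sets.
"""

from __future__ import annotations

import numpy as np

from .ablation import ablation_test
from .cv import CVResult, FoldSpec, PreparedSubject, _session_stack, make_folds, run_cv
from .preprocess import bandpass_decimate, standardize
from .rnn import ArchitectureSpec, TrainingConfig
from .saliency import build_saliency_networks, mean_saliency_variance
from .synthdata import Cohort, CohortConfig, make_partition, simulate_cohort

__all__ = [
    "prepare_cohort",
    "desk_study",
    "desk_partition",
    "fold_saliency_maps",
    "validation_saliency_map",
    "saliency_network_power",
]

DESK_NETWORK_SIZES = [3, 5, 8, 10, 14, 20]  # heterogeneous, like real RSNs


def desk_partition(n_regions: int = 60, seed: int = 0):
    """Desk-scale region->network partition with heterogeneous sizes."""
    if n_regions == sum(DESK_NETWORK_SIZES):
        return make_partition(n_regions, sizes=DESK_NETWORK_SIZES, seed=seed)
    return make_partition(n_regions, n_networks=max(2, n_regions // 6), seed=seed)


def prepare_cohort(
    cohort: Cohort, f_low: float = 0.008, f_high: float = 0.09
) -> list[PreparedSubject]:
    """Band-pass + decimate + standardize every session of every subject."""
    prepared = []
    for subj in cohort.subjects:
        sessions = [
            standardize(bandpass_decimate(s, f_low, f_high)).values
            for s in subj.sessions
        ]
        prepared.append(
            PreparedSubject(
                subject_id=subj.subject_id,
                family_id=subj.family_id,
                g=subj.g,
                confounds=np.asarray(subj.confounds, dtype=float),
                sessions=np.stack(sessions),
                region_ids=list(cohort.region_ids),
            )
        )
    return prepared


def desk_study(
    seed: int = 0,
    n_subjects: int = 300,
    arch: ArchitectureSpec | None = None,
    train_config: TrainingConfig | None = None,
    cohort_overrides: dict | None = None,
    k_folds: int = 10,
) -> tuple[Cohort, list[PreparedSubject], FoldSpec, CVResult]:
    """Run the scaled-down study end to end, fully determined by ``seed``."""
    overrides = dict(cohort_overrides or {})
    config = CohortConfig.desk_scale(n_subjects=n_subjects, seed=seed, **overrides)
    partition = desk_partition(config.n_regions, seed=seed)
    cohort = simulate_cohort(config, partition)
    prepared = prepare_cohort(cohort)
    folds = make_folds(prepared, k=k_folds, seed=seed)
    if arch is None:
        arch = ArchitectureSpec.desk_scale(input_dim=config.n_regions)
    if train_config is None:
        train_config = TrainingConfig.desk_scale(seed=seed)
    cv_result = run_cv(prepared, folds, arch, train_config)
    return cohort, prepared, folds, cv_result


def fold_saliency_maps(cv_result: CVResult, on: str = "train") -> list[np.ndarray]:
    """Per-fold mean saliency-temporal-variance maps.

    ``on="train"`` uses each fold's training subjects (the cross-validated
    selection rule for saliency-defined networks, avoiding double dipping);
    ``on="val"`` uses validation subjects (the reporting convention for
    regional reliance maps).
    """
    maps = []
    for fr in cv_result.folds:
        idx = fr.train_idx if on == "train" else fr.val_idx
        X, _ = _session_stack(cv_result.subjects, idx)
        maps.append(mean_saliency_variance(fr.members, X))
    return maps


def validation_saliency_map(cv_result: CVResult) -> np.ndarray:
    """Session-weighted mean saliency variance over all validation folds.

    Every subject appears exactly once as a validation case, so this is the
    cohort-level regional-reliance map.
    """
    maps = fold_saliency_maps(cv_result, on="val")
    weights = np.array(
        [
            sum(cv_result.subjects[i].sessions.shape[0] for i in fr.val_idx)
            for fr in cv_result.folds
        ],
        dtype=float,
    )
    return np.average(np.stack(maps), axis=0, weights=weights)


def saliency_network_power(
    cv_result: CVResult,
    set_size: int,
    n_random: int = 10,
    seed: int = 0,
    metric: str = "r2",
) -> dict:
    """Compare saliency-defined network ablation against random same-size sets.

    Saliency networks are defined per fold from training-fold saliency maps
    and ablated on that fold's validation data. The comparison quantity is
    the cross-fold mean metric degradation: at desk scale the paired-T
    statistic saturates (a random set that degrades mildly but consistently
    can out-T a set that degrades massively with some cross-fold spread), so
    the degradation magnitude is what discriminates; both are reported.
    """
    train_maps = fold_saliency_maps(cv_result, on="train")
    per_fold_sets = [
        build_saliency_networks(m, [set_size])[set_size] for m in train_maps
    ]
    sal_res = ablation_test(cv_result, per_fold_sets, metric=metric)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 41])
    n_regions = cv_result.subjects[0].sessions.shape[-1]
    random_results = [
        ablation_test(
            cv_result,
            list(rng.choice(n_regions, size=set_size, replace=False)),
            metric=metric,
        )
        for _ in range(n_random)
    ]
    random_deltas = np.array([r.deltas.mean() for r in random_results])
    return {
        "saliency_delta": float(sal_res.deltas.mean()),
        "random_deltas": random_deltas,
        "saliency_t": sal_res.t_stat,
        "random_t": np.array([r.t_stat for r in random_results]),
        "saliency_beats_random_mean": bool(
            sal_res.deltas.mean() > random_deltas.mean()
        ),
        "per_fold_sets": per_fold_sets,
        "ablation_result": sal_res,
    }
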