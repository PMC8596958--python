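"""Family-stratified k-fold cross-validation and metric computation.

Families are never split across folds: each family is placed in one of nine
strata (terciles of family-averaged trait x family-size group {1, 2, 3+}),
shuffled within its stratum with a seeded generator and dealt round-robin
into the k folds; the per-stratum folds are then unioned. A running deal
pointer is carried across strata so no fold systematically collects the first
family of every stratum.

Metrics follow the coefficient-of-determination convention
R^2 = 1 - MSE(y, yhat) / Var(y) with the population variance (divisor n,
matching the MSE divisor, so a constant mean prediction scores exactly 0),
plus the squared Pearson correlation rho^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    DecorrelationModel,
    apply_decorrelation,
    fit_decorrelation,
)
from .rnn import (
    ArchitectureSpec,
    EnsembleParams,
    TrainingConfig,
    predict_matrix,
    train_ensemble,
)

__all__ = [
    "FoldSpec",
    "Metrics",
    "PreparedSubject",
    "make_folds",
    "evaluate",
    "run_cv",
    "CVResult",
    "FoldResult",
    "predict_subjects",
    "ensemble_size_curve",
]


@dataclass
class FoldSpec:
    """Family -> fold assignment for k folds."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_of(self, family_id: str) -> int:
        return self.assignment[family_id]

    def to_json_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed, "assignment": self.assignment}


@dataclass(frozen=True)
class Metrics:
    mse: float
    r2: float
    rho2: float


@dataclass
class PreparedSubject:
    """A subject after preprocessing: standardized decimated sessions."""

    subject_id: str
    family_id: str
    g: float
    confounds: np.ndarray
    sessions: np.ndarray  # (n_sessions, T, R)
    region_ids: list[str] | None = None


def _size_group(n: int) -> int:
    return 1 if n == 1 else (2 if n == 2 else 3)


def make_folds(records, k: int = 10, seed: int = 0) -> FoldSpec:
    """Stratified family-level fold assignment.

    ``records`` is any sequence of objects with ``family_id`` and ``g``
    attributes (subject records or prepared subjects).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    fam_g: dict[str, list[float]] = {}
    for rec in records:
        fam_g.setdefault(rec.family_id, []).append(float(rec.g))
    families = sorted(fam_g)
    if len(families) < k:
        raise ValueError(f"need at least k={k} families, got {len(families)}")
    means = np.array([np.mean(fam_g[f]) for f in families])
    edges = np.quantile(means, [1 / 3, 2 / 3])

    def tercile(x: float) -> int:
        # ties at an edge go to the lower tercile
        return 0 if x <= edges[0] else (1 if x <= edges[1] else 2)

    strata: dict[tuple[int, int], list[str]] = {}
    for fam, mean in zip(families, means):
        key = (tercile(mean), _size_group(len(fam_g[fam])))
        strata.setdefault(key, []).append(fam)

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 23])
    assignment: dict[str, int] = {}
    pointer = 0  # carried across strata to balance fold sizes
    for key in sorted(strata):
        fams = strata[key]
        order = rng.permutation(len(fams))
        for i in order:
            assignment[fams[i]] = pointer % k
            pointer += 1
    return FoldSpec(k=k, assignment=assignment, seed=seed)


def fold_indices(fold_spec: FoldSpec, records) -> list[np.ndarray]:
    """Subject index arrays per fold, in record order."""
    folds = [[] for _ in range(fold_spec.k)]
    for i, rec in enumerate(records):
        folds[fold_spec.assignment[rec.family_id]].append(i)
    return [np.array(f, dtype=int) for f in folds]


def evaluate(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """MSE, R^2 = 1 - MSE/Var(y) (population variance) and squared Pearson r."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D and of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    var = y.var()
    if var == 0:
        raise ValueError("Var(y) is zero; R^2 undefined")
    mse = float(np.mean((y - yhat) ** 2))
    r2 = 1.0 - mse / var
    if yhat.var() == 0:
        raise ValueError("yhat has zero variance; rho^2 undefined")
    rho = np.corrcoef(y, yhat)[0, 1]
    return Metrics(mse=mse, r2=float(r2), rho2=float(rho**2))


@dataclass
class FoldResult:
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    members: EnsembleParams
    decor: DecorrelationModel
    y_val: np.ndarray
    yhat_val: np.ndarray
    metrics: Metrics
    loss_history: np.ndarray


@dataclass
class CVResult:
    subjects: list[PreparedSubject]
    fold_spec: FoldSpec
    arch: ArchitectureSpec
    config: TrainingConfig
    folds: list[FoldResult] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        """Mean and standard error (SD/sqrt(k), divisor k-1) of each metric."""
        out: dict[str, float] = {}
        k = len(self.folds)
        for name in ("mse", "r2", "rho2"):
            vals = np.array([getattr(f.metrics, name) for f in self.folds])
            out[f"{name}_mean"] = float(vals.mean())
            out[f"{name}_stderr"] = float(vals.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
        return out


def _session_stack(subjects, idx, ablate_idx=None):
    """Stack all sessions of the chosen subjects into one (N, T, R) batch.

    Returns (X, owner) where owner[i] is the position (within idx) of the
    subject owning session i.
    """
    chunks, owners = [], []
    for pos, i in enumerate(idx):
        s = subjects[i].sessions
        chunks.append(s)
        owners += [pos] * s.shape[0]
    X = np.concatenate(chunks, axis=0)
    if ablate_idx is not None and len(ablate_idx):
        X = X.copy()
        X[:, :, np.asarray(ablate_idx, dtype=int)] = 0.0
    return X, np.array(owners)


def predict_subjects(
    members: EnsembleParams,
    subjects,
    idx,
    ablate_idx=None,
    n_members: int | None = None,
) -> np.ndarray:
    """Per-subject predictions: mean over members and over sessions.

    ``ablate_idx`` optionally zero-fills the listed region columns (zero is
    the post-standardization mean) before prediction.
    """
    X, owners = _session_stack(subjects, idx, ablate_idx)
    preds = predict_matrix(members, X)  # (M, n_sessions_total)
    if n_members is not None:
        preds = preds[:n_members]
    per_session = preds.mean(axis=0)
    out = np.zeros(len(idx))
    counts = np.zeros(len(idx))
    np.add.at(out, owners, per_session)
    np.add.at(counts, owners, 1.0)
    return out / counts


def run_cv(
    subjects: list[PreparedSubject],
    fold_spec: FoldSpec,
    arch: ArchitectureSpec,
    config: TrainingConfig,
) -> CVResult:
    """Train and evaluate one ensemble per fold.

    Per fold: the confound-decorrelation transform is fitted on training
    subjects and applied (with train coefficients and scale) to both sides;
    the ensemble is trained on training sessions (each session a separate
    sample); validation predictions average members and sessions per subject.
    """
    folds = fold_indices(fold_spec, subjects)
    result = CVResult(subjects, fold_spec, arch, config)
    g = np.array([s.g for s in subjects])
    confounds = np.stack([s.confounds for s in subjects])
    for fold_id, val_idx in enumerate(folds):
        if val_idx.size < 2:
            raise ValueError(f"fold {fold_id} has fewer than 2 validation subjects")
        train_idx = np.setdiff1d(np.arange(len(subjects)), val_idx)
        decor = fit_decorrelation(g[train_idx], confounds[train_idx])
        y_train = apply_decorrelation(decor, g[train_idx], confounds[train_idx])
        y_val = apply_decorrelation(decor, g[val_idx], confounds[val_idx])

        X_train, owners = _session_stack(subjects, train_idx)
        y_sessions = y_train[owners]
        fold_cfg = TrainingConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            max_crop=config.max_crop,
            batch_size=config.batch_size,
            ensemble_size=config.ensemble_size,
            seed=int(config.seed) * 1000 + fold_id,
            dtype=config.dtype,
        )
        members, losses = train_ensemble(arch, X_train, y_sessions, fold_cfg)
        yhat_val = predict_subjects(members, subjects, val_idx)
        metrics = evaluate(y_val, yhat_val)
        result.folds.append(
            FoldResult(
                fold=fold_id,
                train_idx=train_idx,
                val_idx=val_idx,
                members=members,
                decor=decor,
                y_val=y_val,
                yhat_val=yhat_val,
                metrics=metrics,
                loss_history=losses,
            )
        )
    return result


def ensemble_size_curve(result: CVResult, metric: str = "r2") -> np.ndarray:
    """Mean validation metric across folds for ensemble sizes 1..M.

    Members are added in training order (prefix averaging), mirroring the
    ensemble-size performance curve of the study design.
    """
    n_members = result.folds[0].members.n_members
    curve = np.zeros(n_members)
    for n in range(1, n_members + 1):
        vals = []
        for fr in result.folds:
            yhat = predict_subjects(fr.members, result.subjects, fr.val_idx, n_members=n)
            vals.append(getattr(evaluate(fr.y_val, yhat), metric))
        curve[n - 1] = float(np.mean(vals))
    return curve
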