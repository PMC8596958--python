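"""Session-level preprocessing of parcellated BOLD timeseries.

Implements the three stages that sit between raw regional timeseries and the
recurrent model:

* band-pass filtering with spectral-truncation decimation (the session is
  re-expressed on a coarser time grid that exactly carries the retained band,
  so no information inside the band is lost and the long-range autocorrelation
  induced by filtering disappears);
* per-region standardization (mean 0, unit variance, divisor T-1) — this is a
  constituent stage of the differentiable model, which is why saliencies are
  later propagated through it;
* confound decorrelation of the behavioural target: the trait is residualized
  on nuisance covariates with coefficients, centering and scaling estimated on
  training data only, so that no validation information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionTimeseries",
    "DecorrelationModel",
    "bandpass_decimate",
    "standardize",
    "fit_decorrelation",
    "apply_decorrelation",
]


@dataclass
class RegionTimeseries:
    """One session's T x R matrix of regional activity.

    Parameters
    ----------
    values
        Array of shape (T, R); rows are timepoints, columns are regions.
    tr
        Sampling interval in seconds. After decimation this is the *virtual*
        sampling interval ``duration / T``.
    region_ids
        Ordered, unique region labels, one per column.
    duration
        Session length in seconds. Defaults to ``T * tr``; kept explicitly
        because decimation preserves duration while changing T and tr.
    """

    values: np.ndarray
    tr: float
    region_ids: list[str] = field(default_factory=list)
    duration: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (timepoints x regions) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        T, R = self.values.shape
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(R)]
        self.region_ids = list(self.region_ids)
        if len(self.region_ids) != R:
            raise ValueError("region_ids length does not match number of columns")
        if len(set(self.region_ids)) != R:
            raise ValueError("region_ids must be unique")
        if self.duration is None:
            self.duration = T * self.tr
        if abs(self.duration / self.tr - T) > 1:
            raise ValueError(
                f"duration {self.duration} inconsistent with T={T}, tr={self.tr}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def bandpass_decimate(
    series: RegionTimeseries, f_low: float = 0.008, f_high: float = 0.09
) -> RegionTimeseries:
    """Band-pass filter each region and decimate by spectral truncation.

    Each column is taken to the frequency domain with a real FFT; bins whose
    frequency k/duration lies outside [f_low, f_high] are zeroed (the DC bin
    always is), the spectrum is truncated at ``k_max = floor(f_high *
    duration)``, and the result is transformed back onto a grid of
    ``T' = 2*k_max + 1`` samples. The output carries exactly the retained band
    — a 1,200-point, 864-s session filtered to [0.008, 0.09] Hz becomes 155
    timepoints with a virtual sampling interval of 864/155 ≈ 5.57 s.

    The operation is linear in the input, produces an odd number of samples,
    and is idempotent: a second application with the same band on the
    decimated grid is the identity.
    """
    T = series.n_timepoints
    if T < 4:
        raise ValueError("need at least 4 timepoints to band-pass filter")
    if f_low < 0:
        raise ValueError("f_low must be non-negative")
    if f_high <= f_low:
        raise ValueError("f_high must exceed f_low")
    dur = float(series.duration)
    k_max = int(np.floor(f_high * dur))
    if k_max > (T - 1) // 2:
        raise ValueError(
            f"f_high={f_high} Hz exceeds the highest representable frequency "
            f"{((T - 1) // 2) / dur:.6g} Hz for this grid"
        )
    if k_max < 1:
        raise ValueError("band contains no non-DC frequency bin")

    spec = np.fft.rfft(series.values, axis=0)
    freqs = np.arange(spec.shape[0]) / dur
    spec[(freqs < f_low) | (freqs > f_high)] = 0.0
    spec[0] = 0.0  # DC removed unconditionally
    t_out = 2 * k_max + 1
    # rescale so retained sinusoids keep their amplitude on the new grid
    out = np.fft.irfft(spec[: k_max + 1] * (t_out / T), n=t_out, axis=0)
    return RegionTimeseries(
        out, tr=dur / t_out, region_ids=list(series.region_ids), duration=dur
    )


def standardize(series: RegionTimeseries, ddof: int = 1) -> RegionTimeseries:
    """Center each region to mean 0 and scale to unit variance (divisor T-ddof).

    The divisor T-1 matches the one used for saliency temporal variance and
    for the correlation normalizer in the connectivity-perturbation analysis.
    Raises if any region has zero variance, naming the offending region.
    """
    X = series.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(series.region_ids[i] for i in bad[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    return RegionTimeseries(
        (X - mean) / sd,
        tr=series.tr,
        region_ids=list(series.region_ids),
        duration=series.duration,
    )


@dataclass
class DecorrelationModel:
    """OLS residualization of the trait on confounds, frozen at fit time.

    ``coefficients`` holds the intercept followed by one coefficient per
    confound; ``train_center``/``train_scale`` are the mean and standard
    deviation (divisor n-1) of the training residual, reused verbatim on
    validation data so the transform never sees validation statistics.
    """

    coefficients: np.ndarray
    train_center: float
    train_scale: float

    def __post_init__(self) -> None:
        if self.train_scale <= 0:
            raise ValueError("train_scale must be positive")


def _design(confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.ndim != 2:
        raise ValueError("confounds must be a 2-D (subjects x confounds) array")
    return np.column_stack([np.ones(confounds.shape[0]), confounds])


def fit_decorrelation(
    g_train: np.ndarray, confounds_train: np.ndarray
) -> DecorrelationModel:
    """Fit the confound-decorrelation transform on training subjects only."""
    g = np.asarray(g_train, dtype=float)
    A = _design(confounds_train)
    if A.shape[0] != g.shape[0]:
        raise ValueError("confound rows must match length of g")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("confound design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, g, rcond=None)
    resid = g - A @ beta
    scale = resid.std(ddof=1)
    if scale <= 1e-12 * max(1.0, float(np.abs(g).max())):
        raise ValueError("training residual variance is zero; g is linear in confounds")
    return DecorrelationModel(
        coefficients=beta, train_center=float(resid.mean()), train_scale=float(scale)
    )


def apply_decorrelation(
    model: DecorrelationModel, g: np.ndarray, confounds: np.ndarray
) -> np.ndarray:
    """Residualize, center and rescale ``g`` using train-time statistics only."""
    g = np.asarray(g, dtype=float)
    A = _design(confounds)
    if A.shape[1] != model.coefficients.shape[0]:
        raise ValueError("confound count differs from the fitted model")
    resid = g - A @ model.coefficients
    return (resid - model.train_center) / model.train_scale
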