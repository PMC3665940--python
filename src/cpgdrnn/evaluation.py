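"""Fidelity and structure metrics: similarity index, planar covariation, and
excitatory/inhibitory connectivity statistics.

The similarity index (SI) is the normalized inner product of two waveforms
over one gait cycle after synchronizing them on their maxima,

    SI = integral(p1 p2) / sqrt(integral(p1^2) * integral(p2^2)),

so |SI| <= 1 by Cauchy-Schwarz and SI = 1 exactly when the aligned patterns
are positively proportional.  Planar covariation is quantified by principal
component analysis of the mean-centered (thigh, shank, foot) trajectory: the
planarity index is the variance fraction captured by the first two principal
components.  Structure summaries count inhibitory (negative) versus
excitatory (positive) synaptic weights and describe the time-constant
distribution of a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.decomposition import PCA

from .drnn_core import DRNNParams
from .errors import DegenerateInputError, UndefinedSIError
from .harmonic_features import extract_trial_spec
from .synthetic_gait import ElevationSeries


@dataclass
class SIResult:
    """Per-channel similarity indices for a six-channel comparison."""

    per_channel: dict[str, float]
    mean_si: float
    Tc: float
    shifts: dict[str, int]  # applied circular alignment shift, samples


@dataclass
class CovariationPlane:
    """PCA description of the inter-segmental covariation loop."""

    axes: np.ndarray  # (3, 3) orthonormal principal axes (rows)
    variance_fractions: np.ndarray  # (3,), sums to 1
    planarity: float  # PC1 + PC2 variance fraction
    loop: np.ndarray  # (n, 3) trajectory in principal coordinates


@dataclass
class StructureSummary:
    """Signs of the synaptic weights and the time-constant distribution."""

    n_units: int
    n_hidden: int
    n_positive: int
    n_negative: int
    n_zero: int
    frac_positive: float
    frac_negative: float
    T_median: float
    T_quartiles: tuple[float, float]
    T_min: float
    T_max: float
    T_values: np.ndarray = field(repr=False, default=None)


def _locate_maximum(p: np.ndarray, Tc: float, dt: float) -> int:
    """Index of the pattern maximum, located on a zero-phase low-passed copy
    (cutoff 4 / Tc: keeps the first three gait harmonics, discards broadband
    noise that would otherwise jitter the argmax of a flat-topped peak by
    several samples).  Falls back to the raw argmax for very short or
    already-smooth signals.  Earliest maximum wins ties."""
    cutoff = 4.0 / Tc
    nyquist = 0.5 / dt
    if p.size >= 24 and cutoff < 0.8 * nyquist:
        sos = _signal.butter(2, cutoff / nyquist, output="sos")
        p = _signal.sosfiltfilt(sos, p)
    return int(np.argmax(p))


def similarity_index(p1: np.ndarray, p2: np.ndarray, Tc: float, dt: float = 0.01) -> float:
    """SI between two waveforms sampled at interval ``dt`` covering >= 1 period.

    ``p2`` is circularly shifted so its maximum coincides with ``p1``'s
    (maxima located on low-passed copies, earliest occurrence on ties); the
    normalized inner product of the raw patterns is then taken over exactly
    one period ``Tc`` by trapezoidal quadrature, anchored at the reference
    maximum.
    """
    p1 = np.asarray(p1, float).ravel()
    p2 = np.asarray(p2, float).ravel()
    if p1.shape != p2.shape:
        raise UndefinedSIError("patterns must share a common grid")
    n_period = int(round(Tc / dt))
    if n_period < 2 or n_period > p1.size:
        raise UndefinedSIError(
            f"period Tc={Tc} maps to {n_period} samples; need 2..{p1.size}"
        )
    if not (np.any(p1 != p1[0]) and np.any(p2 != p2[0])):
        raise UndefinedSIError("constant pattern has zero energy")
    anchor = _locate_maximum(p1, Tc, dt)
    shift = anchor - _locate_maximum(p2, Tc, dt)
    p2s = np.roll(p2, shift)
    idx = (anchor + np.arange(n_period + 1)) % p1.size
    w1 = p1[idx]
    w2 = p2s[idx]
    num = np.trapezoid(w1 * w2)
    d1 = np.trapezoid(w1 * w1)
    d2 = np.trapezoid(w2 * w2)
    if d1 <= 0 or d2 <= 0:
        raise UndefinedSIError("zero-energy pattern over the analysis period")
    return float(num / np.sqrt(d1 * d2))


def evaluate_fit(
    predicted: ElevationSeries | np.ndarray,
    reference: ElevationSeries,
    dt: float | None = None,
) -> SIResult:
    """Per-channel SI between a predicted and a reference six-channel pattern.

    The cycle period Tc is the reference's spectral stride period (1 / f1 of
    its pooled harmonic spec).  The mean over the six channels is the headline
    score.
    """
    ref = reference.data
    pred = predicted.data if isinstance(predicted, ElevationSeries) else np.asarray(predicted, float)
    if pred.shape != ref.shape:
        raise UndefinedSIError("prediction and reference shapes differ")
    step = 1.0 / reference.sample_rate if dt is None else dt
    Tc = 1.0 / extract_trial_spec(reference).f1
    per = {}
    shifts = {}
    for i, name in enumerate(reference.channels):
        per[name] = similarity_index(ref[:, i], pred[:, i], Tc, step)
        shifts[name] = _locate_maximum(ref[:, i], Tc, step) - _locate_maximum(
            pred[:, i], Tc, step
        )
    return SIResult(
        per_channel=per, mean_si=float(np.mean(list(per.values()))), Tc=Tc, shifts=shifts
    )


def fit_covariation_plane(
    thigh: np.ndarray, shank: np.ndarray, foot: np.ndarray
) -> CovariationPlane:
    """Fit the covariation plane of one leg's normalized elevation angles by
    covariance PCA of the mean-centered 3-D trajectory."""
    X = np.column_stack([np.asarray(thigh, float), np.asarray(shank, float), np.asarray(foot, float)])
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least 3 samples for a plane fit")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("trajectory has no variance (rank 0)")
    pca = PCA(n_components=3)
    loop = pca.fit_transform(X)
    fractions = pca.explained_variance_ratio_
    return CovariationPlane(
        axes=pca.components_,
        variance_fractions=fractions,
        planarity=float(fractions[0] + fractions[1]),
        loop=loop,
    )


def _structure(params: DRNNParams) -> StructureSummary:
    w = params.w
    n_zero = int(np.count_nonzero(w == 0.0))
    n_pos = int(np.count_nonzero(w > 0.0))
    n_neg = int(np.count_nonzero(w < 0.0))
    denom = max(n_pos + n_neg, 1)
    T = params.T
    q1, med, q3 = np.percentile(T, [25, 50, 75])
    return StructureSummary(
        n_units=params.n_units,
        n_hidden=params.n_hidden,
        n_positive=n_pos,
        n_negative=n_neg,
        n_zero=n_zero,
        frac_positive=n_pos / denom,
        frac_negative=n_neg / denom,
        T_median=float(med),
        T_quartiles=(float(q1), float(q3)),
        T_min=float(T.min()),
        T_max=float(T.max()),
        T_values=T.copy(),
    )


def weight_sign_distribution(params: DRNNParams) -> StructureSummary:
    """Fractions of excitatory/inhibitory directed connections over all
    ``n_units^2`` entries of the weight matrix (self-connections included;
    exact zeros counted separately and excluded from the denominators)."""
    return _structure(params)


def time_constant_stats(params: DRNNParams) -> StructureSummary:
    """Median, quartiles and range of the per-unit time constants."""
    return _structure(params)
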