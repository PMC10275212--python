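"""Weighted connectivity estimation.

Builds the per-layer connectivity matrices of the pipeline:

* MEG-like layers — brickwall Fourier band filtering into the six canonical
  frequency bands, then the phase lag index (PLI) between all region pairs.
  The PLI is |mean over samples of sign(sin(delta-phi))| with delta-phi the
  instantaneous phase difference from the analytic (Hilbert) signal; it is 0
  for zero-lag (or no consistent) coupling and 1 for a perfectly consistent
  nonzero lag, and is insensitive to amplitude scaling.
* BOLD-like layer — absolutized Pearson correlation between region time
  series (negative correlations are kept, magnitude only).
* Structural layer — streamline-count-like matrices are not recomputed but
  validated (symmetric, nonnegative, zero diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "MEG_BAND_NAMES",
    "EpochedTimeSeries",
    "ConnectivityMatrix",
    "bandpass",
    "pli_pair",
    "pli_matrix",
    "correlation_matrix",
    "validate_structural",
    "exclude_regions",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name!r}: f_lo must be < f_hi")


#: The six canonical MEG bands.
CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "lower_alpha": BandSpec("lower_alpha", 8.0, 10.0),
    "upper_alpha": BandSpec("upper_alpha", 10.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 48.0),
}

MEG_BAND_NAMES: tuple[str, ...] = tuple(CANONICAL_BANDS)


@dataclass
class EpochedTimeSeries:
    """Regional time series cut into equal-length epochs.

    ``values`` has shape (epochs, samples, regions).
    """

    values: np.ndarray
    sampling_rate: float
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single epoch convenience
            self.values = self.values[None, :, :]
        if self.values.ndim != 3:
            raise ValueError("values must have shape (epochs, samples, regions)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.region_labels:
            self.region_labels = tuple(self.region_labels)
            if len(self.region_labels) != self.values.shape[2]:
                raise ValueError(
                    f"{len(self.region_labels)} region labels for "
                    f"{self.values.shape[2]} regions"
                )
        else:
            self.region_labels = tuple(f"R{i:03d}" for i in range(self.values.shape[2]))

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_regions(self) -> int:
        return self.values.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Epoch length in seconds (samples / sampling rate)."""
        return self.n_samples / self.sampling_rate

    def flat(self) -> np.ndarray:
        """Concatenate epochs into one (samples, regions) array."""
        return self.values.reshape(-1, self.n_regions)


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative N x N weights for one subject and layer."""

    weights: np.ndarray
    modality: str = ""
    subject_id: str = ""
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"weights asymmetric beyond tolerance ({asym:.3g} > {_SYM_TOL})")
        w = (w + w.T) / 2.0
        d = np.abs(np.diag(w))
        if d.size and d.max() > _SYM_TOL:
            raise ValueError(f"nonzero diagonal (max {d.max():.3g})")
        np.fill_diagonal(w, 0.0)
        if w.size and w.min() < 0:
            raise ValueError(f"negative weight {w.min():.3g}")
        self.weights = w
        if self.region_labels:
            self.region_labels = tuple(self.region_labels)
            if len(self.region_labels) != w.shape[0]:
                raise ValueError("region label count does not match matrix size")
        else:
            self.region_labels = tuple(f"R{i:03d}" for i in range(w.shape[0]))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def bandpass(series: EpochedTimeSeries, band: BandSpec) -> EpochedTimeSeries:
    """Brickwall Fourier filter: zero all bins with |f| outside [f_lo, f_hi).

    Applied per epoch and per region; adjacent canonical bands partition the
    spectrum without double counting because the upper edge is exclusive.
    """
    nyq = series.sampling_rate / 2.0
    if band.f_hi >= nyq + 1e-12 and band.f_hi != nyq:
        raise ValueError(
            f"band {band.name!r}: f_hi={band.f_hi} Hz at or above Nyquist ({nyq} Hz)"
        )
    if series.n_samples < 2:
        raise ValueError("epoch length must be at least 2 samples")
    freqs = np.fft.rfftfreq(series.n_samples, d=1.0 / series.sampling_rate)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    spec = np.fft.rfft(series.values, axis=1)
    spec[:, ~mask, :] = 0.0
    out = np.fft.irfft(spec, n=series.n_samples, axis=1)
    return EpochedTimeSeries(out, series.sampling_rate, series.region_labels)


def _check_signal(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 16:
        raise ValueError(f"{name}: need at least 16 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"{name}: constant signal, instantaneous phase undefined")
    return x


def pli_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index between two equal-length real signals.

    PLI = |mean_t sign(sin(phi_x(t) - phi_y(t)))| with phases from the
    analytic signal. Samples with phase difference exactly 0 or pi contribute
    0 (the sign of a zero sine).
    """
    x = _check_signal(x, "x")
    y = _check_signal(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    ax = hilbert(x)
    ay = hilbert(y)
    dphi = np.angle(ax * np.conj(ay))
    return float(abs(np.mean(_lag_sign(dphi))))


def _lag_sign(dphi: np.ndarray) -> np.ndarray:
    """sign(sin(dphi)) with numerically zero lags (0 or pi) contributing 0."""
    s = np.sin(dphi)
    return np.where(np.abs(s) <= 1e-12, 0.0, np.sign(s))


def _pairwise_sign_sum(phases: np.ndarray, block: int = 256) -> np.ndarray:
    """Sum over samples of sign(sin(phi_i - phi_j)); phases (samples, regions)."""
    n, r = phases.shape
    acc = np.zeros((r, r))
    for start in range(0, n, block):
        p = phases[start : start + block]
        acc += _lag_sign(p[:, :, None] - p[:, None, :]).sum(axis=0)
    return acc


def pli_matrix(
    series: EpochedTimeSeries,
    band: BandSpec | None = None,
    *,
    epoch_average: bool = True,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """All-pairs PLI of a (band-filtered) epoched recording.

    PLI is computed per epoch from the analytic-signal phases and averaged
    across epochs (the default); ``epoch_average=False`` instead pools the
    per-sample phase-difference signs over all epochs before taking the
    absolute mean.
    """
    if series.n_epochs < 1:
        raise ValueError("need at least one epoch")
    if band is not None:
        series = bandpass(series, band)
    for r in range(series.n_regions):
        if np.ptp(series.values[:, :, r]) == 0:
            raise ValueError(f"region {series.region_labels[r]!r} is constant")
    phases = np.angle(hilbert(series.values, axis=1))
    n = series.n_samples
    if epoch_average:
        mats = [np.abs(_pairwise_sign_sum(phases[e]) / n) for e in range(series.n_epochs)]
        w = np.mean(mats, axis=0)
    else:
        acc = sum(_pairwise_sign_sum(phases[e]) for e in range(series.n_epochs))
        w = np.abs(acc / (n * series.n_epochs))
    np.fill_diagonal(w, 0.0)
    name = band.name if band is not None else "broadband"
    return ConnectivityMatrix(w, modality=name, subject_id=subject_id,
                              region_labels=series.region_labels)


def correlation_matrix(
    series: np.ndarray | EpochedTimeSeries,
    region_labels: Sequence[str] = (),
    *,
    subject_id: str = "",
    modality: str = "rsfmri",
) -> ConnectivityMatrix:
    """Absolutized Pearson correlation between region time series.

    ``series`` is (samples, regions), or an :class:`EpochedTimeSeries` whose
    epochs are concatenated first (the BOLD-like layer is one continuous
    acquisition).
    """
    if isinstance(series, EpochedTimeSeries):
        region_labels = region_labels or series.region_labels
        data = series.flat()
    else:
        data = np.asarray(series, dtype=float)
    if data.ndim != 2:
        raise ValueError("series must be (samples, regions)")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    labels = tuple(region_labels) or tuple(f"R{i:03d}" for i in range(data.shape[1]))
    sd = data.std(axis=0)
    constant = sd <= 1e-12 * (np.abs(data).max(axis=0) + 1.0)
    if np.any(constant):
        bad = labels[int(np.argmax(constant))]
        raise ValueError(f"region {bad!r} has a constant time series")
    r = np.corrcoef(data, rowvar=False)
    w = np.abs(r)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return ConnectivityMatrix(w, modality=modality, subject_id=subject_id,
                              region_labels=labels)


def validate_structural(
    matrix: np.ndarray,
    region_labels: Sequence[str] = (),
    *,
    subject_id: str = "",
    tol: float = _SYM_TOL,
) -> ConnectivityMatrix:
    """Validate a raw streamline-count-like matrix and tag it ``dmri``.

    Symmetry is required to ``tol``; a diagonal within ``tol`` of zero is
    zeroed; negative entries are rejected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"structural matrix must be square, got {m.shape}")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > tol:
        raise ValueError(f"structural matrix asymmetric beyond tolerance ({asym:.3g})")
    if np.max(np.abs(np.diag(m))) > tol:
        raise ValueError("structural matrix has a nonzero diagonal beyond tolerance")
    if m.min() < 0:
        if m.min() < -tol:
            raise ValueError(f"structural matrix has negative entries (min {m.min():.3g})")
        m = np.clip(m, 0.0, None)
    return ConnectivityMatrix(m, modality="dmri", subject_id=subject_id,
                              region_labels=tuple(region_labels))


def exclude_regions(
    matrices: Iterable[ConnectivityMatrix],
    bad_regions: Sequence[int],
    mapping=None,
):
    """Remove regions (rows+columns) globally from a set of matrices.

    The same exclusion list applies to every matrix of every subject and
    layer, mirroring the global removal of signal-loss regions; matrices with
    differing sizes or region orderings are rejected.

    Returns ``(matrices, mapping)`` where ``mapping`` is the reduced atlas
    mapping (or None if none was given).
    """
    mats = list(matrices)
    if not mats:
        return [], mapping.subset(np.array([], dtype=int)) if mapping else None
    n = mats[0].n_regions
    labels = mats[0].region_labels
    for m in mats[1:]:
        if m.n_regions != n or m.region_labels != labels:
            raise ValueError(
                "matrices disagree on region count/ordering; regions must be "
                "excluded identically across all subjects and layers"
            )
    bad = sorted(set(int(b) for b in bad_regions))
    if bad and (bad[0] < 0 or bad[-1] >= n):
        raise ValueError(f"region index out of range for N={n}: {bad}")
    keep = np.setdiff1d(np.arange(n), bad)
    out = [
        ConnectivityMatrix(
            m.weights[np.ix_(keep, keep)],
            modality=m.modality,
            subject_id=m.subject_id,
            region_labels=tuple(labels[i] for i in keep),
        )
        for m in mats
    ]
    new_mapping = mapping.subset(keep) if mapping is not None else None
    return out, new_mapping
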