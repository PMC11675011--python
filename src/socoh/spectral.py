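"""Welch spectral estimation and magnitude-squared coherence.

Power spectra use the Welch method: the signal is cut into 1-s tapered
windows with 80% overlap, each windowed periodogram is zero-padded so the
frequency grid has 0.5-Hz spacing, and the periodograms are averaged.
Magnitude-squared coherence between channels i and j is

    C_ij(f) = |S_ij(f)|^2 / (S_ii(f) S_jj(f)),

computed from the same windowed cross/auto spectra, so it lies in [0, 1]
and equals 1 for identical (or affinely related) signals.  With K averaged
windows of independent noise, the estimator has a positive bias of roughly
1/K — the "coherence floor" — which is why epochs shorter than a handful of
windows are rejected upstream.

For pooling across the chamber visits ("trials") of a condition, windowed
cross-spectra are accumulated over *all* windows of all epochs before the
coherence ratio is formed (:class:`CrossSpectralAccumulator`); this is more
stable than averaging per-epoch coherences and weights epochs by their
window counts automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectralParams",
    "BandDef",
    "DEFAULT_BANDS",
    "GAMMA",
    "welch_psd",
    "ms_coherence",
    "band_aggregate",
    "pool_epochs",
    "window_count",
    "CrossSpectralAccumulator",
]


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimator settings.

    ``window_s`` (s) and ``overlap_frac`` control segmentation; the native
    grid of a 1-s window is 1 Hz, so the finer ``freq_resolution_hz`` grid
    is realised by zero-padding the FFT.  ``f_range`` restricts the
    reported grid.
    """

    window_s: float = 1.0
    overlap_frac: float = 0.8
    freq_resolution_hz: float = 0.5
    f_range: tuple = (0.1, 150.0)
    taper: str = "hamming"

    def __post_init__(self):
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.freq_resolution_hz <= 0 or self.window_s <= 0:
            raise ValueError("window and resolution must be positive")

    def nperseg(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def noverlap(self, fs: float) -> int:
        return int(round(self.overlap_frac * self.nperseg(fs)))

    def nstep(self, fs: float) -> int:
        return self.nperseg(fs) - self.noverlap(fs)

    def nfft(self, fs: float) -> int:
        return max(self.nperseg(fs), int(round(fs / self.freq_resolution_hz)))

    def freqs(self, fs: float) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft(fs), 1.0 / fs)

    def range_mask(self, fs: float) -> np.ndarray:
        f = self.freqs(fs)
        lo, hi = self.f_range
        return (f >= lo - 1e-12) & (f <= hi + 1e-12)


@dataclass(frozen=True)
class BandDef:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band lo must be < hi")


#: Conventional rodent LFP bands; the gamma band used throughout the
#: connectivity analysis is 25-60 Hz.
DEFAULT_BANDS = {
    "delta": BandDef("delta", 1.0, 4.0),
    "theta": BandDef("theta", 4.0, 8.0),
    "alpha": BandDef("alpha", 8.0, 15.0),
    "beta": BandDef("beta", 15.0, 30.0),
    "gamma": BandDef("gamma", 25.0, 60.0),
}
GAMMA = DEFAULT_BANDS["gamma"]

_DEFAULT = SpectralParams()


def window_count(n_samples: int, fs: float, params: SpectralParams = _DEFAULT) -> int:
    """Number of Welch windows for a signal of ``n_samples``."""
    nperseg = params.nperseg(fs)
    if n_samples < nperseg:
        return 0
    return 1 + (n_samples - nperseg) // params.nstep(fs)


def welch_psd(x, fs: float, params: SpectralParams = _DEFAULT):
    """Welch power spectral density (power/Hz) restricted to ``f_range``.

    Returns ``(freqs, psd)``; raises if the signal is shorter than one
    window (such epochs should have been filtered out by the minimum
    epoch-length rule).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < params.nperseg(fs):
        raise ValueError("signal shorter than one Welch window")
    f, p = sps.welch(
        x, fs=fs, window=params.taper, nperseg=params.nperseg(fs),
        noverlap=params.noverlap(fs), nfft=params.nfft(fs),
        detrend="constant", scaling="density",
    )
    m = params.range_mask(fs)
    return f[m], p[..., m]


def ms_coherence(x, y, fs: float, params: SpectralParams = _DEFAULT):
    """Magnitude-squared coherence of two equal-length signals.

    Returns ``(freqs, coherence)`` on the same grid as :func:`welch_psd`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.shape[-1] < params.nperseg(fs):
        raise ValueError("signal shorter than one Welch window")
    f, c = sps.coherence(
        x, y, fs=fs, window=params.taper, nperseg=params.nperseg(fs),
        noverlap=params.noverlap(fs), nfft=params.nfft(fs),
        detrend="constant",
    )
    m = params.range_mask(fs)
    return f[m], np.clip(c[..., m], 0.0, 1.0)


def band_aggregate(freqs, spectrum, band: BandDef) -> float:
    """Unweighted mean of the spectrum bins with ``lo <= f <= hi``."""
    freqs = np.asarray(freqs)
    m = (freqs >= band.lo_hz - 1e-12) & (freqs <= band.hi_hz + 1e-12)
    if not m.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    return np.asarray(spectrum)[..., m].mean(axis=-1)


def pool_epochs(values, weights=None):
    """Window-count-weighted mean of per-epoch values.

    ``None``/NaN entries are treated as missing; if everything is missing
    the result is NaN (a missing condition, propagated downstream).
    """
    v = np.asarray([np.nan if x is None else x for x in values], dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must align")
    ok = ~np.isnan(v)
    if not ok.any() or w[ok].sum() == 0:
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


class CrossSpectralAccumulator:
    """Accumulates windowed cross-spectra over epochs for one condition.

    Feeding multichannel epochs via :meth:`add_epoch` accumulates the sum
    over Welch windows of the outer products ``X(f) X(f)^H`` of the
    windowed channel FFTs.  PSDs and the full pairwise coherence matrix are
    then formed from the pooled sums, which weights every epoch by its
    window count.  ``f_max`` can restrict the stored grid (e.g. to the
    analysis band) to bound memory and compute.
    """

    def __init__(self, n_channels: int, fs: float,
                 params: SpectralParams = _DEFAULT, f_max: float | None = None,
                 chunk_windows: int = 256, single_precision: bool = False):
        self.fs = float(fs)
        self._rdtype = np.float32 if single_precision else np.float64
        self._cdtype = np.complex64 if single_precision else np.complex128
        self.params = params
        self.n_channels = int(n_channels)
        self.chunk_windows = int(chunk_windows)
        full = params.freqs(fs)
        lo, hi = params.f_range
        hi = min(hi, f_max) if f_max is not None else hi
        self._mask = (full >= lo - 1e-12) & (full <= hi + 1e-12)
        self.freqs = full[self._mask]
        nf = self.freqs.size
        self._window = sps.get_window(params.taper, params.nperseg(fs))
        self._win_norm = float((self._window ** 2).sum())
        self.csd_sum = np.zeros((nf, n_channels, n_channels),
                                dtype=self._cdtype)
        self.n_windows = 0
        # density scaling doubles all bins except DC and Nyquist
        nyq = fs / 2.0
        self._two = np.where(
            (self.freqs > 1e-12) & (np.abs(self.freqs - nyq) > 1e-12), 2.0, 1.0
        )

    def add_epoch(self, signals: np.ndarray) -> int:
        """Accumulate one epoch (channels x samples); returns its window count."""
        signals = np.asarray(signals, dtype=self._rdtype)
        if signals.ndim != 2 or signals.shape[0] != self.n_channels:
            raise ValueError("expected (n_channels, n_samples)")
        fs, p = self.fs, self.params
        nperseg, nstep, nfft = p.nperseg(fs), p.nstep(fs), p.nfft(fs)
        n = signals.shape[1]
        k = window_count(n, fs, p)
        if k == 0:
            return 0
        for start in range(0, k, self.chunk_windows):
            kk = min(self.chunk_windows, k - start)
            idx = (start + np.arange(kk))[:, None] * nstep + np.arange(nperseg)
            seg = signals[:, idx]                       # (C, kk, nperseg)
            seg = seg - seg.mean(axis=-1, keepdims=True)
            seg *= self._window.astype(self._rdtype)
            X = np.fft.rfft(seg, n=nfft, axis=-1)[..., self._mask]
            X = X.astype(self._cdtype, copy=False)
            Xf = np.ascontiguousarray(np.moveaxis(X, -1, 0))  # (F, C, kk)
            self.csd_sum += Xf @ Xf.conj().transpose(0, 2, 1)
        self.n_windows += k
        return k

    def _check(self):
        if self.n_windows == 0:
            raise ValueError("no windows accumulated")

    def psd(self) -> np.ndarray:
        """Per-channel PSD (power/Hz), shape (n_channels, n_freqs)."""
        self._check()
        auto = np.einsum("fcc->fc", self.csd_sum).real
        scale = self._two[:, None] / (self.n_windows * self.fs * self._win_norm)
        return (auto * scale).T

    def coherence(self) -> np.ndarray:
        """Pooled coherence, shape (n_freqs, n_channels, n_channels)."""
        self._check()
        auto = np.einsum("fcc->fc", self.csd_sum).real
        denom = auto[:, :, None] * auto[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(self.csd_sum) ** 2 / denom
        return np.clip(c.real, 0.0, 1.0)

    def band_coherence(self, band: BandDef = GAMMA) -> np.ndarray:
        """Band-mean pairwise coherence matrix, shape (C, C)."""
        return band_aggregate(self.freqs, np.moveaxis(self.coherence(), 0, -1), band)

    def band_power(self, band: BandDef = GAMMA) -> np.ndarray:
        """Band-mean PSD per channel."""
        return band_aggregate(self.freqs, self.psd(), band)
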