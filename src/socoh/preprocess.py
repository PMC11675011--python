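"""LFP conditioning: referencing, robust normalisation, artifact rejection.

The cleaning chain, in the order the pipeline applies it:

1. **decimate** — anti-alias filter and downsample raw acquisition-rate
   data; the analysis band tops out at 150 Hz, so anything >= 300 Hz
   preserves it.
2. **local_reference** — subtract, per cannula bundle, the mean of the four
   wires implanted together.  This removes bundle-common-mode noise
   (volume-conducted and cable artefacts) while leaving local signal.
3. **trimmed_zscore** — normalise each channel by the mean/SD of the
   central 80% of its samples (top and bottom 10% by amplitude excluded),
   so large artefacts do not inflate the normalisation.
4. **reject_channels** — drop channels whose broadband power deviates more
   than 5 SD from the across-channel mean.
5. **build_epochs / reject_epochs** — cut the session into chamber visits
   ("trials") and drop any visit in which any kept channel exceeds |z| = 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal as sps

from .behavior import CHAMBERS
from .io import LFPRecording
from .spectral import SpectralParams, welch_psd

__all__ = [
    "Epoch",
    "decimate",
    "local_reference",
    "trimmed_stats",
    "trimmed_zscore",
    "channel_power",
    "reject_channels",
    "build_epochs",
    "reject_epochs",
    "epoch_samples",
]

_ANALYSIS_F_HI = 150.0


@dataclass(frozen=True)
class Epoch:
    """A maximal interval spent in one chamber (a 'trial')."""

    start_s: float
    end_s: float
    chamber: str
    animal_id: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def decimate(rec: LFPRecording, target_fs: float) -> LFPRecording:
    """Anti-alias filter and resample to ``target_fs``.

    ``target_fs`` must respect Nyquist for the 150-Hz analysis band.  A
    no-op when the rate already matches.  Rational ratios are handled with
    a polyphase FIR resampler.
    """
    if target_fs < 2 * _ANALYSIS_F_HI:
        raise ValueError(
            f"target_fs={target_fs} violates Nyquist for the "
            f"{_ANALYSIS_F_HI}-Hz analysis band"
        )
    if abs(target_fs - rec.fs_hz) < 1e-9:
        return rec
    up, down = int(round(target_fs)), int(round(rec.fs_hz))
    g = gcd(up, down)
    out = sps.resample_poly(rec.signal, up // g, down // g, axis=-1)
    return LFPRecording(out, float(target_fs), rec.channel_names,
                        rec.bundle_id, rec.t0)


def local_reference(rec: LFPRecording, exclude_self: bool = False) -> LFPRecording:
    """Per-bundle common-average referencing.

    Each channel has the mean of the four wires of its own cannula
    subtracted (including itself by default, so the per-bundle sum of the
    referenced channels is exactly zero).  ``exclude_self=True`` instead
    subtracts the mean of the *other* bundle members, which differs from
    the default only by a 4/3 gain.  Bundles with missing channels are
    referenced over the remaining members.
    """
    if rec.bundle_id is None:
        raise ValueError("recording has no bundle map")
    sig = rec.signal
    if not np.issubdtype(sig.dtype, np.floating):
        sig = sig.astype(float)
    out = sig.copy()
    for b in np.unique(rec.bundle_id):
        members = np.flatnonzero(rec.bundle_id == b)
        if members.size < 2:
            continue  # nothing to reference against
        block = sig[members]
        if exclude_self:
            total = block.sum(axis=0, keepdims=True)
            out[members] = block - (total - block) / (members.size - 1)
        else:
            out[members] = block - block.mean(axis=0, keepdims=True)
    return LFPRecording(out, rec.fs_hz, rec.channel_names, rec.bundle_id, rec.t0)


def trimmed_stats(x: np.ndarray, trim: float = 0.1) -> tuple:
    """Mean and SD of the central ``1 - 2*trim`` of samples by value rank.

    Computed along the last axis.  Trimming is symmetric in the amplitude
    quantiles (not in time), so a few enormous artefact samples cannot
    drag the normalisation.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    n = x.shape[-1]
    lo = int(np.floor(trim * n))
    hi = n - lo
    if hi - lo < 2:
        raise ValueError("too few samples after trimming")
    core = np.sort(x, axis=-1)[..., lo:hi]
    return core.mean(axis=-1), core.std(axis=-1, ddof=0)


def trimmed_zscore(x: np.ndarray, trim: float = 0.1) -> np.ndarray:
    """Z-score using trimmed moments; the *full* signal is transformed."""
    m, s = trimmed_stats(x, trim)
    if np.any(s == 0):
        raise ValueError("trimmed SD is zero (constant central mass)")
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return (x - m[..., None]) / s[..., None]


def channel_power(z_signals: np.ndarray, fs: float,
                  params: SpectralParams | None = None) -> np.ndarray:
    """Broadband (0.1-150 Hz) mean PSD per channel of z-scored signals.

    The rejection statistic only needs a stable whole-session power
    estimate, so the Welch windows here do not overlap (overlap buys
    variance reduction that a 5-SD outlier rule does not need, at five
    times the cost).
    """
    from dataclasses import replace
    params = replace(params or SpectralParams(), overlap_frac=0.0)
    _, psd = welch_psd(z_signals, fs, params)
    return psd.mean(axis=-1)


def reject_channels(power: np.ndarray, n_sd: float = 5.0) -> np.ndarray:
    """Keep-mask over channels from the 5-SD broadband-power rule.

    A channel is discarded when its power deviates from the across-channel
    mean by more than ``n_sd`` times the across-channel SD (mean and SD are
    computed over *all* channels, outlier candidates included).
    """
    power = np.asarray(power, dtype=float)
    if power.size < 2:
        raise ValueError("need at least 2 channels")
    dev = np.abs(power - power.mean())
    sd = power.std(ddof=0)
    if sd == 0:
        return np.ones(power.size, dtype=bool)
    return dev <= n_sd * sd


def build_epochs(labels: np.ndarray, fps: float, min_epoch_s: float = 2.0,
                 animal_id: str = "") -> list:
    """Chamber visits as epochs; visits shorter than ``min_epoch_s`` are dropped.

    Maximal constant-label runs of the per-frame chamber labels become
    epochs ``[start_s, end_s)``.  Short runs are discarded (they cannot fit
    enough Welch windows) and their neighbours are *not* merged — the
    animal genuinely left the chamber.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    epochs = []
    for s, e in zip(starts, ends):
        dur = (e - s) / fps
        if dur >= min_epoch_s:
            epochs.append(Epoch(s / fps, e / fps, str(labels[s]), animal_id))
    if not epochs:
        raise ValueError("no epoch survives the minimum-length rule")
    return epochs


def epoch_samples(epoch: Epoch, fs: float, n_samples: int | None = None) -> slice:
    """Sample slice of an epoch in a signal sampled at ``fs``."""
    i0 = int(round(epoch.start_s * fs))
    i1 = int(round(epoch.end_s * fs))
    if n_samples is not None:
        i1 = min(i1, n_samples)
    return slice(i0, i1)


def reject_epochs(epochs: list, z_signals: np.ndarray, fs: float,
                  z_max: float = 5.0,
                  channel_mask: np.ndarray | None = None) -> tuple:
    """Drop epochs containing any |z| > ``z_max`` sample on a kept channel.

    Returns ``(kept, dropped)``.  ``z_max=inf`` is the identity.  Raises if
    nothing survives.
    """
    z = np.asarray(z_signals)
    if channel_mask is not None:
        z = z[np.asarray(channel_mask, dtype=bool)]
    kept, dropped = [], []
    for ep in epochs:
        seg = z[:, epoch_samples(ep, fs, z.shape[-1])]
        if seg.size and np.abs(seg).max() > z_max:
            dropped.append(ep)
        else:
            kept.append(ep)
    if not kept:
        raise ValueError("all epochs rejected by the artifact rule")
    return kept, dropped
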