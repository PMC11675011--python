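"""Synthetic three-chamber cohorts with known ground truth.

The generator emulates the data structure the analysis assumes: two groups
of animals (sham and injured), each contributing one 30-min session of a
20-fps snout trajectory through a three-chamber maze plus a 32-channel LFP
recording (8 cannula bundles x 4 wires) on a shared clock.

Behaviour
---------
Chamber occupancy follows a per-animal dwell-probability vector over
(social, center, nonsocial).  Visits are scheduled by a deficit-tracking
scheduler (the next chamber is the one furthest below its target share,
dwell durations jittered around a preference-scaled mean), so realised
occupancy fractions converge to the programmed probabilities to within
roughly one dwell.  Within a visit the snout performs a persistent-velocity
random walk with reflecting chamber walls, which yields session path
lengths in the 15-25 m range typical of a 30-min test.

Electrophysiology
-----------------
Each channel is a sum of

* a dominant low-frequency rhythm (constant-envelope oscillation whose
  instantaneous frequency wanders over 2-6 Hz),
* pink (1/f) background noise, softly saturated,
* a bundle-wide common-mode component (what local referencing removes),
* a gamma-band oscillator (25-60 Hz), whose amplitude in injured animals
  is scaled by ``power_deficit`` — band power therefore scales by its
  square.

Oscillators are constant-envelope phase-modulated waves rather than
filtered Gaussian noise: real LFP rhythms have a bounded crest factor, and
this keeps artifact-free synthetic data well clear of the |z| = 5
trial-rejection threshold applied downstream.

Coupling between the designated hub regions is a single shared latent
gamma source mixed into each hub channel as
``sqrt(1 - kappa^2) * private + kappa * shared`` with the gain kappa
switched per sample by (group, occupied chamber): ``coupling_social_sham``
while a sham animal is in the social chamber, ``coupling_baseline``
everywhere else.  The mixing is variance-preserving, so coupling changes
coherence without changing band power, and the programmed band coherence
between two hubs is approximately ``kappa^4 * (r / (1 + r))^2`` where r is
the in-band oscillator-to-background power ratio.  Per-bundle local
referencing downstream keeps a fraction (m-1)/m of each channel (m = 4
wires per bundle) and therefore scales hub-pair coherence by a further
((m-1)/m)^2 = 0.5625; the default gains are chosen so the *pipeline*
estimates land near 0.33 (sham social) vs 0.23 (elsewhere), a range
typical of strongly coupled region pairs in such preparations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import CHAMBERS, ChamberGeometry
from .io import (LFPRecording, write_json, write_lfp_h5, write_region_map,
                 write_track_csv)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "DEFAULT_REGIONS",
    "DEFAULT_BUNDLES",
    "HUB_REGIONS",
    "generate_track",
    "generate_lfp",
    "generate_session",
    "generate_cohort_data",
    "generate_cohort",
]

#: Default 32-region montage: 8 cannula bundles x 4 wires.  Region labels
#: follow the rodent atlas abbreviations used for this recording technique;
#: ``-R`` marks the contralateral duplicates that fill the montage.
DEFAULT_BUNDLES = {
    0: ("M2", "Prl", "IL", "VO"),
    1: ("A24b", "LO", "AI", "LFC"),
    2: ("M1", "ALM", "PPx", "V1"),
    3: ("DMS", "VMS", "AcbC", "MT"),
    4: ("AcbSh", "CT", "DLS", "STN"),
    5: ("BLaAMG", "CeAMG", "CA3", "CA1"),
    6: ("DG", "V1-R", "M1-R", "M2-R"),
    7: ("PPx-R", "DMS-R", "MT-R", "CA1-R"),
}
DEFAULT_REGIONS = tuple(n for b in sorted(DEFAULT_BUNDLES) for n in DEFAULT_BUNDLES[b])
DEFAULT_BUNDLE_ID = tuple(b for b in sorted(DEFAULT_BUNDLES) for _ in DEFAULT_BUNDLES[b])

#: The six hub regions that carry the programmed social-coupling effect:
#: ventromedial striatum, cingulate A24b, accumbens shell, anterolateral
#: motor cortex, prelimbic cortex, basolateral amygdala — one per bundle,
#: so no hub pair is masked by the same-cannula rule.
HUB_REGIONS = ("VMS", "A24b", "AcbSh", "ALM", "Prl", "BLaAMG")

_GROUPS = ("sham", "tbi")


def _stable_key(animal_id: str) -> int:
    """Process-independent integer key for an animal id."""
    return zlib.crc32(animal_id.encode()) & 0x7FFFFFFF


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the emulated study: 9 sham vs 12 injured animals,
    30-min sessions, 20-fps tracking, LFP at 600 Hz (the analysis band
    tops out at 150 Hz; raw-rate data are decimated on ingestion), the
    25-60 Hz gamma band, a 0.75 gamma-amplitude deficit after injury, and
    hub coupling gains chosen so hub-pair coherence estimated by the full
    pipeline is ~0.33 in sham social epochs vs ~0.23 elsewhere.
    Dwell-probability vectors are
    ordered (social, center, nonsocial) and anchored to the reported
    group-mean chamber times.
    """

    n_sham: int = 9
    n_tbi: int = 12
    session_s: float = 1800.0
    fs_hz: float = 600.0
    fps: float = 20.0
    gamma_band: tuple = (25.0, 60.0)
    power_deficit: float = 0.75
    coupling_social_sham: float = 0.92
    coupling_baseline: float = 0.84
    pref_sham: tuple = (0.407, 0.478, 0.115)
    pref_tbi: tuple = (0.167, 0.537, 0.296)
    pref_jitter_conc: float = 60.0
    coupled_regions: tuple = HUB_REGIONS
    region_names: tuple = DEFAULT_REGIONS
    bundle_id: tuple = DEFAULT_BUNDLE_ID
    delta_amp: float = 5.0
    gamma_amp: float = 1.5
    bg_sigma: float = 1.0
    cm_sigma: float = 1.0
    amp_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("pref_sham", "pref_tbi"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != 3 or (v < 0).any():
                raise ValueError(f"{name} must be 3 non-negative probabilities")
            if v.sum() <= 0:
                raise ValueError(f"{name} has zero total")
            setattr(self, name, tuple(v / v.sum()))
        if not 0 < self.power_deficit <= 1:
            raise ValueError("power_deficit must be in (0, 1]")
        for name in ("coupling_social_sham", "coupling_baseline"):
            k = getattr(self, name)
            if not 0 <= k <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fs_hz <= 2 * self.gamma_band[1]:
            raise ValueError("fs_hz must exceed twice the gamma upper edge")
        if len(self.region_names) != len(self.bundle_id):
            raise ValueError("region_names and bundle_id must align")
        missing = set(self.coupled_regions) - set(self.region_names)
        if missing:
            raise ValueError(f"coupled regions not in montage: {sorted(missing)}")

    def pref(self, group: str) -> np.ndarray:
        return np.asarray(self.pref_sham if group == "sham" else self.pref_tbi)

    def animal_ids(self):
        return ([f"sham{i + 1:02d}" for i in range(self.n_sham)]
                + [f"tbi{i + 1:02d}" for i in range(self.n_tbi)])

    def group_of(self, animal_id: str) -> str:
        for g in _GROUPS:
            if animal_id.startswith(g):
                return g
        raise ValueError(f"cannot infer group from animal id {animal_id!r}")

    def kappa(self, group: str, chamber: str) -> float:
        if group == "sham" and chamber == "social":
            return self.coupling_social_sham
        return self.coupling_baseline


@dataclass
class GroundTruth:
    """Programmed quantities of a generated cohort, for recovery tests."""

    dwell_s: dict = field(default_factory=dict)        # animal -> chamber -> s
    pref: dict = field(default_factory=dict)           # animal -> 3-vector
    gamma_amplitude: dict = field(default_factory=dict)  # animal -> per-channel
    kappa: dict = field(default_factory=dict)          # group -> chamber -> gain
    coupled_regions: tuple = HUB_REGIONS

    def as_dict(self) -> dict:
        return {
            "dwell_s": self.dwell_s,
            "pref": {a: list(p) for a, p in self.pref.items()},
            "gamma_amplitude": {a: list(v) for a, v in self.gamma_amplitude.items()},
            "kappa": self.kappa,
            "coupled_regions": list(self.coupled_regions),
        }


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def _schedule_visits(pref: np.ndarray, n_frames: int, fps: float,
                     rng: np.random.Generator,
                     base_dwell_s: float = 15.0) -> list:
    """Chamber visit schedule tracking the target occupancy fractions.

    Greedy deficit scheduler: after each visit the next chamber is the
    (different) one whose realised share lags its target the most, so
    occupancy is controlled by visit *frequency* while every visit keeps a
    comparable (uniform-jittered) duration — long enough that chamber
    visits are not lost to the downstream minimum-epoch rule.  Realised
    occupancy deviates from target by at most about one dwell length.
    """
    active = [i for i in range(3) if pref[i] > 0]
    if len(active) == 1:
        return [(active[0], n_frames)]
    mean_frames = base_dwell_s * fps
    start = 1 if pref[1] > 0 else int(np.argmax(pref))  # start in the center
    realized = np.zeros(3)
    t, current = 0, start
    runs = []
    while t < n_frames:
        dwell = int(round(mean_frames * rng.uniform(0.6, 1.4)))
        dwell = max(1, min(dwell, n_frames - t))
        runs.append((current, dwell))
        realized[current] += dwell
        t += dwell
        deficits = pref * t - realized
        nxt = max((i for i in active if i != current), key=lambda i: deficits[i])
        current = nxt
    return runs


def _walk_positions(runs: list, geom: ChamberGeometry, rng: np.random.Generator,
                    step_sd_mm: float = 0.55, persistence: float = 0.9,
                    margin_mm: float = 10.0) -> np.ndarray:
    """Persistent-velocity reflecting walk through the scheduled visits."""
    n = sum(d for _, d in runs)
    pos = np.empty((n, 2))
    v = np.zeros(2)
    sd_innov = step_sd_mm * np.sqrt(1.0 - persistence ** 2)
    first_chamber = CHAMBERS[runs[0][0]]
    x_lo, x_hi, y_lo, y_hi = geom.chamber_bounds(first_chamber)
    p = np.array([(x_lo + x_hi) / 2.0, (y_lo + y_hi) / 2.0])
    t = 0
    for ci, dwell in runs:
        x_lo, x_hi, y_lo, y_hi = geom.chamber_bounds(CHAMBERS[ci])
        lo = np.array([x_lo + margin_mm, y_lo + margin_mm])
        hi = np.array([x_hi - margin_mm, y_hi - margin_mm])
        p = np.clip(p, lo, hi)  # enter through the nearest wall point
        innov = rng.normal(0.0, sd_innov, size=(dwell, 2))
        for k in range(dwell):
            v = persistence * v + innov[k]
            p = p + v
            for ax in range(2):  # reflect off chamber walls
                if p[ax] < lo[ax]:
                    p[ax] = 2 * lo[ax] - p[ax]
                    v[ax] = -v[ax]
                elif p[ax] > hi[ax]:
                    p[ax] = 2 * hi[ax] - p[ax]
                    v[ax] = -v[ax]
            pos[t + k] = p
        t += dwell
    return pos


def _likelihoods(runs: list, n: int, rng: np.random.Generator,
                 low_frac: float = 0.01) -> np.ndarray:
    """Tracking confidences: ~0.99 typically, a few low-confidence frames.

    Low-confidence frames are drawn away from visit boundaries so that the
    downstream hold-last-position filter cannot flip a chamber label —
    the written track then reproduces the ground-truth labels exactly.
    """
    lik = np.clip(1.0 - rng.exponential(0.003, size=n), 0.0, 1.0)
    interior = []
    t = 0
    for _, dwell in runs:
        if dwell > 6:
            interior.append(np.arange(t + 3, t + dwell - 3))
        t += dwell
    if interior:
        interior = np.concatenate(interior)
        n_low = int(round(low_frac * n))
        if n_low > 0 and interior.size:
            low_idx = rng.choice(interior, size=min(n_low, interior.size),
                                 replace=False)
            lik[low_idx] = rng.uniform(0.2, 0.85, size=low_idx.size)
    return lik


def generate_track(spec: CohortSpec, animal_id: str, group: str | None = None,
                   pref=None, rng: np.random.Generator | None = None,
                   geom: ChamberGeometry | None = None):
    """Generate one animal's snout track.

    Returns ``(track, truth)`` where ``track`` is a frame-indexed DataFrame
    with ``x_mm, y_mm, likelihood`` and ``truth`` holds the per-frame
    chamber labels, realised dwell seconds and the dwell-probability
    vector used.  Dwell seconds sum exactly to the session length.
    """
    group = group or spec.group_of(animal_id)
    pref = np.asarray(spec.pref(group) if pref is None else pref, dtype=float)
    if pref.sum() <= 0:
        raise ValueError("dwell-probability vector has zero total")
    pref = pref / pref.sum()
    rng = rng or np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_stable_key(animal_id),)))
    geom = geom or ChamberGeometry()
    n = int(round(spec.session_s * spec.fps))
    runs = _schedule_visits(pref, n, spec.fps, rng)
    labels = np.concatenate([np.full(d, CHAMBERS[c], dtype="<U9")
                             for c, d in runs])
    pos = _walk_positions(runs, geom, rng)
    lik = _likelihoods(runs, n, rng)
    track = pd.DataFrame({"x_mm": pos[:, 0], "y_mm": pos[:, 1],
                          "likelihood": lik},
                         index=pd.RangeIndex(n))
    dwell = {ch: float(np.count_nonzero(labels == ch)) / spec.fps
             for ch in CHAMBERS}
    truth = {"animal_id": animal_id, "group": group, "labels": labels,
             "dwell_s": dwell, "pref": pref.tolist()}
    return track, truth


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------

def _pink_noise(rng, shape, fs, f_floor=0.5):
    """Unit-variance 1/f-power noise along the last axis (flat below ``f_floor``)."""
    white = rng.standard_normal(shape, dtype=np.float32)
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = (1.0 / np.sqrt(np.maximum(f, f_floor))).astype(np.float32)
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _saturate(x, c=3.0):
    """Soft amplitude saturation at ``c`` (in units of each row's SD)."""
    s = x.std(axis=-1, keepdims=True)
    return c * s * np.tanh(x / (c * s))


def _wandering_oscillator(rng, shape, fs, lo, hi, tau_s):
    """Constant-envelope wave with OU-wandering instantaneous frequency.

    The frequency performs an AR(1) walk around the band centre (sd one
    quarter of the bandwidth, mixing time ``tau_s``), folded back into
    [lo, hi]; the returned signal is ``cos(phase)`` with a random initial
    phase per row — unit crest factor, variance 1/2.
    """
    mu, sd = 0.5 * (lo + hi), 0.25 * (hi - lo)
    dt = 1.0 / fs
    a = max(0.0, 1.0 - dt / tau_s)
    innov = rng.standard_normal(shape, dtype=np.float32)
    innov *= np.float32(sd * np.sqrt(1.0 - a ** 2))
    f = mu + sps.lfilter([np.float32(1.0)], [1.0, -a],
                         innov, axis=-1).astype(np.float32)
    width = hi - lo
    f = lo + np.abs(np.mod(f - lo, 2 * width) - width)  # reflect into band
    # accumulate the phase in float64 (it grows without bound), then wrap
    phase = np.cumsum(f, axis=-1, dtype=np.float64) * (2.0 * np.pi * dt)
    phase += rng.uniform(0, 2 * np.pi, size=shape[:-1] + (1,))
    return np.cos(np.mod(phase, 2.0 * np.pi).astype(np.float32))


def _kappa_per_sample(spec: CohortSpec, group: str, epoch_labels: np.ndarray,
                      n_samples: int) -> np.ndarray:
    """Per-sample coupling gain from the per-frame chamber labels."""
    frame = np.minimum(
        (np.arange(n_samples) / spec.fs_hz * spec.fps).astype(int),
        len(epoch_labels) - 1,
    )
    lab = np.asarray(epoch_labels)[frame]
    kap = np.full(n_samples, spec.kappa(group, "center"), dtype=np.float32)
    for ch in CHAMBERS:
        kap[lab == ch] = spec.kappa(group, ch)
    return kap


def generate_lfp(spec: CohortSpec, animal_id: str, epoch_labels: np.ndarray,
                 group: str | None = None,
                 rng: np.random.Generator | None = None,
                 coupled_regions: tuple | None = None):
    """Generate one animal's 32-channel LFP session.

    ``epoch_labels`` are the per-frame chamber labels from the animal's
    track (same clock).  Returns ``(recording, truth)``; ``truth`` records
    the per-channel gamma amplitudes and the coupling gains per chamber.
    """
    group = group or spec.group_of(animal_id)
    if spec.fs_hz <= 2 * spec.gamma_band[1]:
        raise ValueError("sampling rate too low for the gamma band")
    rng = rng or np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(_stable_key(animal_id), 1)))
    coupled = tuple(coupled_regions if coupled_regions is not None
                    else spec.coupled_regions)
    names = list(spec.region_names)
    bundles = np.asarray(spec.bundle_id)
    n_ch = len(names)
    n = int(round(spec.session_s * spec.fs_hz))
    fs = spec.fs_hz
    g_lo, g_hi = spec.gamma_band

    deficit = spec.power_deficit if group == "tbi" else 1.0
    amp = (spec.gamma_amp * deficit * np.exp(
        rng.normal(0.0, spec.amp_jitter_sd, size=n_ch))).astype(np.float32)

    kap = _kappa_per_sample(spec, group, epoch_labels, n)
    mix_private = np.sqrt(1.0 - kap ** 2)
    shared = _wandering_oscillator(rng, (n,), fs, g_lo, g_hi, tau_s=0.1)

    uniq = np.unique(bundles)
    common = _saturate(_pink_noise(rng, (uniq.size, n), fs)) * spec.cm_sigma
    cm_row = {b: i for i, b in enumerate(uniq)}

    sig = np.float32(spec.delta_amp) * _wandering_oscillator(
        rng, (n_ch, n), fs, 2.0, 6.0, tau_s=0.5)
    sig += _saturate(_pink_noise(rng, (n_ch, n), fs)) * spec.bg_sigma
    private = _wandering_oscillator(rng, (n_ch, n), fs, g_lo, g_hi, tau_s=0.1)
    is_coupled = np.array([nm in coupled for nm in names])
    gamma = private
    gamma[is_coupled] = (mix_private * private[is_coupled]
                         + kap * shared)
    sig += amp[:, None] * gamma
    sig += common[[cm_row[b] for b in bundles]]

    rec = LFPRecording(sig.astype(np.float32, copy=False), fs, names,
                       bundles, t0=0.0)
    truth = {
        "animal_id": animal_id, "group": group,
        "gamma_amplitude": amp.tolist(),
        "coupled_regions": list(coupled),
        "kappa": {ch: spec.kappa(group, ch) for ch in CHAMBERS},
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _jitter_pref(pref: np.ndarray, conc: float, rng) -> np.ndarray:
    """Per-animal dwell vector: Dirichlet around the group preference."""
    if conc <= 0:
        return pref.copy()
    nz = pref > 0
    out = np.zeros_like(pref)
    out[nz] = rng.dirichlet(conc * pref[nz])
    return out


def generate_session(spec: CohortSpec, animal_id: str, index: int):
    """One animal's full session (track + LFP) with a deterministic stream."""
    group = spec.group_of(animal_id)
    ss = np.random.SeedSequence(spec.seed, spawn_key=(index,))
    r_pref, r_track, r_lfp = [np.random.default_rng(s) for s in ss.spawn(3)]
    pref = _jitter_pref(spec.pref(group), spec.pref_jitter_conc, r_pref)
    track, t_truth = generate_track(spec, animal_id, group, pref, r_track)
    rec, l_truth = generate_lfp(spec, animal_id, t_truth["labels"], group, r_lfp)
    return {"animal_id": animal_id, "group": group, "track": track,
            "labels": t_truth["labels"], "rec": rec,
            "dwell_s": t_truth["dwell_s"], "pref": pref,
            "gamma_amplitude": l_truth["gamma_amplitude"]}


def generate_cohort_data(spec: CohortSpec):
    """All sessions in memory plus the cohort ground truth."""
    sessions = [generate_session(spec, a, i)
                for i, a in enumerate(spec.animal_ids())]
    truth = GroundTruth(coupled_regions=tuple(spec.coupled_regions))
    for s in sessions:
        truth.dwell_s[s["animal_id"]] = s["dwell_s"]
        truth.pref[s["animal_id"]] = list(np.round(s["pref"], 12))
        truth.gamma_amplitude[s["animal_id"]] = s["gamma_amplitude"]
    truth.kappa = {g: {ch: spec.kappa(g, ch) for ch in CHAMBERS}
                   for g in _GROUPS}
    return sessions, truth


def generate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a full synthetic cohort to disk.

    Produces ``tracks/<animal>.csv`` (pose CSV dialect),
    ``lfp/<animal>.h5`` (HDF5 container), ``region_map.yaml`` and a
    ``manifest.json`` holding the ground truth; returns the manifest.
    Regenerating with the same spec yields byte-identical manifests.
    """
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "lfp").mkdir(parents=True, exist_ok=True)
    sessions, truth = generate_cohort_data(spec)
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "animals": [],
        "ground_truth": truth.as_dict(),
    }
    for s in sessions:
        track_path = out / "tracks" / f"{s['animal_id']}.csv"
        lfp_path = out / "lfp" / f"{s['animal_id']}.h5"
        write_track_csv(track_path, s["track"])
        write_lfp_h5(lfp_path, s["rec"])
        manifest["animals"].append({
            "animal_id": s["animal_id"], "group": s["group"],
            "track": str(track_path.relative_to(out)),
            "lfp": str(lfp_path.relative_to(out)),
        })
    write_region_map(out / "region_map.yaml", spec.region_names, spec.bundle_id)
    write_json(out / "manifest.json", manifest)
    return manifest
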