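"""End-to-end orchestration: session processing and cohort statistics.

A *session* run scores behaviour from the pose track, conditions the LFP
(decimate -> per-bundle local referencing -> trimmed z-score -> 5-SD
channel rejection), cuts the session into chamber epochs, rejects
artifact epochs, and pools windowed cross-spectra per chamber condition.

A *cohort* run repeats this over all animals and then reproduces the
analysis sequence:

1. group x chamber mixed ANOVAs on chamber time and entries; independent
   t tests on social preference and locomotion;
2. gamma-band (25-60 Hz) power: group x chamber ANOVA on channel-mean
   power, per-channel group contrasts in the social chamber (Sidak), and
   optional per-frequency t-test masks (uncorrected + FDR);
3. gamma coherence: per-animal 32 x 32 matrices, per-region RSS, region
   selection from the sham/social reference condition, a group x chamber
   ANOVA on region-mean RSS, and per-pair ANOVAs + post hoc t tests for
   the C(k,2) selected-region pairs (the per-pair summary table).

Everything is deterministic given the configuration and inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (CHAMBERS, BehaviorSummary, ChamberGeometry,
                       assign_chamber, filter_likelihood, summarize_track)
from .connectivity import (CoherenceMatrix, build_matrix, connectogram_edges,
                           pairwise_table, rss_by_region, select_top_regions)
from .io import (LFPRecording, read_json, read_lfp_h5, read_track_csv,
                 write_json)
from .preprocess import (build_epochs, channel_power, decimate, epoch_samples,
                         local_reference, reject_channels, reject_epochs,
                         trimmed_zscore)
from .spectral import (DEFAULT_BANDS, GAMMA, CrossSpectralAccumulator,
                       SpectralParams)
from . import stats as st

__all__ = ["RunConfig", "SessionResult", "CohortResult",
           "run_session", "run_cohort", "load_cohort_dir"]

_LFP_CHAMBERS = ("social", "nonsocial")


@dataclass
class RunConfig:
    """All thresholds and estimator settings of one analysis run.

    Defaults are the documented analysis settings: 1-s Welch windows with
    80% overlap on a 0.5-Hz grid over 0.1-150 Hz, the 25-60 Hz gamma
    band, |z| = 5 trial rejection, 5-SD channel rejection, 10% two-sided
    amplitude trimming, 2-s minimum epochs, 0.25-s entry debounce, top
    k = 6 region selection, alpha = 0.05.
    """

    target_fs: float = 600.0
    spectral: SpectralParams = field(default_factory=SpectralParams)
    band: str = "gamma"
    z_max: float = 5.0
    channel_sd: float = 5.0
    trim: float = 0.1
    min_epoch_s: float = 2.0
    debounce_s: float = 0.25
    likelihood_min: float = 0.9
    include_center_in_T: bool = False
    reference_exclude_self: bool = False
    selection_k: int = 6
    alpha: float = 0.05
    fps: float = 20.0
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    compute_per_frequency: bool = True
    csd_f_max: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("z_max", "channel_sd", "min_epoch_s", "debounce_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.band_def.lo_hz, self.band_def.hi_hz
        flo, fhi = self.spectral.f_range
        if not (flo <= lo < hi <= fhi):
            raise ValueError("analysis band must lie within f_range")

    @property
    def band_def(self):
        return DEFAULT_BANDS.get(self.band, GAMMA)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectral"]["f_range"] = list(d["spectral"]["f_range"])
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        if "spectral" in doc:
            sp = doc["spectral"]
            if "f_range" in sp:
                sp["f_range"] = tuple(sp["f_range"])
            doc["spectral"] = SpectralParams(**sp)
        if "geometry" in doc:
            doc["geometry"] = ChamberGeometry(**doc["geometry"])
        return cls(**doc)


@dataclass
class SessionResult:
    """Per-session outputs feeding the cohort statistics."""

    animal_id: str
    group: str
    behavior: BehaviorSummary
    kept_channels: np.ndarray
    freqs: np.ndarray
    psd: dict                 # chamber -> (C, F) or None if missing
    band_coherence: dict      # chamber -> (C, C) or None
    n_windows: dict           # chamber -> pooled window count
    n_epochs: dict            # chamber -> kept epoch count
    dropped: dict             # stage -> count
    region_names: list
    bundle_id: np.ndarray


def run_session(cfg: RunConfig, track: pd.DataFrame, rec: LFPRecording,
                animal_id: str = "", group: str = "") -> SessionResult:
    """Process one session end to end (behaviour + LFP conditioning + spectra)."""
    behavior = summarize_track(
        track, cfg.geometry, cfg.fps, animal_id,
        min_likelihood=cfg.likelihood_min, debounce_s=cfg.debounce_s,
        include_center=cfg.include_center_in_T, with_heatmap=False,
    )
    labels = assign_chamber(filter_likelihood(track, cfg.likelihood_min),
                            cfg.geometry)

    rec = decimate(rec, cfg.target_fs)
    rec = local_reference(rec, exclude_self=cfg.reference_exclude_self)
    z = trimmed_zscore(rec.signal, cfg.trim)
    power = channel_power(z, rec.fs_hz, cfg.spectral)
    kept = reject_channels(power, cfg.channel_sd)

    n_runs = 1 + int(np.count_nonzero(labels[1:] != labels[:-1]))
    epochs = build_epochs(labels, cfg.fps, cfg.min_epoch_s, animal_id)
    n_built = len(epochs)
    epochs, dropped_epochs = reject_epochs(epochs, z, rec.fs_hz, cfg.z_max,
                                           channel_mask=kept)

    psd, band_coh, n_windows, n_epochs = {}, {}, {}, {}
    freqs = None
    for chamber in _LFP_CHAMBERS:
        chamber_eps = [e for e in epochs if e.chamber == chamber]
        n_epochs[chamber] = len(chamber_eps)
        if not chamber_eps:
            psd[chamber] = None
            band_coh[chamber] = None
            n_windows[chamber] = 0
            continue
        acc = CrossSpectralAccumulator(
            rec.n_channels, rec.fs_hz, cfg.spectral, f_max=cfg.csd_f_max,
            single_precision=(z.dtype == np.float32))
        for e in chamber_eps:
            acc.add_epoch(z[:, epoch_samples(e, rec.fs_hz, z.shape[-1])])
        freqs = acc.freqs
        if acc.n_windows == 0:
            psd[chamber] = None
            band_coh[chamber] = None
            n_windows[chamber] = 0
            continue
        psd[chamber] = acc.psd()
        band_coh[chamber] = acc.band_coherence(cfg.band_def)
        n_windows[chamber] = acc.n_windows

    return SessionResult(
        animal_id=animal_id, group=group, behavior=behavior,
        kept_channels=kept, freqs=freqs, psd=psd, band_coherence=band_coh,
        n_windows=n_windows, n_epochs=n_epochs,
        dropped={"channels": int((~kept).sum()),
                 "epochs_artifact": len(dropped_epochs),
                 "epochs_short": n_runs - n_built,
                 "epochs_built": n_built},
        region_names=list(rec.channel_names), bundle_id=rec.bundle_id,
    )


@dataclass
class CohortResult:
    """Cohort-level tables, selections, and statistics."""

    behavior: pd.DataFrame
    band_power: pd.DataFrame        # animal, group, chamber, region, value
    rss: pd.DataFrame               # animal, group, chamber, region, value
    selected_regions: list
    pair_values: pd.DataFrame
    stats: dict                     # name -> stats DataFrame
    matrices: dict                  # (animal, group, chamber) -> CoherenceMatrix
    per_frequency: pd.DataFrame | None
    provenance: dict

    def stats_table(self) -> pd.DataFrame:
        frames = []
        for name, df in self.stats.items():
            d = df.copy()
            d.insert(0, "analysis", name)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        self.band_power.to_csv(out / "band_power.csv", index=False)
        self.rss.to_csv(out / "rss.csv", index=False)
        self.pair_values.to_csv(out / "pair_coherence.csv", index=False)
        self.stats_table().to_csv(out / "stats.csv", index=False)
        if self.per_frequency is not None:
            self.per_frequency.to_csv(out / "per_frequency.csv", index=False)
        write_json(out / "selected_regions.json",
                   {"selected": self.selected_regions})
        write_json(out / "provenance.json", self.provenance)
        # group-mean connectogram for the reference condition
        ref = [m for (a, g, c), m in self.matrices.items()
               if g == "sham" and c == "social"]
        if ref:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean([m.masked() for m in ref], axis=0)
            mat = CoherenceMatrix(np.nan_to_num(mean), ref[0].valid,
                                  ref[0].region_names)
            write_json(out / "connectogram.json",
                       {"edges": connectogram_edges(mat)})


def load_cohort_dir(cohort_dir):
    """Sessions from a directory written by :func:`generate_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = read_json(cohort_dir / "manifest.json")
    sessions = []
    for a in manifest["animals"]:
        track = read_track_csv(cohort_dir / a["track"])
        rec = read_lfp_h5(cohort_dir / a["lfp"])
        sessions.append({"animal_id": a["animal_id"], "group": a["group"],
                         "track": track, "rec": rec})
    return sessions, manifest


def _mixed_2x2(table, dv="value"):
    return st.mixed_anova(table, dv=dv)


def _behavior_stats(behavior: pd.DataFrame, alpha: float) -> dict:
    long_rows = []
    for _, r in behavior.iterrows():
        for ch in _LFP_CHAMBERS:
            long_rows.append({"animal_id": r["animal_id"], "group": r["group"],
                              "chamber": ch, "time": r[f"time_{ch}_s"],
                              "entries": r[f"entries_{ch}"]})
    long = pd.DataFrame(long_rows)
    out = {
        "behavior_time": _mixed_2x2(long, dv="time"),
        "behavior_entries": _mixed_2x2(long, dv="entries"),
    }
    sham = behavior[behavior.group == "sham"]
    tbi = behavior[behavior.group == "tbi"]
    rows = [
        st.t_test_ind(sham["preference_ratio"], tbi["preference_ratio"],
                      "preference_ratio"),
        st.t_test_ind(sham["preference_diff"], tbi["preference_diff"],
                      "preference_diff"),
        st.t_test_ind(sham["distance_cm"], tbi["distance_cm"], "locomotion"),
    ]
    # post hoc chamber contrasts, Sidak over the two chambers
    posthoc = []
    for ch in _LFP_CHAMBERS:
        r = st.t_test_ind(sham[f"time_{ch}_s"], tbi[f"time_{ch}_s"],
                          f"time_{ch}: sham vs tbi")
        posthoc.append(r)
    for g, df_g in (("sham", sham), ("tbi", tbi)):
        r = st.t_test_paired(df_g["time_social_s"], df_g["time_nonsocial_s"],
                             f"time {g}: social vs nonsocial")
        posthoc.append(r)
    for r in posthoc:
        r["p_adj"] = st.sidak(r["p"], 2) if np.isfinite(r["p"]) else np.nan
        r["method"] += "+sidak"
        r["family_size"] = 2
    out["behavior_tests"] = pd.DataFrame(rows + posthoc,
                                         columns=st.STATS_COLUMNS)
    return out


def run_cohort(cfg: RunConfig, sessions: list, out_dir=None) -> CohortResult:
    """Cohort analysis over processed or raw sessions.

    ``sessions`` is a list of dicts with ``animal_id``, ``group``,
    ``track`` and ``rec`` (as produced by
    :func:`socoh.simulate.generate_cohort_data` or
    :func:`load_cohort_dir`).  Requires >= 2 animals per group.
    """
    groups = pd.Series([s["group"] for s in sessions])
    if (groups.value_counts().reindex(["sham", "tbi"]).fillna(0) < 2).any():
        raise ValueError("need at least 2 animals per group")

    results = [run_session(cfg, s["track"], s["rec"], s["animal_id"], s["group"])
               for s in sessions]

    behavior = pd.DataFrame([r.behavior.as_row() for r in results])
    behavior.insert(1, "group", [r.group for r in results])

    region_names = results[0].region_names
    band = cfg.band_def

    # --- tidy per-condition tables -------------------------------------
    power_rows, rss_rows = [], []
    matrices = {}
    for r in results:
        for chamber in _LFP_CHAMBERS:
            if r.psd[chamber] is None:
                continue  # condition missing (never visited long enough)
            from .spectral import band_aggregate
            bp = band_aggregate(r.freqs, r.psd[chamber], band)
            mat = build_matrix(r.band_coherence[chamber], r.bundle_id,
                               r.kept_channels, region_names)
            matrices[(r.animal_id, r.group, chamber)] = mat
            rss_vals = rss_by_region(mat)
            for i, name in enumerate(region_names):
                power_rows.append({
                    "animal_id": r.animal_id, "group": r.group,
                    "chamber": chamber, "region": name,
                    "value": bp[i] if r.kept_channels[i] else np.nan})
                rss_rows.append({
                    "animal_id": r.animal_id, "group": r.group,
                    "chamber": chamber, "region": name, "value": rss_vals[i]})
    band_power = pd.DataFrame(power_rows)
    rss_table = pd.DataFrame(rss_rows)

    stats_out = _behavior_stats(behavior, cfg.alpha)

    # --- gamma power ----------------------------------------------------
    chan_mean = (band_power.groupby(["animal_id", "group", "chamber"])["value"]
                 .mean().reset_index().rename(columns={"value": "value"}))
    stats_out["gamma_power"] = _mixed_2x2(chan_mean)

    social = band_power[band_power.chamber == "social"]
    rows = []
    for name in region_names:
        sub = social[social.region == name]
        a = sub[sub.group == "sham"]["value"].dropna()
        b = sub[sub.group == "tbi"]["value"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            rows.append(st.t_test_ind(a, b, name))
    per_channel = pd.DataFrame(rows, columns=st.STATS_COLUMNS)
    if len(per_channel):
        m = len(per_channel)
        per_channel["p_adj"] = st.sidak(per_channel["p"].to_numpy(), m)
        per_channel["method"] += "+sidak"
        per_channel["family_size"] = m
    stats_out["gamma_power_per_region"] = per_channel

    # --- per-frequency contrasts (social chamber, channel-mean PSD) ----
    per_freq = None
    if cfg.compute_per_frequency:
        freqs = results[0].freqs
        by_group = {}
        for g in ("sham", "tbi"):
            arrs = [r.psd["social"][r.kept_channels].mean(axis=0)
                    for r in results
                    if r.group == g and r.psd["social"] is not None]
            by_group[g] = np.vstack(arrs) if arrs else None
        if by_group["sham"] is not None and by_group["tbi"] is not None:
            per_freq = st.per_frequency_contrast(by_group["sham"],
                                                 by_group["tbi"], freqs,
                                                 cfg.alpha)

    # --- RSS and region selection --------------------------------------
    ref = rss_table[(rss_table.group == "sham")
                    & (rss_table.chamber == "social")]
    ref_mean = ref.groupby("region")["value"].mean()
    ref_mean = ref_mean.reindex(region_names)
    selected = select_top_regions(ref_mean.to_numpy(), region_names,
                                  cfg.selection_k)

    rss_mean = (rss_table.groupby(["animal_id", "group", "chamber"])["value"]
                .mean().reset_index())
    stats_out["rss"] = _mixed_2x2(rss_mean)

    # electrode factor across the selected regions (social chamber):
    # repeated-measures ANOVA with sphericity (GG) correction
    sel_power = band_power[(band_power.chamber == "social")
                           & band_power.region.isin(selected)]
    wide_sel = sel_power.pivot_table(index="animal_id", columns="region",
                                     values="value")
    if wide_sel.shape[1] >= 3 and not wide_sel.isna().any().any():
        stats_out["gamma_power_electrode"] = st.rm_anova_gg(
            wide_sel.to_numpy())

    # --- selected-pair coherence (per-pair summary table) ---------------
    pair_vals = pairwise_table(selected, matrices)
    pair_anovas, posthoc_rows = [], []
    m_pairs = max(1, len(pair_vals["pair"].unique()))
    for pair, sub in pair_vals.groupby("pair", sort=True):
        try:
            aov = st.mixed_anova(sub)
        except ValueError:
            continue
        aov.insert(0, "pair", pair)
        pair_anovas.append(aov)
        wide = sub.pivot_table(index=["animal_id", "group"], columns="chamber",
                               values="value").reset_index()
        for g in ("sham", "tbi"):
            wg = wide[wide.group == g]
            if len(wg) >= 2 and {"social", "nonsocial"} <= set(wide.columns):
                r = st.t_test_paired(wg["social"], wg["nonsocial"],
                                     f"{pair} {g}: social vs nonsocial")
                posthoc_rows.append(r)
        for ch in _LFP_CHAMBERS:
            sub_ch = sub[sub.chamber == ch]
            a = sub_ch[sub_ch.group == "sham"]["value"].dropna()
            b = sub_ch[sub_ch.group == "tbi"]["value"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                posthoc_rows.append(st.t_test_ind(a, b,
                                                  f"{pair} {ch}: sham vs tbi"))
    if pair_anovas:
        pair_stats = pd.concat(pair_anovas, ignore_index=True)
        inter = pair_stats.effect == "group x chamber"
        pair_stats.loc[inter, "p_adj"] = st.sidak(
            pair_stats.loc[inter, "p"].to_numpy(), m_pairs)
        pair_stats.loc[inter, "method"] += "+sidak"
        pair_stats.loc[inter, "family_size"] = m_pairs
        stats_out["pair_anovas"] = pair_stats
    if posthoc_rows:
        ph = pd.DataFrame(posthoc_rows, columns=st.STATS_COLUMNS)
        ok = np.isfinite(ph["p"].to_numpy(float))
        ph.loc[ok, "p_adj"] = st.sidak(ph.loc[ok, "p"].to_numpy(), m_pairs)
        ph["method"] += "+sidak"
        ph["family_size"] = m_pairs
        stats_out["pair_posthoc"] = ph

    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_sessions": len(results),
        "dropped": {r.animal_id: r.dropped for r in results},
        "n_epochs": {r.animal_id: r.n_epochs for r in results},
    }

    result = CohortResult(
        behavior=behavior, band_power=band_power, rss=rss_table,
        selected_regions=selected, pair_values=pair_vals, stats=stats_out,
        matrices=matrices, per_frequency=per_freq, provenance=provenance,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
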