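# Methods

This note documents the models, estimators and design choices behind
`socoh`, and what the synthetic validation does and does not establish.

## The analysis

The pipeline links three-chamber sociability behaviour to brain-wide LFP
spectra and gamma-band functional connectivity in a two-group study
(sham-operated vs frontally injured rats, unbalanced 9 vs 12).

### Behavioural scoring

The snout position (20 fps pose tracking) determines chamber occupancy in
a 800 × 400 mm three-chamber maze split into equal vertical thirds.
Frames with tracking likelihood < 0.9 inherit the previous valid
position; points on a divider belong to the center chamber (a
deterministic tie-break). Scores per session:

- occupancy seconds per chamber (raw frame counts / fps — these sum to
  the session length exactly);
- entries, debounced at 0.25 s so boundary chatter of the snout over a
  divider is not counted as repeated entries; the session's first
  chamber counts as one entry;
- social preference, in both conventions in circulation:
  `diff = (S − N) / T` and `ratio = S / (S + N)` with S, N the social
  and nonsocial occupancy. By default T = S + N (center time excluded,
  matching the "total time spent in both chambers" reading), which makes
  `ratio = (diff + 1)/2` an identity; T may be configured to include the
  center, which breaks that identity. Both numbers are always reported
  because published descriptions of the index disagree between the
  difference and ratio forms;
- locomotion as snout path length, and a 10-mm-voxel occupancy heatmap
  smoothed with a mass-preserving Gaussian (σ = 1 voxel; σ is a free
  choice, the grid total stays within edge-truncation error of the
  session length).

### LFP conditioning

32 channels arranged as 8 cannula bundles × 4 microwires. The chain, in
order: decimation to 600 Hz (anti-aliased; the analysis band ends at
150 Hz), per-bundle common-average referencing (each channel minus the
mean of the four wires of its own cannula; configurable to exclude the
channel itself, which only rescales by 4/3), trimmed z-scoring (mean/SD
of the central 80% of samples by amplitude rank, so bipolar artifacts
cannot inflate the normalisation; the full signal is transformed),
channel rejection (drop channels whose broadband 0.1–150 Hz mean PSD
deviates > 5 SD from the across-channel mean, moments computed over all
channels), chamber epoching (maximal constant-chamber runs; runs < 2 s
are dropped — a 2-s epoch is the shortest that fits ≥ 5 Welch windows),
and epoch rejection (any kept channel reaching |z| > 5 inside an epoch
discards that epoch).

Order of operations is decimate → reference → z-score → channel
rejection → epoching → epoch rejection. The rejection statistic uses
non-overlapping Welch windows: a 5-SD outlier rule does not need the
variance reduction overlap buys, and this keeps whole-session scans
cheap.

One property worth knowing: with one deviant channel among 31 equal
ones, the standardised deviation is (31/32)/√(992/32768) ≈ 5.57
*independent of the outlier's magnitude* — a single clear outlier among
an otherwise homogeneous montage is always rejected, and the homogeneous
channels never are.

### Spectra and coherence

Welch estimation with 1-s Hamming windows, 80% overlap, and the FFT
zero-padded to a 0.5-Hz grid (a 1-s window natively yields 1 Hz; padding
is the only way to honour both the stated window length and grid),
restricted to 0.1–150 Hz, density scaling. Magnitude-squared coherence
`C = |Sxy|² / (Sxx Syy)` from the same windowed cross/auto spectra.
Bands: delta 1–4, theta 4–8, alpha 8–15, beta 15–30, and the analysis
gamma band 25–60 Hz; band values are unweighted means over bins.

Pooling across the chamber epochs of a condition accumulates windowed
cross-spectra over *all* windows of all epochs before the coherence
ratio is formed; this weights epochs by window count and is more stable
than averaging per-epoch coherences. With K averaged windows of
independent signals the estimator floor is ≈ 1/K (larger under overlap,
where windows correlate), which is why short epochs are excluded
upstream and why window counts are carried through the pipeline.

### Connectivity, RSS and selection

Per animal and chamber, band coherences fill a symmetric 32 × 32 matrix;
the diagonal, within-bundle pairs (8 × C(4,2) = 48 of 496) and pairs
touching rejected channels are invalid. Per region,
`RSS = sqrt(Σ σ_i²)` over its valid pairwise coherences — one number
combining connection count and strength. Regions are ranked by the
group-mean RSS of the *reference condition* (sham animals, social
chamber) and the top k = 6 are selected, ties broken alphabetically.
Selection never sees injured-group data, so it cannot be biased toward
injury effects; altering TBI data provably leaves the selected set
unchanged (tested).

### Statistics

Classical mixed-design ANOVA (between: group; within: chamber): group is
tested against subjects-within-groups, chamber and the interaction
against the subject × chamber error; with 9 + 12 animals all F tests
have (1, 19) degrees of freedom. Implemented from sums of squares in
NumPy (thousands of ANOVAs run inside replicate studies) and verified
against pingouin exactly for balanced and unbalanced designs. Within
factors of ≥ 3 levels get the Greenhouse–Geisser correction: ε from the
double-centred within-subject covariance, floored at 1/(levels−1)
(attained exactly when levels are perfectly correlated), multiplying
both df. Independent t tests use the pooled-variance (Student) form —
the df convention behind t(19) — and chamber contrasts within group use
paired t tests. Multiplicity: Sidak `1 − (1 − p)^m` for small planned
families (the 15 selected-region pairs; per-chamber contrasts), and
Benjamini–Hochberg step-up FDR for per-frequency-bin t-test masks, which
are reported both raw and adjusted. α = 0.05 throughout.

## The synthetic cohort generator

The generator emulates the *structure* of the study — its sample sizes,
clocks, formats, and programmed effects — with known ground truth.

Behaviour: chamber visits are scheduled by a greedy deficit tracker
(next chamber = the one furthest below its target occupancy share),
dwell ≈ 15 s uniform-jittered; realised occupancy therefore converges to
the per-animal dwell-probability vector to within about one visit.
Within a visit the snout follows a persistent-velocity walk with
reflecting walls (session path length ~15–25 m). Per-animal dwell
vectors are Dirichlet-jittered (concentration 60) around group means
anchored to the reported group-level chamber times: sham
(0.407, 0.478, 0.115) over (social, center, nonsocial), injured
(0.167, 0.537, 0.296). Tracking likelihood is ~0.99 with ~1% low-confidence
frames placed away from chamber transitions, so likelihood filtering
cannot flip a label relative to ground truth.

Electrophysiology (per channel, 600 Hz): a dominant constant-envelope
low-frequency rhythm (instantaneous frequency wandering over 2–6 Hz,
amplitude 5), softly saturated pink (1/f) noise (σ = 1), a bundle-wide
common-mode pink component (σ = 1; exactly what per-bundle referencing
removes), and a constant-envelope gamma oscillator (25–60 Hz wander,
amplitude 1.5, ~10× the in-band 1/f floor). Injured animals have the
gamma amplitude multiplied by `power_deficit` = 0.75 in *both* chambers,
so band power scales by 0.5625 with no chamber dependence. Channel gains
carry mild per-animal lognormal jitter (5%).

Oscillators are phase-modulated constant-envelope waves rather than
filtered Gaussian noise, deliberately: real LFP rhythms have bounded
crest factors, and Gaussian composites would put every clean epoch past
the |z| > 5 artifact threshold (the trimmed SD of a Gaussian is ≈ 0.66 σ,
making the effective threshold ≈ 3.3 σ). The bounded design keeps
artifact-free data clear of the rejection rule, so injected faults — and
only injected faults — trigger it.

Coupling: the six hub regions (VMS, A24b, AcbSh, ALM, Prl, BLaAMG — one
per bundle, so no hub pair is masked) share a single latent gamma source,
mixed as `sqrt(1 − κ²)·private + κ·shared` with κ switched at chamber
boundaries: `coupling_social_sham` = 0.92 while a sham animal occupies
the social chamber, `coupling_baseline` = 0.84 otherwise. The mixing is
variance-preserving, so coupling changes coherence without touching
power. Analytically the band coherence between hubs is
≈ κ⁴ (r/(1+r))² with r the in-band oscillator-to-floor power ratio, and
per-bundle referencing (which keeps 3/4 of each channel) multiplies it
by (3/4)² — the default gains land the *pipeline* estimates near 0.33
(sham social) vs 0.23 (all other cells), a range typical of strongly
coupled pairs in such preparations. A pairwise-independent-source
alternative was rejected on arithmetic grounds: with p independent
sources per hub, pair coherence cannot exceed (1/p)², far below
realistic values.

What the generator does **not** emulate: volume conduction, electrode
drift and impedance changes, movement artifacts with realistic
morphology, behavioural state beyond chamber identity (no grooming /
sniffing structure), cross-frequency coupling, or non-stationary 1/f
slopes. Passing tests therefore validate the *pipeline's* correctness
and calibration on data with the assumed statistical structure — not the
biological claims on real recordings.

## Validation design and problem sizes

- Estimator exactness: Welch PSD and coherence against explicit
  window-loop oracles (60-s fixtures, < 1e-10 relative); the pooled
  multi-channel accumulator against scipy exactly.
- Calibration: self-coherence ≡ 1; independent-noise floors ≈ 1/K and
  decreasing with K; coherence strictly monotone over a programmed
  κ grid {0, 0.25, 0.5, 1} at fixed seeds.
- RSS: brute-force equivalence on 100 random masked matrices (1e-12),
  the c·√m closed form, and the 48/496 mask count.
- Statistics: hand-worked 2 × 2 fixture (F = 18, 6, 6) to 1e-8; a
  1000-replicate null simulation (n = 9 vs 12) keeping the interaction
  rejection rate in [3.7%, 6.5%]; Sidak/BH against closed-form and
  step-up definitions; GG ε at its lower bound for rank-one covariance.
- End-to-end recovery: 20 effect + 20 null replicate cohorts (9 vs 12
  animals). Replicates use 120-s sessions with the cross-spectral grid
  capped at 70 Hz and per-frequency masks off — sizes chosen so the full
  replicate study stays cheap while each chamber condition still pools
  hundreds of Welch windows per animal; pilot runs show the programmed
  effects are detected with large margins at this size. Detection
  criteria: gamma-power group effect in ≥ 16/20 with spurious power
  interaction in ≤ 3/20; exact recovery of the six hubs in ≥ 16/20; RSS
  group × chamber interaction in ≥ 16/20 effect cohorts and ≤ 3/20 null
  cohorts.
- `scripts/acceptance.py` runs one full cohort at 20-min sessions with
  the complete estimator settings and reports the headline quantities.

## Numerical choices and degenerate inputs

- The heavy pipeline path (generation, conditioning, cross-spectral
  pooling) runs in single precision; the public estimator functions are
  double precision and all exactness tests are double precision.
- Coherence values are clipped into [0, 1] against rounding; zero-power
  bins yield flagged NaNs rather than infinities.
- Trimmed z-scoring raises on constant central mass; channel rejection
  with zero spread keeps all channels; epoch rejection raises if nothing
  survives (a session with no usable data should fail loudly, not return
  empty tables).
- A chamber an animal never occupies long enough yields *missing*
  spectral conditions (None / NaN), never fabricated zeros, and missing
  cells propagate into the ANOVA as explicit errors listing the animals.
- Ties in region selection are broken alphabetically; the selected set
  is a deterministic function of the reference-condition RSS vector.

## Known limitations

- The mixed ANOVA covers one between and one within factor (the study's
  design); multi-way within structures beyond the GG-corrected one-way
  case are out of scope.
- Coherence pooled over overlapping windows has an estimator floor above
  1/K; conditions with very little chamber time are noticeably biased
  upward, which is inherent to the estimator, not corrected.
- The per-frequency significance masks are exploratory (reported raw and
  FDR-adjusted); no cluster-based correction is attempted.
- Real acquisition-system ingestion is limited to the documented HDF5
  layout; proprietary formats must be converted upstream.
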