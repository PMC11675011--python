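"""Welch PSD and magnitude-squared coherence on coupled synthetic LFP.

Builds a 60-s two-channel signal pair sharing a gamma-band latent source
and shows how band power and coherence report the programmed structure.
"""

import numpy as np

from socoh.simulate import CohortSpec, generate_lfp
from socoh.spectral import GAMMA, band_aggregate, ms_coherence, welch_psd

spec = CohortSpec(session_s=60.0, seed=4, coupling_social_sham=0.8,
                  coupling_baseline=0.8, coupled_regions=("VMS", "Prl"))
labels = np.full(int(spec.session_s * spec.fps), "social", dtype="<U9")
rec, truth = generate_lfp(spec, "sham01", labels)

i, j = spec.region_names.index("VMS"), spec.region_names.index("Prl")
k = spec.region_names.index("CA1")
sig = rec.signal.astype(float)

f, psd = welch_psd(sig[i], rec.fs_hz)
gamma_power = band_aggregate(f, psd, GAMMA)
print(f"VMS gamma-band (25-60 Hz) power: {gamma_power:.4f} (a.u./Hz)")

for name, other in (("Prl (coupled)", j), ("CA1 (uncoupled)", k)):
    fc, coh = ms_coherence(sig[i], sig[other], rec.fs_hz)
    print(f"VMS vs {name:<16} band coherence = "
          f"{band_aggregate(fc, coh, GAMMA):.3f}")

print()
print("The coupled pair shows strong gamma coherence (~kappa^4 of the")
print("shared-source mixing); the uncoupled pair sits near the 1/K")
print("estimator floor of the Welch coherence.")
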