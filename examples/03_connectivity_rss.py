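"""RSS weighted connectivity and data-driven region selection.

Processes one synthetic sham session, builds the 32 x 32 gamma-coherence
matrix per chamber, computes per-region RSS, and selects the top regions.
"""

import numpy as np

from socoh.connectivity import build_matrix, rss_by_region, select_top_regions
from socoh.pipeline import RunConfig, run_session
from socoh.simulate import CohortSpec, generate_session

spec = CohortSpec(session_s=300.0, seed=2)
session = generate_session(spec, "sham01", 0)
cfg = RunConfig(compute_per_frequency=False)
res = run_session(cfg, session["track"], session["rec"], "sham01", "sham")

mat = build_matrix(res.band_coherence["social"], res.bundle_id,
                   res.kept_channels, res.region_names)
vals = rss_by_region(mat)
top = select_top_regions(vals, res.region_names, k=6)

order = np.argsort(vals)[::-1]
print("per-region RSS of gamma coherence (social chamber, top 10):")
for idx in order[:10]:
    marker = "*" if res.region_names[idx] in top else " "
    print(f" {marker} {res.region_names[idx]:>8}  RSS = {vals[idx]:.3f}")
print()
print("selected regions:", ", ".join(top))
print("Starred regions are the selection; with the default generator the")
print("six programmed hub regions carry the extra sham-social coupling and")
print("rise to the top of the RSS ranking.")
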