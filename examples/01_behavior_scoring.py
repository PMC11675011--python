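"""Score three-chamber sociability from a synthetic pose track.

Generates one 10-min session with a programmed dwell-probability vector,
scores it, and prints occupancy, entries, preference and locomotion.
"""

from socoh.behavior import ChamberGeometry, summarize_track
from socoh.simulate import CohortSpec, generate_track

spec = CohortSpec(session_s=600.0, seed=1)
track, truth = generate_track(spec, "sham01", pref=(0.45, 0.35, 0.20))

summary = summarize_track(track, ChamberGeometry(), fps=spec.fps,
                          animal_id="sham01")

print("programmed dwell fractions (social, center, nonsocial):", truth["pref"])
for ch in ("social", "center", "nonsocial"):
    print(f"  {ch:>9}: {summary.time_s[ch]:6.1f} s "
          f"({summary.entries[ch]} entries)")
print(f"preference (S-N)/(S+N) = {summary.preference_diff:+.3f}, "
      f"S/(S+N) = {summary.preference_ratio:.3f}")
print(f"distance travelled     = {summary.distance_cm:.0f} cm")
print()
print("The occupancy times recover the programmed probabilities to within")
print("about one chamber visit; the two preference conventions obey")
print("ratio = (diff + 1) / 2 exactly.")
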