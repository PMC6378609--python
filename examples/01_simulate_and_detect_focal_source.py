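"""Simulate a focal atrial tachycardia and detect its source as an ROI site.

Builds a 64-electrode basket recording (30 s, 1 kHz) of a regular focal
tachycardia, runs the full pipeline (2-240 Hz + 60 Hz notch filtering, LAT
annotation, quality gating, ROI detection) and compares the detected site
with the simulator's ground truth.
"""

import numpy as np

from roifinder import correlate_sites, run_roi_pipeline, simulate_recording

res = simulate_recording("focal_at", seed=1, cycle_length_ms=250.0)
out = run_roi_pipeline(res.recording)

truth = np.array(res.truth.drivers[0]["xyz"])
print(f"channels passing quality gate: "
      f"{sum(a.passed for a in out.annotations.values())}/{len(out.annotations)}")
print(f"ROI sites detected: {len(out.sites)}")
for s in out.sites:
    ok, d = correlate_sites(s.position, truth)
    print(f"  electrode {s.electrode_id}: longest run {s.max_run} consecutive focal "
          f"beats, {d:.1f} mm from the true source (correlates: {ok})")
# One site with a run spanning the whole recording is expected: every beat of a
# regular focal tachycardia is QS at the source and leads its neighbors.
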