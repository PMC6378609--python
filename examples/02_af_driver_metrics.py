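"""Characterize an intermittent AF driver: consistency, stability, recurrence.

Simulates three 30-s basket maps of fibrillation with a focal driver firing
~11 times per map in runs of ~3 beats, detects ROI sites on each map, and
summarizes the driver across maps.
"""

import numpy as np

from roifinder import driver_metrics, run_roi_pipeline, simulate_recording
from roifinder.simulate import AFDriverProfile

profile = AFDriverProfile(recurrence_per_30s=11.0, run_length_mean=3.0)
per_map, truth = [], None
for seed in (11, 12, 13):
    res = simulate_recording("af_with_driver", seed=seed, profile=profile,
                             source_electrode="D4")
    truth = np.array(res.truth.drivers[0]["xyz"])
    sites = run_roi_pipeline(res.recording).sites
    per_map.append(sites)
    print(f"map seed {seed}: true runs {res.truth.drivers[0]['runs']}, "
          f"{len(sites)} site(s) detected")

m = driver_metrics(per_map, truth)
print(f"consistency        {m.consistency:.2f}  (fraction of maps showing the driver)")
print(f"temporal stability {m.temporal_stability:.2f}  (mean consecutive repetitions)")
print(f"recurrence rate    {m.recurrence_rate:.1f}  (occurrences per 30-s map)")
# Values near the configured profile (runs of ~3, ~11 occurrences) indicate the
# detector recovers the driver's firing statistics, not just its location.
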