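"""Versioned cohort fixtures reproducing the validation study's counts.

The clinical study behind these numbers deposited no recordings, so its
accuracy statistics can only be reproduced arithmetically from the printed
per-driver counts. This module encodes those counts as small CSV fixtures
(shipped under ``roifinder/data/``, regenerated programmatically here):

* a 35-driver cohort in 28 patients — which drivers were detected on global
  basket maps, which belonged to the 23 sequentially mapped patients (30
  drivers), which of those were identified on sequential maps (22), the
  ablation response (20 terminations / 15 cycle-length slowings) and whether
  the driver was seen pre-PVI;
* a 139-map table with the per-map detection flag (121 maps with a site).

Assignments not determined by the published marginals (e.g. *which* five
drivers were missed on basket maps) are fixed deterministically; every
statistic computed from the fixtures depends only on the marginals.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import binomial_ci_exact, fisher_exact, percent

__all__ = [
    "build_driver_cohort",
    "build_global_map_table",
    "driver_cohort",
    "global_map_table",
    "summary_statistics",
    "write_fixture_csvs",
    "REFERENCE_SUMMARY",
]

#: published summary values the fixtures must reproduce (pass/fail table)
REFERENCE_SUMMARY = {
    "basket_detection_pct": 86,  # 30 of 35 drivers on global basket maps
    "sequential_detection_pct": 73,  # 22 of 30 drivers on sequential maps
    "maps_with_roi_pct": 87,  # 121 of 139 global maps
    "sequential_ci_pct": (54, 88),  # exact 95% CI of 22/30, percent-rounded
    "termination_fisher_p_max": 0.001,  # 17/22 vs 0/8 termination split
}


def build_driver_cohort() -> pd.DataFrame:
    """Construct the 35-driver cohort table from the published marginals."""
    rows = []
    seq_identified = set(range(1, 23))  # 22 drivers found on sequential maps
    non_cohort = set(range(24, 29))  # drivers of the 5 patients never mapped sequentially
    termination = set(range(1, 18)) | {24, 25, 26}  # 17 cohort + 3 others = 20
    basket_missed = {23, 27, 28, 29, 30}  # 5 of 35 missed on basket maps
    pre_pvi = set(range(1, 15)) | {24, 25} | set(range(18, 23))  # 16 term + 5 slow

    for d in range(1, 36):
        patient = d if d <= 28 else d - 28  # second drivers for patients 1..7
        in_cohort = d not in non_cohort
        rows.append(
            {
                "driver_id": d,
                "patient_id": patient,
                "response": "termination" if d in termination else "cl_slowing",
                "basket_roi": d not in basket_missed,
                "sequential_cohort": in_cohort,
                "sequential_roi": in_cohort and d in seq_identified,
                "pre_pvi_seen": d in pre_pvi,
            }
        )
    return pd.DataFrame(rows)


def build_global_map_table() -> pd.DataFrame:
    """139 global activation maps; a detection flag on 121 of them."""
    return pd.DataFrame(
        {"map_id": range(1, 140), "roi_detected": [i <= 121 for i in range(1, 140)]}
    )


def _data_path(name: str):
    return resources.files("roifinder").joinpath("data", name)


def driver_cohort() -> pd.DataFrame:
    """Load the shipped driver-cohort fixture CSV."""
    with resources.as_file(_data_path("driver_cohort.csv")) as p:
        return pd.read_csv(p)


def global_map_table() -> pd.DataFrame:
    """Load the shipped global-map fixture CSV."""
    with resources.as_file(_data_path("global_maps.csv")) as p:
        return pd.read_csv(p)


def write_fixture_csvs(out_dir: str | Path) -> list[Path]:
    """Regenerate the fixture CSVs (the generator behind the shipped data)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("driver_cohort.csv", build_driver_cohort()),
        ("global_maps.csv", build_global_map_table()),
    ):
        p = out_dir / name
        df.to_csv(p, index=False, lineterminator="\n")
        paths.append(p)
    return paths


def summary_statistics(
    cohort: pd.DataFrame | None = None, maps: pd.DataFrame | None = None
) -> dict:
    """Recompute the headline accuracy statistics from the fixtures."""
    cohort = build_driver_cohort() if cohort is None else cohort
    maps = build_global_map_table() if maps is None else maps

    n_drivers = len(cohort)
    basket_k = int(cohort["basket_roi"].sum())
    seq = cohort[cohort["sequential_cohort"]]
    seq_k, seq_n = int(seq["sequential_roi"].sum()), len(seq)
    maps_k, maps_n = int(maps["roi_detected"].sum()), len(maps)

    lo, hi = binomial_ci_exact(seq_k, seq_n)
    ident = seq[seq["sequential_roi"]]
    missed = seq[~seq["sequential_roi"]]
    a = int((ident["response"] == "termination").sum())
    b = len(ident) - a
    c = int((missed["response"] == "termination").sum())
    d = len(missed) - c
    return {
        "basket_detection": (basket_k, n_drivers),
        "basket_detection_pct": percent(basket_k / n_drivers),
        "sequential_detection": (seq_k, seq_n),
        "sequential_detection_pct": percent(seq_k / seq_n),
        "maps_with_roi": (maps_k, maps_n),
        "maps_with_roi_pct": percent(maps_k / maps_n),
        "sequential_ci": (lo, hi),
        "sequential_ci_pct": (percent(lo), percent(hi)),
        "sequential_printed": f"{percent(seq_k / seq_n)} ({percent(lo)}-{percent(hi)})",
        "termination_table": ((a, b), (c, d)),
        "termination_fisher_p": fisher_exact(a, b, c, d),
    }


def summary_pass_table(stats: dict | None = None) -> list[tuple[str, object, object, bool]]:
    """(name, computed, expected, pass) rows comparing to published values."""
    s = stats or summary_statistics()
    ref = REFERENCE_SUMMARY
    rows = [
        ("basket detection %", s["basket_detection_pct"], ref["basket_detection_pct"],
         s["basket_detection_pct"] == ref["basket_detection_pct"]),
        ("sequential detection %", s["sequential_detection_pct"], ref["sequential_detection_pct"],
         s["sequential_detection_pct"] == ref["sequential_detection_pct"]),
        ("maps with site %", s["maps_with_roi_pct"], ref["maps_with_roi_pct"],
         s["maps_with_roi_pct"] == ref["maps_with_roi_pct"]),
        ("sequential 95% CI %", s["sequential_ci_pct"], ref["sequential_ci_pct"],
         tuple(s["sequential_ci_pct"]) == ref["sequential_ci_pct"]),
        ("termination Fisher p", round(s["termination_fisher_p"], 6),
         f"<= {ref['termination_fisher_p_max']}",
         s["termination_fisher_p"] <= ref["termination_fisher_p_max"]),
    ]
    return rows
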