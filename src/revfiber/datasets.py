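"""Reference summary data from a published 40-mouse mdx cohort.

Group-level means and standard deviations of revertant-fiber density
(RF/mm^2, averaged over 10-12 sections per muscle and 10 mice per group)
for 11 muscles across four age groups (2, 6, 12, >18 months).  Used as
calibration targets for the synthetic-cohort simulator and as inputs to
worked-example computations.
"""

from __future__ import annotations

import pandas as pd

from .core import AGE_GROUPS, MUSCLES

#: Group-mean RF densities (RF/mm^2) by muscle; one value per age group 1-4.
REFERENCE_DENSITY_MEAN: dict[str, tuple[float, float, float, float]] = {
    "TA": (1.96, 3.39, 4.72, 7.17),
    "EDL": (2.58, 3.35, 4.6, 6.06),
    "SOL": (1.8, 4.13, 5.03, 6.61),
    "GC": (1.13, 3.12, 4.45, 5.63),
    "PL": (1.56, 3.57, 5.6, 6.22),
    "Q": (1.09, 2.61, 3.77, 6.03),
    "TRIC": (1.09, 2.59, 3.72, 6.19),
    "PT": (1.48, 2.02, 2.07, 3.91),
    "D": (0.91, 1.37, 2.9, 4.36),
    "IC": (0.98, 1.54, 2.96, 7.39),
    "H": (0.28, 0.23, 0.47, 1.19),
}

#: Group standard deviations matching :data:`REFERENCE_DENSITY_MEAN`.
REFERENCE_DENSITY_SD: dict[str, tuple[float, float, float, float]] = {
    "TA": (2.04, 1.98, 2.17, 3.45),
    "EDL": (3.49, 2.75, 3.01, 5.38),
    "SOL": (2.28, 3.25, 5.78, 7.35),
    "GC": (0.96, 1.89, 2.28, 3.28),
    "PL": (1.8, 3.74, 4.14, 4.43),
    "Q": (0.54, 1.95, 2.02, 3.82),
    "TRIC": (1.75, 1.35, 2.23, 4.61),
    "PT": (2.09, 2.36, 1.71, 2.07),
    "D": (0.89, 2.15, 2.28, 3.86),
    "IC": (0.84, 1.26, 3.71, 6.22),
    "H": (0.5, 0.27, 0.51, 0.66),
}

#: Study-wide grand densities (RF/mm^2) printed for selected muscles,
#: rounded to one decimal.
REFERENCE_GRAND_DENSITY: dict[str, float] = {
    "D": 2.4,
    "PT": 2.5,
    "TA": 4.4,
    "SOL": 4.4,
    "H": 0.6,
}

#: Largest observed cluster size (fibers per cluster) by muscle and group.
REFERENCE_MAX_CLUSTER: dict[str, tuple[int, int, int, int]] = {
    "TA": (12, 15, 20, 24),
    "EDL": (8, 7, 8, 11),
    "SOL": (4, 20, 14, 29),
    "PL": (3, 9, 13, 22),
    "GC": (11, 21, 35, 26),
    "Q": (17, 36, 23, 30),
    "TRIC": (17, 39, 27, 60),
    "PT": (13, 23, 17, 17),
    "D": (8, 21, 21, 19),
    "IC": (15, 10, 22, 58),
    "H": (10, 8, 7, 11),
}


def reference_density_frame() -> pd.DataFrame:
    """Long-format frame of the reference densities: muscle, age_group, mean, sd."""
    rows = []
    for muscle in MUSCLES:
        for group, (mean, sd) in zip(
            AGE_GROUPS, zip(REFERENCE_DENSITY_MEAN[muscle], REFERENCE_DENSITY_SD[muscle])
        ):
            rows.append({"muscle": muscle, "age_group": group, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)
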