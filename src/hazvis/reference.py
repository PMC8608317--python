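"""Bundled reference data from the published validation study of this model.

Two small tables are shipped as code so downstream analyses (for example
the slope-versus-vision meta-regression) can run without external files:

* ten low-vision observers' clinical measures — logMAR acuity and
  Pelli-Robson contrast sensitivity — together with the slope, deviances
  and reduced deviance ratio of each observer's individual accuracy-vs-HVS
  logistic fit;
* the group-level summary parameters used as simulation defaults (mean
  acuity/CS of the moderate- and severe-blur groups, and the group
  logistic slopes).
"""

from __future__ import annotations

import pandas as pd

#: Per-observer clinical measures and individual logistic-fit statistics.
_LOW_VISION_ROWS = [
    # subject, acuity (logMAR), cs (Pelli-Robson), slope, null dev, resid dev
    ("LV1", 0.80, 1.65, 6.45, 70.81353, 52.82475),
    ("LV2", 1.28, 0.60, 1.57, 265.9621, 255.7521),
    ("LV3", 1.14, 0.30, 3.23, 337.3001, 276.5907),
    ("LV4", 1.16, 1.05, 5.60, 265.9621, 178.1817),
    ("LV5", 1.50, 0.30, 5.56, 338.7891, 267.4427),
    ("LV6", 1.36, 0.80, 3.79, 326.7091, 266.4454),
    ("LV7", 1.44, 0.20, 2.27, 346.5096, 327.4960),
    ("LV8", 1.54, 0.65, 3.04, 344.2660, 302.3751),
    ("LV9", 1.66, 0.57, 2.53, 324.3380, 302.1003),
    ("LV10", 1.02, 1.55, 11.03, 124.2173, 72.18844),
]

#: Group-level simulation defaults: mean clinical measures of the two
#: artificial-blur groups and their aggregated logistic slopes.
GROUP_PARAMS = {
    "moderate": {"acuity": 1.20, "acuity_sd": 0.085, "cs": 0.68, "cs_sd": 0.10, "slope": 3.02},
    "severe": {"acuity": 1.62, "acuity_sd": 0.028, "cs": 0.60, "cs_sd": 0.019, "slope": 1.54},
    "low-vision": {"acuity": 1.29, "acuity_sd": 0.27, "cs": 0.77, "cs_sd": 0.51, "slope": 3.45},
}


def low_vision_observers() -> pd.DataFrame:
    """The ten-observer reference table.

    Columns: ``subject``, ``acuity`` (logMAR), ``cs`` (Pelli-Robson),
    ``slope`` (individual logistic slope A), ``null_deviance``,
    ``residual_deviance``, ``reduced_deviance_ratio``.
    """
    df = pd.DataFrame(
        _LOW_VISION_ROWS,
        columns=["subject", "acuity", "cs", "slope", "null_deviance", "residual_deviance"],
    )
    df["reduced_deviance_ratio"] = (
        df["null_deviance"] - df["residual_deviance"]
    ) / df["null_deviance"]
    return df
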