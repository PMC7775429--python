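"""Daily snow-index processing: exclusion, gap filling, FSC and SCD.

Takes the synthetic world's gappy daily NDSI cube (0-100 scale) through the
standard recipe: drop pixels with more than 60% invalid days, interpolate the
remaining gaps linearly in time, convert to fractional snow cover with
FSC = -0.01 + 1.45 * NDSI truncated to [0, 100] %, and count monthly
snow-cover duration as days with NDSI above 20.
"""

import numpy as np

from gridveg import (GridSpec, SnowConfig, WorldConfig, exclude_high_missing,
                     gap_fill_linear, make_world, snow_monthly_metrics)

world = make_world(WorldConfig(seed=2, ndvi_grid=GridSpec(30, 30, 1.0)))
daily = world.snow_daily
cfg = SnowConfig()

retained, excluded_frac = exclude_high_missing(daily, cfg)
print(f"excluded pixels (> {cfg.missing_exclusion_fraction:.0%} invalid days):"
      f" {excluded_frac:.1%} of the area")

filled = gap_fill_linear(retained)
retained_px = retained.valid_mask.any(axis=0)
print("retained pixels with gaps after linear fill:",
      int((~filled.valid_mask[:, retained_px]).any(axis=0).sum()))

metrics = snow_monthly_metrics(daily, cfg)
jan = metrics["scd"].time.index_of(2001, 1)
jul = metrics["scd"].time.index_of(2001, 7)
print("mean SCD Jan 2001:", round(np.nanmean(metrics["scd"].values[jan]), 1),
      "days | Jul 2001:", round(np.nanmean(metrics["scd"].values[jul]), 1), "days")
print("mean FSC Jan 2001:", round(np.nanmean(metrics["fsc"].values[jan]), 1), "%")
# Winter months carry most of the snow signal; summer SCD is near zero.
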