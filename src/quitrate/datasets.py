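"""Reference data shipped with the package.

``us_cessation_estimates_2009_2017`` is a previously published table of
Kalman-filter estimates of US annual net smoking cessation rates by age
group (25-44, 45-64, 65+), with posterior SDs and the smoker-count-weighted
average, for the years 2009-2017.  It exercises the summary and reporting
layer (period means, percent changes, relative rates) without requiring the
restricted survey inputs behind the original analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import FilterTrace

GROUP_LABELS = ("25-44", "45-64", "65+")

# year, CR 25-44, SD, CR 45-64, SD, CR 65+, SD, CR weighted, SD (percent)
_TABLE = [
    (2009, 4.98, 0.80, 2.46, 0.80, 4.86, 0.84, 3.89, 0.52),
    (2010, 4.76, 0.77, 2.07, 0.79, 5.50, 0.84, 3.66, 0.51),
    (2011, 4.46, 0.76, 2.44, 0.77, 5.63, 0.85, 3.69, 0.50),
    (2012, 4.44, 0.75, 2.40, 0.76, 5.69, 0.86, 3.67, 0.48),
    (2013, 4.13, 0.74, 2.95, 0.75, 5.81, 0.87, 3.79, 0.48),
    (2014, 4.44, 0.73, 3.69, 0.74, 5.87, 0.88, 4.27, 0.47),
    (2015, 4.46, 0.73, 3.73, 0.73, 5.68, 0.89, 4.27, 0.47),
    (2016, 4.69, 0.73, 4.08, 0.73, 5.62, 0.90, 4.53, 0.47),
    (2017, 4.50, 0.73, 4.17, 0.73, 5.49, 0.91, 4.48, 0.47),
]


def us_cessation_estimates_2009_2017() -> pd.DataFrame:
    """The reference estimates as a tidy table (rates in percent)."""
    cols = ["year"]
    for g in GROUP_LABELS + ("weighted",):
        cols += [f"cr_{g}", f"sd_{g}"]
    return pd.DataFrame(_TABLE, columns=cols)


def reference_trace() -> FilterTrace:
    """The reference estimates packed as a trace (proportions), suitable for
    ``summarize_trace``, ``relative_rates`` and report rendering."""
    arr = np.asarray([row[1:] for row in _TABLE]) / 100.0
    years = [row[0] for row in _TABLE]
    return FilterTrace.from_table(
        years=years,
        group_labels=GROUP_LABELS,
        mean=arr[:, [0, 2, 4]],
        sd=arr[:, [1, 3, 5]],
        weighted_mean=arr[:, 6],
        weighted_sd=arr[:, 7],
    )
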