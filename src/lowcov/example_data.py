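"""Bundled example calibration data for the hop-level estimator.

The tables below come from a published dual-sequencing experiment on 26
pigs: every animal was sequenced once multiplexed at ~2x coverage and once
unmultiplexed at ~30x.  Presence/absence genotype calls from independent
down-samples of the hop-free 30x data, with index hopping injected in
silico at 0, 0.1, 0.5, 1, 2 and 5%, give the calibration grid of
called-vs-true concordance percentages; the "observed" row holds the same
variables measured on the real multiplexed 2x data, whose unknown hop
level is the quantity being estimated.

Variables are confusion percentages keyed ``"called|true"`` (column
percents of the 3x3 called-vs-true genotype table).
"""

from __future__ import annotations

import pandas as pd

#: Simulated hop levels of the calibration grid, in percent.
CALIBRATION_LEVELS = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0)

_VARIABLES = ("0|0", "1|0", "2|0", "0|1", "1|1", "2|1", "0|2", "1|2", "2|2")

_CALIBRATION_ROWS = {
    0.0: (99.62, 0.35, 0.03, 23.57, 52.98, 23.45, 0.04, 0.47, 99.48),
    0.1: (99.53, 0.44, 0.03, 23.59, 53.52, 22.89, 0.08, 0.52, 99.40),
    0.5: (99.28, 0.66, 0.06, 23.91, 53.22, 22.87, 0.10, 0.92, 98.98),
    1.0: (98.99, 0.90, 0.10, 23.70, 53.23, 23.07, 0.14, 1.33, 98.53),
    2.0: (98.20, 1.64, 0.16, 23.73, 52.90, 23.37, 0.23, 2.16, 97.62),
    5.0: (96.34, 3.29, 0.37, 23.56, 53.37, 23.07, 0.59, 4.75, 94.66),
}

_OBSERVED_ROW = (98.45, 1.42, 0.13, 24.15, 52.62, 23.23, 0.18, 1.71, 98.10)


def example_calibration() -> pd.DataFrame:
    """Calibration grid as a long table (level_percent, variable, value)."""
    rows = [
        (level, var, value)
        for level, values in _CALIBRATION_ROWS.items()
        for var, value in zip(_VARIABLES, values)
    ]
    return pd.DataFrame(rows, columns=["level_percent", "variable", "value"])


def example_observed() -> dict[str, float]:
    """Observed multiplexed-2x concordance variables, keyed ``"called|true"``."""
    return dict(zip(_VARIABLES, _OBSERVED_ROW))
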