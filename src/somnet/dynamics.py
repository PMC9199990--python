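"""Dynamic functional connectivity at sleep-stage transitions.

At every stage-run onset the first artifact-free 30-s epoch is split into
three 10-s segments; each segment gets its own WPLI network (8 sliding
windows) and global efficiency.  Aggregating the per-onset GE values by
(group, band, stage, segment position) gives a three-point mean and
standard-deviation trace across the transition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import global_efficiency, proportional_threshold
from .wavelet import connectivity_from_phase

__all__ = ["segment_ge", "transition_traces"]


def segment_ge(phase_slices, fs: float, density: float = 0.30,
               window_s: float = 3.0, hop_s: float = 1.0,
               aggregation: str = "pooled"):
    """GE of each (phase, valid) segment slice: WPLI -> threshold -> GE."""
    out = []
    for phase, valid in phase_slices:
        mat = connectivity_from_phase(phase, valid, fs, window_s=window_s,
                                      hop_s=hop_s, aggregation=aggregation)
        out.append(global_efficiency(proportional_threshold(mat, density)))
    return out


def transition_traces(onset_ge: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD GE trace per (group, band, stage, position).

    ``onset_ge`` is long-format with one row per (subject, band, stage
    onset, position 1..3) and a ``ge`` column.  The SD is the sample SD
    (n-1 denominator) over contributing onsets and is reported as missing
    (NaN) when only one onset contributes.
    """
    required = {"group", "band", "stage", "position", "ge"}
    missing = required - set(onset_ge.columns)
    if missing:
        raise ValueError(f"onset table lacks columns {sorted(missing)}")
    grouped = onset_ge.groupby(["group", "band", "stage", "position"],
                               sort=True)["ge"]
    out = grouped.agg(mean_ge="mean",
                      sd_ge=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                      n_onsets="count").reset_index()
    return out
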