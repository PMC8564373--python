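"""End-to-end color calling: volume + traces -> binary codes per cell.

Chains the stages of :mod:`bitbow.calling` the way they run on real data:
unmix the whole volume once, median-filter it once, then per traced cell
sample, smooth along the trace, sum-normalize, and threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import (
    CellColor,
    MixingMatrix,
    TraceIntensitySeries,
    background_floor,
    call_cells,
    median_filter_volume,
    normalize_channels,
    sample_volume,
    smooth,
    unmix_volume,
)
from .io import SWC_SOMA_TYPE

__all__ = ["call_traced_cells", "trace_series", "split_soma_neurite"]


def trace_series(
    trace: pd.DataFrame,
    volume: np.ndarray,
    cell_id=None,
    label: str = "neurite",
) -> TraceIntensitySeries:
    """Build an intensity series by sampling a channel-first volume at the
    trace's (x, y, z) node coordinates."""
    coords = trace[["x", "y", "z"]].to_numpy(float)
    ids = trace["node_id"].to_numpy(int)
    return TraceIntensitySeries(
        node_ids=ids,
        coords=coords,
        intensities=sample_volume(volume, coords, ids),
        label=label,
        cell_id=cell_id,
    )


def split_soma_neurite(trace: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an SWC trace into soma (type 1) and neurite nodes."""
    is_soma = trace["type"] == SWC_SOMA_TYPE
    return trace[is_soma], trace[~is_soma]


def call_traced_cells(
    volume: np.ndarray,
    mixing: MixingMatrix,
    traces: list[pd.DataFrame],
    thresholds: float | np.ndarray | str = "auto",
    window: int = 10,
    floor: float | None = None,
) -> list[CellColor]:
    """Run unmix -> smooth -> normalize -> call over every traced cell.

    ``floor`` is the background sum-intensity cutoff applied after
    smoothing; by default 1% of the unmixed volume's 99th-percentile
    summed intensity.  Returns one :class:`CellColor` per trace, in order.
    """
    unmixed = unmix_volume(volume, mixing)
    filtered = median_filter_volume(unmixed)
    if floor is None:
        floor = background_floor(unmixed)
    cell_pixels = []
    for i, trace in enumerate(traces):
        series = trace_series(trace, filtered, cell_id=i)
        smoothed = smooth(series, volume=filtered, window=window, prefiltered=True)
        normed, bg = normalize_channels(smoothed.intensities, floor=floor)
        cell_pixels.append(normed[~bg])
    return call_cells(cell_pixels, thresholds=thresholds)
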