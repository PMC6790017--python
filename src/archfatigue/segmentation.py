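"""Cycle segmentation of load/displacement traces.

A loading cycle is a maximal run of samples with axial load at or above the
weight-bearing threshold (50 N by default), paired with the non-weight-bearing
trough that follows it.  Per cycle, the navicular height is read at the sample
of maximum load within the run (weight-bearing height) and at the sample of
minimum load within the following trough (non-weight-bearing height).  Ties in
the load are broken toward the earliest sample; a final run with no following
trough is dropped.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .synthgen import SpecimenTrace

__all__ = [
    "segment_cycles",
    "checkpoint_series",
    "default_checkpoints",
    "CYCLE_COLUMNS",
    "DEFAULT_WB_THRESHOLD_N",
]

log = logging.getLogger(__name__)

CYCLE_COLUMNS = (
    "cycle",
    "h_wb_mm",
    "h_nwb_mm",
    "peak_load_N",
    "min_load_N",
    "wb_duration_s",
)

#: weight-bearing phase definition: axial load of at least 50 N
DEFAULT_WB_THRESHOLD_N = 50.0


def default_checkpoints(total_cycles: int = 10_000, step: int = 1000) -> tuple[int, ...]:
    """Checkpoint grid {1, step, 2*step, ..., total_cycles}."""
    return (1, *range(step, total_cycles + 1, step))


def segment_cycles(
    trace: SpecimenTrace,
    wb_threshold: float = DEFAULT_WB_THRESHOLD_N,
) -> pd.DataFrame:
    """Segment a specimen trace into per-cycle height/load records.

    Returns a DataFrame with one row per completed cycle (columns
    :data:`CYCLE_COLUMNS`, cycle indices 1-based and consecutive).  Cycles
    where the non-weight-bearing height falls below the weight-bearing height
    (physically implausible negative deformation) are kept but counted with a
    warning downstream.

    Raises
    ------
    ValueError
        If the trace is empty or its timestamps are not uniform.
    """
    data = trace.data
    if len(data) == 0:
        raise ValueError(f"{trace.specimen_id}: empty trace")
    t = data["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * max(dt.max(), 1e-12):
            raise ValueError(f"{trace.specimen_id}: non-uniform timestamps; resample first")
    load = data["load_N"].to_numpy(dtype=float)
    height = data["navicular_y_mm"].to_numpy(dtype=float)
    rate = trace.sampling_rate_hz

    above = load >= wb_threshold
    if not above.any():
        warnings.warn(
            f"{trace.specimen_id}: load never reaches the {wb_threshold} N "
            "weight-bearing threshold; no cycles segmented",
            stacklevel=2,
        )
        return pd.DataFrame({c: [] for c in CYCLE_COLUMNS})

    # run starts/ends of the weight-bearing excursions (end exclusive)
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]

    records = []
    dropped_samples = 0
    for i, (s, e) in enumerate(zip(starts, ends)):
        trough_start = e
        trough_end = starts[i + 1] if i + 1 < len(starts) else len(load)
        if trough_start >= trough_end:
            # final excursion without a following non-weight-bearing trough
            dropped_samples += e - s
            continue
        k_wb = s + int(np.argmax(load[s:e]))
        k_nwb = trough_start + int(np.argmin(load[trough_start:trough_end]))
        records.append(
            (
                len(records) + 1,
                height[k_wb],
                height[k_nwb],
                load[k_wb],
                load[k_nwb],
                (e - s) / rate,
            )
        )
    if dropped_samples:
        log.info(
            "%s: dropped %d trailing samples from an incomplete final cycle",
            trace.specimen_id,
            dropped_samples,
        )
    df = pd.DataFrame(records, columns=list(CYCLE_COLUMNS))
    df["cycle"] = df["cycle"].astype(int)
    n_implausible = int((df["h_nwb_mm"] < df["h_wb_mm"]).sum())
    if n_implausible:
        warnings.warn(
            f"{trace.specimen_id}: {n_implausible} cycles with non-weight-bearing height "
            "below weight-bearing height (negative deformation); kept as measured",
            stacklevel=2,
        )
    return df


def checkpoint_series(records: pd.DataFrame, checkpoints) -> pd.DataFrame:
    """Rows of a per-cycle table at the requested cycle checkpoints.

    Raises
    ------
    ValueError
        Naming the first checkpoint that lies beyond the observed cycles.
    """
    checkpoints = [int(c) for c in checkpoints]
    observed = set(records["cycle"].astype(int))
    for cp in checkpoints:
        if cp not in observed:
            raise ValueError(
                f"checkpoint {cp} is outside the observed cycle range "
                f"(1..{max(observed) if observed else 0})"
            )
    out = records.set_index("cycle").loc[checkpoints].reset_index()
    return out
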