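"""Arch metrics: bony arch index, flexibility, energy absorption, deltas.

Definitions (navicular height h in mm, foot length l in mm, load in N):

* ``BAI = h / l`` — unitless; under load, BAI < 0.21 is a low arch and
  0.21-0.27 a normal arch (the 0.21 boundary belongs to "normal").
* deformation ``d = h_nwb - h_wb`` (mm) between the unloaded and loaded
  states of a cycle.
* flexibility ``= 1000 d / load`` (μm/N) — the inverse of arch stiffness;
  the load is the cycle's peak load, the load that produced the deformation.
* energy absorption ``E = (d / 1000) * load / 2`` (J) — elastic strain
  energy of a linear spring compressed by d under the peak load.

These definitions tie flexibility and energy together as
``E = flexibility * load^2 / 2e6``, an identity checked in the test suite on
every record.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LOW_ARCH_THRESHOLD",
    "HIGH_ARCH_THRESHOLD",
    "compute_bai",
    "compute_flexibility",
    "compute_energy",
    "classify_arch",
    "cycle_metrics",
    "compute_deltas",
    "METRIC_COLUMNS",
]

LOW_ARCH_THRESHOLD = 0.21
HIGH_ARCH_THRESHOLD = 0.27

METRIC_COLUMNS = (
    "cycle",
    "bai_wb",
    "bai_nwb",
    "deformation_mm",
    "flexibility_um_per_N",
    "energy_J",
    "arch_class",
)


def compute_bai(h, l):
    """Bony arch index h / l (heights and lengths in the same unit)."""
    h = np.asarray(h, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("foot length must be positive")
    if np.any(h < 0):
        raise ValueError("navicular height must be non-negative")
    out = h / l
    return float(out) if out.ndim == 0 else out


def compute_flexibility(h_nwb, h_wb, load):
    """Arch flexibility in μm/N: 1000 (h_nwb - h_wb) / load, heights in mm."""
    load = np.asarray(load, dtype=float)
    if np.any(load <= 0):
        raise ValueError("load must be positive")
    out = 1000.0 * (np.asarray(h_nwb, dtype=float) - np.asarray(h_wb, dtype=float)) / load
    return float(out) if out.ndim == 0 else out


def compute_energy(deformation_mm, load):
    """Energy absorption in J: (deformation/1000) * load / 2."""
    load = np.asarray(load, dtype=float)
    if np.any(load <= 0):
        raise ValueError("load must be positive")
    d = np.asarray(deformation_mm, dtype=float)
    if np.any(d < 0):
        warnings.warn("negative deformation encountered; energy kept signed", stacklevel=2)
    out = d / 1000.0 * load / 2.0
    return float(out) if out.ndim == 0 else out


def classify_arch(bai_wb):
    """Arch class from the weight-bearing BAI: low / normal / high."""
    b = np.asarray(bai_wb, dtype=float)
    out = np.where(b < LOW_ARCH_THRESHOLD, "low", np.where(b <= HIGH_ARCH_THRESHOLD, "normal", "high"))
    return str(out) if out.ndim == 0 else out


def cycle_metrics(cycles: pd.DataFrame, foot_length_mm: float) -> pd.DataFrame:
    """Per-cycle arch metrics from a segmented cycle table.

    ``cycles`` must carry the columns written by
    :func:`archfatigue.segmentation.segment_cycles`.
    """
    if foot_length_mm <= 0 or not np.isfinite(foot_length_mm):
        raise ValueError(f"foot length must be positive and finite, got {foot_length_mm}")
    h_wb = cycles["h_wb_mm"].to_numpy(dtype=float)
    h_nwb = cycles["h_nwb_mm"].to_numpy(dtype=float)
    load = cycles["peak_load_N"].to_numpy(dtype=float)
    deform = h_nwb - h_wb
    n_neg = int((deform < 0).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} cycles have negative deformation (h_nwb < h_wb); retained as measured",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative deformation already reported once
        energy = compute_energy(deform, load)
    return pd.DataFrame(
        {
            "cycle": cycles["cycle"].astype(int),
            "bai_wb": compute_bai(h_wb, foot_length_mm),
            "bai_nwb": compute_bai(h_nwb, foot_length_mm),
            "deformation_mm": deform,
            "flexibility_um_per_N": compute_flexibility(h_nwb, h_wb, load),
            "energy_J": energy,
            "arch_class": classify_arch(h_wb / foot_length_mm),
        }
    )


def compute_deltas(
    metrics: pd.DataFrame,
    first_cycle: int = 1,
    last_cycle: int = 10_000,
    specimen_id: str = "",
    columns: Iterable[str] = ("bai_wb", "flexibility_um_per_N", "energy_J"),
) -> pd.Series:
    """First-minus-last differences of the arch metrics for one specimen.

    Returns a Series of ``delta_<metric>`` values (value at ``first_cycle``
    minus value at ``last_cycle``); positive deltas mean the metric declined
    over the loading history.
    """
    indexed = metrics.set_index("cycle")
    for cp in (first_cycle, last_cycle):
        if cp not in indexed.index:
            raise ValueError(
                f"specimen {specimen_id or '<unnamed>'}: cycle {cp} missing; "
                "cannot compute first-vs-last deltas"
            )
    first = indexed.loc[first_cycle]
    last = indexed.loc[last_cycle]
    return pd.Series({f"delta_{c}": float(first[c]) - float(last[c]) for c in columns})
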