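"""Shared fixtures: one fully analysed default cohort, reused session-wide."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import archfatigue as af

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: master seed of the reference cohort used throughout the suite
MASTER_SEED = 0


class CohortAnalysis:
    """Full pipeline products of the 18-specimen, 10,000-cycle default cohort."""

    def __init__(self, master_seed: int = MASTER_SEED, n_per_group: int = 6):
        self.checkpoints = af.default_checkpoints()
        self.traces, self.manifest = af.simulate_cohort(
            n_per_group=n_per_group, master_seed=master_seed
        )
        self.group_of = dict(zip(self.manifest.specimen_id, self.manifest.group))
        self.metrics: dict[str, pd.DataFrame] = {}
        rows, delta_rows = [], []
        for trace in self.traces:
            cycles = af.segment_cycles(trace)
            m = af.cycle_metrics(cycles, trace.foot_length_mm)
            self.metrics[trace.specimen_id] = m
            rows.append(
                af.checkpoint_series(m, self.checkpoints).assign(
                    specimen_id=trace.specimen_id, group=trace.group
                )
            )
            d = af.compute_deltas(m, 1, 10_000, trace.specimen_id)
            delta_rows.append({"specimen_id": trace.specimen_id, "group": trace.group, **d})
        self.checkpoint_table = pd.concat(rows, ignore_index=True)
        self.deltas = pd.DataFrame(delta_rows)
        self.fits, self.fit_report = af.fit_specimens(self.metrics, self.checkpoints)
        self.inflections = pd.DataFrame(
            [
                {
                    "specimen_id": sid,
                    "group": self.group_of[sid],
                    "selected_order": fit.selected_order,
                    "r2_cubic": fit.fits[3].r2,
                    "inflection_cycle": fit.inflection_cycle,
                }
                for sid, fit in self.fits.items()
            ]
        )
        self.stats = af.cohort_stats(
            self.checkpoint_table, deltas=self.deltas, inflections=self.inflections
        )

    def group_mean(self, group: str, cycle: int, metric: str = "bai_wb") -> float:
        tab = self.checkpoint_table
        sel = tab[(tab.group == group) & (tab.cycle == cycle)]
        return float(sel[metric].mean())


@pytest.fixture(scope="session")
def cohort() -> CohortAnalysis:
    return CohortAnalysis()


@pytest.fixture()
def noise_free_params():
    """Obese-shaped trajectory rescaled to 200 cycles, all noise off."""
    coef = af.calibrate_group_trajectory(
        [(1, 0.24), (20, 0.203)], 130, 0.124, total_cycles=200
    )
    return af.GeneratorParams(
        group="custom",
        peak_load_n=1000.0,
        trajectory_coef=tuple(coef),
        foot_length_mm_sd=0.0,
        bai_offset_sd=0.0,
        inflection_jitter_sd_cycles=0.0,
        cycle_noise_sd_mm=0.0,
        lack_of_fit_rms_mm=0.0,
        d0_mm=6.0,
        d0_rel_sd=0.0,
        d_retained_fraction=0.6,
        d_noise_sd_mm=0.0,
        marker_noise_sd_mm=0.0,
        tendon_noise_sd_n=0.0,
        total_cycles=200,
    )
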