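"""Synthetic trace generator: planted-value round trips and contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import archfatigue as af
from archfatigue.synthgen import GROUPS, _lack_of_fit_profile, default_params


def test_noise_free_trace_round_trips_the_group_cubic(noise_free_params):
    """With every noise source off, extracted per-cycle BAI equals the cubic."""
    p = noise_free_params
    trace = af.simulate_specimen(p, 7)
    cycles = af.segment_cycles(trace)
    assert len(cycles) == p.total_cycles
    m = af.cycle_metrics(cycles, trace.foot_length_mm)
    expected = p.trajectory(np.arange(1, p.total_cycles + 1, dtype=float))
    np.testing.assert_allclose(m["bai_wb"].to_numpy(), expected, atol=1e-12)
    # peak load is hit exactly and the planted deformation is recovered
    np.testing.assert_allclose(cycles["peak_load_N"], p.peak_load_n)
    planted_d = p.d0_mm * p.deformation_decay(np.arange(1, p.total_cycles + 1))
    np.testing.assert_allclose(m["deformation_mm"], planted_d, atol=1e-10)
    # group-mean extracted BAI is non-increasing on the noise-free trace
    assert np.all(np.diff(m["bai_wb"]) <= 1e-12)


def test_tendon_engages_exactly_with_the_load_threshold():
    p = default_params("obese", total_cycles=50)
    trace = af.simulate_specimen(p, 3)
    load = trace.data["load_N"].to_numpy()
    tendon = trace.data["tendon_N"].to_numpy()
    engaged = np.abs(tendon - p.tendon_force_n) < 5 * p.tendon_noise_sd_n + 1e-9
    assert np.array_equal(engaged, load >= p.tendon_engage_threshold_n)
    assert np.all(tendon[load < p.tendon_engage_threshold_n] == 0.0)
    assert np.all(load >= 0)


def test_cohort_is_deterministic_and_complete(tmp_path):
    """Same master seed twice: byte-identical files; 18 traces + manifest."""
    gp = {g: default_params(g, total_cycles=40) for g in GROUPS}
    a1, m1 = af.simulate_cohort(gp, 6, master_seed=11, outdir=tmp_path / "a")
    a2, m2 = af.simulate_cohort(gp, 6, master_seed=11, outdir=tmp_path / "b")
    assert len(a1) == 18 and len(m1) == 18
    pd.testing.assert_frame_equal(m1, m2)
    for f1 in sorted((tmp_path / "a").iterdir()):
        f2 = tmp_path / "b" / f1.name
        assert f1.read_bytes() == f2.read_bytes()
    # a different seed changes the data
    a3, _ = af.simulate_cohort(gp, 6, master_seed=12)
    assert not np.allclose(
        a1[0].data["navicular_y_mm"], a3[0].data["navicular_y_mm"]
    )


def test_trace_csv_round_trip(tmp_path):
    p = default_params("normal", total_cycles=10)
    trace = af.simulate_specimen(p, 5, specimen_id="normal_x")
    af.write_trace(trace, tmp_path / "normal_x.csv")
    back = af.read_trace(tmp_path / "normal_x.csv", group="normal",
                         foot_length_mm=trace.foot_length_mm, peak_load_n=500.0)
    assert back.sampling_rate_hz == pytest.approx(p.sampling_rate_hz)
    np.testing.assert_allclose(back.data["navicular_y_mm"], trace.data["navicular_y_mm"],
                               rtol=1e-9)


@pytest.mark.parametrize(
    "field,value",
    [
        ("d0_mm", -1.0),
        ("d_retained_fraction", 0.0),
        ("d_retained_fraction", 1.5),
        ("foot_length_mm_mean", -5.0),
        ("peak_load_n", 750.0),  # named groups use 500 or 1000 N
    ],
)
def test_invalid_parameters_rejected(field, value):
    base = dataclasses.asdict(default_params("obese"))
    base[field] = value
    with pytest.raises(ValueError):
        af.GeneratorParams(**base)


def test_lack_of_fit_profile_is_invisible_to_polynomials_and_checkpoints():
    """The systematic non-cubic component perturbs neither checkpoint values
    nor polynomial fits: it is orthogonal to the monomials on the cycle grid
    and pinned to zero at the checkpoint nodes."""
    n = 2000
    nodes = af.default_checkpoints(n, n // 10)
    w = _lack_of_fit_profile(n, tuple(nodes), 5)
    assert np.sqrt(np.mean(w**2)) == pytest.approx(1.0, rel=1e-9)
    x = np.arange(n) / (n - 1)
    for deg in range(6):
        assert abs(np.dot(w, x**deg)) < 1e-6 * n
    assert np.all(np.abs(w[[c - 1 for c in nodes]]) < 1e-9)


def test_specimen_inflection_jitter_has_configured_spread():
    """Planted per-specimen inflections scatter around the group value with
    roughly the configured SD (time-scaling keeps them exact per specimen)."""
    p = default_params("obese", total_cycles=10)  # trajectory is what matters
    chi0 = p.inflection_cycle
    sd = p.inflection_jitter_sd_cycles
    planted = []
    for k in range(400):
        rng = np.random.default_rng([33, k])
        rng.normal(), rng.normal()  # foot length, offset draws
        delta = float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd))
        planted.append(chi0 + delta)
    planted = np.asarray(planted)
    assert planted.mean() == pytest.approx(chi0, abs=0.25 * sd)
    assert planted.std() == pytest.approx(sd, rel=0.15)


def test_single_specimen_cohort_runs():
    gp = {"obese": default_params("obese", total_cycles=20)}
    traces, manifest = af.simulate_cohort(gp, 1, master_seed=2)
    assert len(traces) == 1
    summ = af.summarize_group(
        [af.cycle_metrics(af.segment_cycles(traces[0]), traces[0].foot_length_mm)["bai_wb"].iloc[0]]
    )
    assert summ["ci_defined"] is False
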