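"""Permeation counting: constructed paths, symmetry properties, the
brute-force per-frame oracle, and the conductance arithmetic."""

import numpy as np
import pandas as pd
import pytest

from ionspike.permeation import (
    CrossingRecord,
    PoreDefinition,
    TrajectoryTable,
    block_errors,
    conductance,
    count_crossings,
    events_dataframe,
    read_trajectory,
    write_trajectory,
)
from ionspike.synthetic import make_drift_trajectory

PORE = PoreDefinition(z_lower=-10.0, z_upper=10.0, radius=5.0)


def traj_from_z(z, x=None, y=None, dt=10.0, box=None, ion=0):
    n = len(z)
    frames = pd.DataFrame(
        {
            "time_ps": np.arange(n) * dt,
            "ion": ion,
            "x": np.zeros(n) if x is None else np.asarray(x, float),
            "y": np.zeros(n) if y is None else np.asarray(y, float),
            "z": np.asarray(z, float),
        }
    )
    return TrajectoryTable(frames, dt, box)


# --------------------------------------------------------------------------
# brute-force reference counter (independent per-frame implementation)


def brute_force_count(traj: TrajectoryTable, pore: PoreDefinition):
    events = []
    box_z = traj.box_a[2] if traj.box_a is not None else None
    for ion, sub in traj.frames.groupby("ion"):
        t = sub["time_ps"].to_numpy()
        x = sub["x"].to_numpy()
        y = sub["y"].to_numpy()
        z = sub["z"].to_numpy().astype(float).copy()
        if box_z is not None:
            for k in range(1, len(z)):
                while z[k] - z[k - 1] > box_z / 2:
                    z[k:] -= box_z
                    break
                while z[k] - z[k - 1] < -box_z / 2:
                    z[k:] += box_z
                    break
        side = None  # "below"/"above"
        pending = None  # (origin, entry_time) while validly inside
        for k in range(len(z)):
            if z[k] < pore.z_lower:
                if pending and pending[0] == "above":
                    events.append((int(ion), "down", pending[1], float(t[k])))
                side, pending = "below", None
            elif z[k] > pore.z_upper:
                if pending and pending[0] == "below":
                    events.append((int(ion), "up", pending[1], float(t[k])))
                side, pending = "above", None
            else:
                lateral_ok = pore.radius is None or (
                    np.hypot(x[k] - pore.axis_xy[0], y[k] - pore.axis_xy[1])
                    <= pore.radius
                )
                if not lateral_ok:
                    pending, side = None, None
                elif pending is None and side is not None:
                    pending = (side, float(t[k]))
    return events


def as_tuples(events):
    return [(e.ion, e.direction, e.entry_time, e.exit_time) for e in events]


# --------------------------------------------------------------------------
# constructed paths


def test_monotone_pass_counts_one_up_event():
    events = count_crossings(traj_from_z([-20, -5, 0, 5, 20]), PORE)
    assert len(events) == 1
    assert events[0].direction == "up"
    assert events[0].entry_time == 10.0 and events[0].exit_time == 40.0


def test_reentry_from_same_side_is_rejected():
    events = count_crossings(traj_from_z([-20, -5, 0, -5, -20]), PORE)
    assert events == []


def test_lateral_excursion_invalidates_transit():
    z = [-20, -5, 0, 5, 20]
    x = [0, 0, 9.0, 0, 0]  # exits the 5 A radius while inside
    assert count_crossings(traj_from_z(z, x=x), PORE) == []
    # same path within the radius counts
    assert len(count_crossings(traj_from_z(z), PORE)) == 1


def test_slab_criterion_ignores_radius_when_disabled():
    slab = PoreDefinition(-10.0, 10.0, radius=None)
    z = [-20, 0, 20]
    x = [0, 50.0, 0]
    assert len(count_crossings(traj_from_z(z, x=x), slab)) == 1


def test_periodic_unwrap_across_box_jump():
    # ion drifts up and wraps from +45 to -45 in a 100 A box: after
    # unwrapping it has simply moved above the pore
    z = [-20, -5, 5, 20, 45, -45, -30]
    events = count_crossings(traj_from_z(z, box=(50.0, 50.0, 100.0)), PORE)
    assert len(events) == 1 and events[0].direction == "up"


def test_unsorted_times_raise():
    frames = pd.DataFrame(
        {"time_ps": [10.0, 0.0], "ion": 0, "x": 0.0, "y": 0.0, "z": [0.0, 1.0]}
    )
    with pytest.raises(ValueError, match="sorted"):
        count_crossings(TrajectoryTable(frames, 10.0), PORE)


# --------------------------------------------------------------------------
# properties


def test_time_reversal_swaps_up_and_down():
    traj, _ = make_drift_trajectory(6, 1.5, 10.0, 30.0, 40.0, PORE, seed=8)
    fwd = count_crossings(traj, PORE)
    rev_frames = (
        traj.frames.sort_values(["ion", "time_ps"], ascending=[True, False])
        .assign(time_ps=lambda d: d.groupby("ion")["time_ps"].transform(
            lambda s: s.max() - s
        ))
        .reset_index(drop=True)
    )
    rev = count_crossings(TrajectoryTable(rev_frames, 10.0), PORE)
    n_up_f = sum(e.direction == "up" for e in fwd)
    n_dn_f = len(fwd) - n_up_f
    n_up_r = sum(e.direction == "up" for e in rev)
    n_dn_r = len(rev) - n_up_r
    assert (n_up_f, n_dn_f) == (n_dn_r, n_up_r)


def test_concatenation_additivity():
    a = traj_from_z([-20, 0, 20])
    b_z = [20, 25, 30]  # continues above: no boundary-spanning event
    both = traj_from_z([-20, 0, 20, 20, 25, 30])
    na = len(count_crossings(a, PORE))
    nb = len(count_crossings(traj_from_z(b_z), PORE))
    assert len(count_crossings(both, PORE)) == na + nb + 0


@pytest.mark.parametrize("seed", range(5))
def test_counter_matches_brute_force(seed):
    traj, truth = make_drift_trajectory(
        4, 1.0, 10.0, drift_a_per_ns=20.0, diffusion_a2_per_ns=80.0,
        pore=PORE, seed=seed,
    )
    fast = count_crossings(traj, PORE)
    assert as_tuples(fast) == brute_force_count(traj, PORE)
    assert as_tuples(fast) == as_tuples(truth)


# --------------------------------------------------------------------------
# conductance arithmetic


def test_conductance_zero_events():
    assert conductance([], 500.0, 600.0) == (0.0, 0.0)


def test_conductance_hand_arithmetic():
    events = [CrossingRecord(0, "up", 0.0, 1.0)] * 19
    current_pa, g_ps = conductance(events, 500.0, 600.0, ion_charge=1.0)
    assert current_pa == pytest.approx(6.088, abs=0.005)
    assert g_ps == pytest.approx(10.147, rel=0.005)


def test_conductance_cancellation_and_errors():
    events = [CrossingRecord(0, "up", 0.0, 1.0), CrossingRecord(1, "down", 0.0, 1.0)]
    assert conductance(events, 100.0, 600.0)[0] == 0.0
    with pytest.raises(ZeroDivisionError):
        conductance(events, 100.0, 0.0)
    with pytest.raises(ValueError):
        conductance(events, -1.0, 600.0)


# --------------------------------------------------------------------------
# block averaging


def test_block_errors_identical_blocks_zero_se():
    # one up-crossing per 100 ps, perfectly periodic over 4 blocks
    z = np.tile([-20.0, 0.0, 20.0, 20.0, -20.0], 8)[:40]
    traj = traj_from_z(z, dt=5.0)
    mean, se = block_errors(traj, PORE, 4, v_m_mv=600.0)
    assert se == pytest.approx(0.0, abs=1e-12)
    assert mean > 0


def test_block_errors_validation():
    traj = traj_from_z([-20, 0, 20, -20, 0, 20], dt=5.0)
    with pytest.raises(ValueError):
        block_errors(traj, PORE, 1, 600.0)
    with pytest.raises(ValueError, match="frames"):
        block_errors(traj, PORE, 5, 600.0)


def test_block_errors_scatter_tracks_poisson_scale():
    """A stationary random crossing process gives block-to-block scatter on
    the order of the square-root counting error."""
    rng = np.random.default_rng(12)
    dt, n_frames, n_ions = 20.0, 200, 60
    times = np.arange(n_frames) * dt
    rows = []
    for ion in range(n_ions):
        # each ion makes one quick transit at a uniformly random time
        z = np.full(n_frames, -20.0)
        k = rng.integers(2, n_frames - 2)
        z[k] = 0.0
        z[k + 1 :] = 20.0
        rows.append(
            pd.DataFrame(
                {"time_ps": times, "ion": ion, "x": 0.0, "y": 0.0, "z": z}
            )
        )
    traj = TrajectoryTable(pd.concat(rows, ignore_index=True), dt)
    events = count_crossings(traj, PORE)
    n = len(events)
    assert n == n_ions
    mean, se = block_errors(traj, PORE, 4, v_m_mv=600.0)
    _, g_all = conductance(events, traj.duration_ns, 600.0)
    se_theory = g_all / np.sqrt(n)
    assert 0 < se < 3 * se_theory


# --------------------------------------------------------------------------
# I/O round trip


def test_trajectory_roundtrip(tmp_path):
    traj, _ = make_drift_trajectory(2, 0.2, 10.0, 30.0, 20.0, PORE, seed=1)
    p = tmp_path / "traj.tsv"
    write_trajectory(traj, p)
    back = read_trajectory(p)
    pd.testing.assert_frame_equal(back.frames, traj.frames)
    assert back.frame_interval_ps == traj.frame_interval_ps
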