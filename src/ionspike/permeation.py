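"""Ion permeation counting and single-channel conductance from trajectory
data.

A trajectory table holds (time ps, ion id, x/y/z Angstrom) samples.  A pore
is a slab between two z planes, optionally with a lateral radius gate
around a pore axis.  Complete crossings are detected per ion by a
three-state machine over (below / inside / above): an up-crossing is
below -> inside -> above without an intervening return to below or, when
the radius gate is enabled, a lateral excursion beyond the radius while
inside (symmetrically for down-crossings).  The z coordinate is unwrapped
across periodic-box jumps larger than box_z/2 before classification.

Current and conductance follow I = n_net * z * e / T and g = I / V_m,
with n_net the signed (up - down) crossing count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import E_CHARGE

__all__ = [
    "TrajectoryTable",
    "PoreDefinition",
    "CrossingRecord",
    "count_crossings",
    "conductance",
    "block_errors",
    "read_trajectory",
    "write_trajectory",
]


@dataclass
class TrajectoryTable:
    """Tidy ion-position table with columns time_ps, ion, x, y, z (A)."""

    frames: pd.DataFrame
    frame_interval_ps: float
    box_a: tuple[float, float, float] | None = None  # box dims, A; None = unwrapped

    def __post_init__(self) -> None:
        required = {"time_ps", "ion", "x", "y", "z"}
        missing = required - set(self.frames.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {sorted(missing)}")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def duration_ns(self) -> float:
        t = self.frames["time_ps"]
        return float(t.max() - t.min()) / 1000.0

    def per_ion(self):
        for ion, sub in self.frames.groupby("ion", sort=True):
            t = sub["time_ps"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"ion {ion}: times not sorted")
            yield ion, t, sub[["x", "y", "z"]].to_numpy()


@dataclass
class PoreDefinition:
    z_lower: float  # A
    z_upper: float  # A
    axis_xy: tuple[float, float] = (0.0, 0.0)
    radius: float | None = None  # None disables the lateral gate (slab criterion)
    ion_charge: float = 1.0  # e0

    def __post_init__(self) -> None:
        if self.z_upper <= self.z_lower:
            raise ValueError("z_upper must exceed z_lower")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class CrossingRecord:
    ion: int
    direction: str  # "up" or "down"
    entry_time: float  # ps, first frame inside the pore
    exit_time: float  # ps, first frame on the far side

    def __post_init__(self) -> None:
        if self.exit_time <= self.entry_time:
            raise ValueError("exit_time must be after entry_time")


def _unwrap_z(z: np.ndarray, box_z: float | None) -> np.ndarray:
    if box_z is None or len(z) < 2:
        return z
    dz = np.diff(z)
    jumps = np.zeros_like(dz)
    jumps[dz > box_z / 2] = -box_z
    jumps[dz < -box_z / 2] = box_z
    return z + np.concatenate([[0.0], np.cumsum(jumps)])


# per-sample region codes
_BELOW, _INSIDE, _ABOVE, _GUTTER = 0, 1, 2, 3


def _classify(xyz: np.ndarray, pore: PoreDefinition, box_z: float | None) -> np.ndarray:
    z = _unwrap_z(xyz[:, 2].astype(float), box_z)
    region = np.full(len(z), _INSIDE, dtype=np.int64)
    region[z < pore.z_lower] = _BELOW
    region[z > pore.z_upper] = _ABOVE
    if pore.radius is not None:
        lateral = np.hypot(
            xyz[:, 0] - pore.axis_xy[0], xyz[:, 1] - pore.axis_xy[1]
        )
        region[(region == _INSIDE) & (lateral > pore.radius)] = _GUTTER
    return region


def count_crossings(
    traj: TrajectoryTable, pore: PoreDefinition
) -> list[CrossingRecord]:
    """Detect complete pore crossings for every ion in the trajectory."""
    box_z = traj.box_a[2] if traj.box_a is not None else None
    events: list[CrossingRecord] = []
    for ion, times, xyz in traj.per_ion():
        region = _classify(xyz, pore, box_z)
        origin = -1  # side the ion last occupied: _BELOW, _ABOVE, or -1
        entry_t = np.nan
        inside_valid = False
        for k in range(len(region)):
            r = region[k]
            if r == _BELOW:
                if inside_valid and origin == _ABOVE:
                    events.append(
                        CrossingRecord(int(ion), "down", entry_t, float(times[k]))
                    )
                origin = _BELOW
                inside_valid = False
            elif r == _ABOVE:
                if inside_valid and origin == _BELOW:
                    events.append(
                        CrossingRecord(int(ion), "up", entry_t, float(times[k]))
                    )
                origin = _ABOVE
                inside_valid = False
            elif r == _INSIDE:
                if not inside_valid:
                    if origin >= 0:
                        inside_valid = True
                        entry_t = float(times[k])
            else:
                # lateral excursion: void the transit; a new one can only
                # begin after the ion returns to either side
                inside_valid = False
                origin = -1
    return events


def events_dataframe(events: list[CrossingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ion": e.ion,
                "direction": e.direction,
                "entry_time_ps": e.entry_time,
                "exit_time_ps": e.exit_time,
            }
            for e in events
        ],
        columns=["ion", "direction", "entry_time_ps", "exit_time_ps"],
    )


def conductance(
    events: list[CrossingRecord],
    duration_ns: float,
    v_m_mv: float,
    ion_charge: float = 1.0,
) -> tuple[float, float]:
    """(current pA, conductance pS) from net crossings:
    I = (n_up - n_down) * z * e / T and g = I / V_m."""
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    if v_m_mv == 0:
        raise ZeroDivisionError(
            "v_m = 0: conductance g = I/V_m is undefined at zero bias; "
            "supply the applied membrane voltage"
        )
    n_up = sum(1 for e in events if e.direction == "up")
    n_down = sum(1 for e in events if e.direction == "down")
    n_net = n_up - n_down
    current_a = n_net * ion_charge * E_CHARGE / (duration_ns * 1e-9)
    current_pa = current_a * 1e12
    g_ps = current_pa / v_m_mv * 1e3  # pA/mV = nS; expressed in pS
    return current_pa, g_ps


def block_errors(
    traj: TrajectoryTable,
    pore: PoreDefinition,
    n_blocks: int,
    v_m_mv: float,
    ion_charge: float = 1.0,
) -> tuple[float, float]:
    """Block averaging: split the trajectory time span into equal blocks,
    compute the conductance per block (events assigned by exit time), and
    return (mean, standard error of the mean)."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    t = traj.frames["time_ps"]
    t0, t1 = float(t.min()), float(t.max())
    block_ps = (t1 - t0) / n_blocks
    if block_ps < 2 * traj.frame_interval_ps:
        raise ValueError("blocks shorter than 2 frames; use fewer blocks")
    events = count_crossings(traj, pore)
    g_blocks = np.zeros(n_blocks)
    for b in range(n_blocks):
        lo = t0 + b * block_ps
        hi = t0 + (b + 1) * block_ps if b < n_blocks - 1 else t1 + 1e-9
        sub = [e for e in events if lo <= e.exit_time < hi]
        _, g_blocks[b] = conductance(sub, block_ps / 1000.0, v_m_mv, ion_charge)
    mean = float(np.mean(g_blocks))
    se = float(np.std(g_blocks, ddof=1) / np.sqrt(n_blocks))
    return mean, se


def write_trajectory(traj: TrajectoryTable, path) -> None:
    """Delimited-text trajectory with a JSON metadata sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    traj.frames.to_csv(path, sep="\t", index=False)
    meta = {
        "frame_interval_ps": traj.frame_interval_ps,
        "box_a": list(traj.box_a) if traj.box_a is not None else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_trajectory(path) -> TrajectoryTable:
    import json
    from pathlib import Path

    path = Path(path)
    frames = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        box = tuple(meta["box_a"]) if meta.get("box_a") else None
        return TrajectoryTable(frames, meta["frame_interval_ps"], box)
    dt = float(np.median(np.diff(np.unique(frames["time_ps"]))))
    return TrajectoryTable(frames, dt, None)
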