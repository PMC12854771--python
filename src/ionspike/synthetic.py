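"""Synthetic data generators: neuron morphologies and ion trajectories.

All generators are pure functions of their specification and a seed.  The
morphology generators stand in for reconstructed pyramidal-cell
morphologies: a ball-and-stick cell (cylindrical soma of 20 um height,
whose lateral area equals that of the equal-diameter sphere, plus a single
dendrite) and a random binary dendritic tree with tapering diameters.  The
trajectory generator produces drift-diffusion ion traces through a defined
pore together with the ground-truth crossing events, computed sample by
sample during generation, for validating the permeation counter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import Morphology, Segment
from .permeation import CrossingRecord, PoreDefinition, TrajectoryTable

__all__ = [
    "SyntheticTreeSpec",
    "make_ball_and_stick",
    "make_random_tree",
    "make_drift_trajectory",
]


def make_ball_and_stick(
    soma_diam: float = 20.0,
    dend_len: float = 200.0,
    dend_diam: float = 2.0,
) -> Morphology:
    """Two-segment cell: soma cylinder (height = diameter, so its lateral
    area equals the sphere of the same diameter) plus one dendrite."""
    if soma_diam <= 0 or dend_len <= 0 or dend_diam <= 0:
        raise ValueError("all dimensions must be positive")
    soma = Segment(
        id=0,
        parent=-1,
        p0=np.zeros(3),
        p1=np.array([0.0, soma_diam, 0.0]),
        d0=soma_diam,
        d1=soma_diam,
        region="soma",
    )
    dend = Segment(
        id=1,
        parent=0,
        p0=soma.p1,
        p1=soma.p1 + np.array([0.0, dend_len, 0.0]),
        d0=dend_diam,
        d1=dend_diam,
        region="dendrite",
    )
    return Morphology([soma, dend])


@dataclass
class SyntheticTreeSpec:
    """Random binary dendritic tree.  The first two branching levels always
    bifurcate (guaranteeing >= 11 dendritic segments at the default depth);
    deeper levels bifurcate with probability ``branch_prob``.  Diameters
    taper by ``taper`` per level from ``trunk_diam``."""

    depth: int = 6
    branch_prob: float = 0.85
    seg_len_range: tuple[float, float] = (80.0, 150.0)
    trunk_diam: float = 2.0
    taper: float = 0.85
    min_diam: float = 0.5
    soma_diam: float = 20.0  # soma height/diameter, um

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must be a probability")
        lo, hi = self.seg_len_range
        if not 0 < lo <= hi:
            raise ValueError("invalid segment length range")


def make_random_tree(spec: SyntheticTreeSpec, seed: int) -> Morphology:
    """Deterministic random dendritic tree on top of a cylindrical soma."""
    rng = np.random.default_rng(seed)
    soma = Segment(
        id=0,
        parent=-1,
        p0=np.zeros(3),
        p1=np.array([0.0, spec.soma_diam, 0.0]),
        d0=spec.soma_diam,
        d1=spec.soma_diam,
        region="soma",
    )
    segments = [soma]
    next_id = [1]

    def grow(parent: Segment, direction: np.ndarray, level: int, diam: float) -> None:
        if level >= spec.depth:
            return
        length = rng.uniform(*spec.seg_len_range)
        # jitter the growth direction, biased outward from the soma
        jitter = rng.normal(scale=0.4, size=3)
        d = direction + jitter
        d /= np.linalg.norm(d)
        d1 = max(diam * spec.taper, spec.min_diam)
        seg = Segment(
            id=next_id[0],
            parent=parent.id,
            p0=parent.p1,
            p1=parent.p1 + d * length,
            d0=diam,
            d1=d1,
            region="dendrite",
        )
        next_id[0] += 1
        segments.append(seg)
        if level + 1 >= spec.depth:
            n_children = 0
        elif level < 2:
            n_children = 2  # deterministic bifurcation near the soma
        else:
            n_children = 2 if rng.random() < spec.branch_prob else 1
        for _ in range(n_children):
            grow(seg, d, level + 1, d1)

    grow(soma, np.array([0.0, 1.0, 0.0]), 0, spec.trunk_diam)
    morph = Morphology(segments)
    if len(morph.region_segments("dendrite")) < 1:
        raise ValueError("tree specification produced no dendritic segments")
    return morph


def make_drift_trajectory(
    n_ions: int,
    duration_ns: float,
    dt_ps: float,
    drift_a_per_ns: float,
    diffusion_a2_per_ns: float,
    pore: PoreDefinition,
    seed: int,
    start_z: float | None = None,
    lateral_sigma: float = 1.0,
) -> tuple[TrajectoryTable, list[CrossingRecord]]:
    """Biased random walk of ``n_ions`` along z with Gaussian lateral
    jitter about the pore axis, plus the ground-truth crossing events
    tracked sample by sample during generation.

    The z step per frame is drift*dt + sqrt(2*D*dt)*N(0,1).  Ions start at
    ``start_z`` (default: 20 A below the lower pore mouth).
    """
    if n_ions < 1 or duration_ns <= 0 or dt_ps <= 0:
        raise ValueError("n_ions, duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ns * 1000.0 / dt_ps)) + 1
    dt_ns = dt_ps / 1000.0
    z0 = start_z if start_z is not None else pore.z_lower - 20.0
    sigma_step = np.sqrt(2.0 * diffusion_a2_per_ns * dt_ns)

    rows = []
    truth: list[CrossingRecord] = []
    times = np.arange(n_frames) * dt_ps
    for ion in range(n_ions):
        dz = drift_a_per_ns * dt_ns + sigma_step * rng.standard_normal(n_frames - 1)
        z = z0 + np.concatenate([[0.0], np.cumsum(dz)])
        x = pore.axis_xy[0] + lateral_sigma * rng.standard_normal(n_frames)
        y = pore.axis_xy[1] + lateral_sigma * rng.standard_normal(n_frames)

        # ground truth, tracked with the slab/radius semantics frame by frame
        origin = -1  # 0 below, 2 above
        inside_valid = False
        entry_t = np.nan
        for k in range(n_frames):
            if z[k] < pore.z_lower:
                if inside_valid and origin == 2:
                    truth.append(CrossingRecord(ion, "down", entry_t, float(times[k])))
                origin, inside_valid = 0, False
            elif z[k] > pore.z_upper:
                if inside_valid and origin == 0:
                    truth.append(CrossingRecord(ion, "up", entry_t, float(times[k])))
                origin, inside_valid = 2, False
            else:
                lateral_ok = (
                    pore.radius is None
                    or np.hypot(x[k] - pore.axis_xy[0], y[k] - pore.axis_xy[1])
                    <= pore.radius
                )
                if not lateral_ok:
                    inside_valid = False
                    origin = -1
                elif not inside_valid and origin >= 0:
                    inside_valid = True
                    entry_t = float(times[k])
        rows.append(
            pd.DataFrame(
                {"time_ps": times, "ion": ion, "x": x, "y": y, "z": z}
            )
        )
    frames = pd.concat(rows, ignore_index=True)
    traj = TrajectoryTable(frames, frame_interval_ps=dt_ps, box_a=None)
    return traj, truth
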