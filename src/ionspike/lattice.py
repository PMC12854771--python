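"""Coarse-grained lattice Monte Carlo model of voltage-gated channels in a
binary lipid membrane.

A square lattice with periodic boundaries holds exactly one occupant per
site: a saturated lipid, an unsaturated lipid, or a voltage-gated channel
(Na or K selective).  Each channel carries four voltage sensors, one facing
each lattice neighbour; the channel conducts only when all four sensors are
activated.  The Hamiltonian is Ising-like, with a "gating" term for the
intrinsic plus voltage-dependent energy of each activated sensor and an
"interaction" term summed over nearest-neighbour pairs: lipid-lipid
couplings drive phase separation of the binary mixture, and state-dependent
sensor-lipid couplings let the local lipid environment stabilise or
destabilise the open state.

Dynamics are Metropolis Monte Carlo with a fixed move mixture: sensor
flips (Glauber), lipid swaps (Kawasaki, composition-conserving), channel
translation into a neighbouring lipid site, and 90-degree channel rotation.
All energies are in units of k_B*T_REF (see :mod:`ionspike.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .units import F_V, PS_MV_TO_PA, beta_ref, celsius_to_kelvin

__all__ = [
    "NA",
    "K",
    "GatingParams",
    "MembranePatch",
    "PatchObservables",
    "PatchTrace",
    "build_patch",
    "total_energy",
    "mc_sweep",
    "run_sweeps",
    "count_open",
    "patch_current",
    "eps_for_vhalf",
    "save_trace",
]

# occupant encoding on the lattice
OCC_SAT = 0
OCC_UNSAT = 1
OCC_CHANNEL_BASE = 2  # occupant = OCC_CHANNEL_BASE + channel index

# selectivity encoding
NA = 0
K = 1

# neighbour directions: 0:+row, 1:+col, 2:-row, 3:-col.
# sensor s of a channel with orientation o faces direction (s + o) % 4.
_DI = np.array([1, 0, -1, 0], dtype=np.int64)
_DJ = np.array([0, 1, 0, -1], dtype=np.int64)


def eps_for_vhalf(q_gate: float, v_half_mv: float) -> float:
    """Sensor activation energy (k_B*T_REF) giving a two-state midpoint at
    ``v_half_mv`` for gating charge ``q_gate`` (e0) in the zero-coupling
    limit, where P(activated) = 1/(1 + exp((eps - q*V*F_V)/k_B T))."""
    return q_gate * F_V * v_half_mv


@dataclass
class GatingParams:
    """All couplings and thermodynamic inputs of the lattice model.

    Energies are in k_B*T_REF.  Index order for per-selectivity pairs is
    (Na, K); lipid species index order is (saturated, unsaturated); sensor
    state index order is (resting, activated).
    """

    q_gate: tuple[float, float] = (1.5, 1.5)
    eps_g: tuple[float, float] = (
        eps_for_vhalf(1.5, -45.0),  # Na half-activation at -45 mV
        eps_for_vhalf(1.5, -35.0),  # K half-activation at -35 mV
    )
    j_lipid: np.ndarray = field(
        default_factory=lambda: np.array([[-0.35, 0.35], [0.35, -0.35]])
    )
    j_sensor_lipid: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [0.1, -0.3]])
    )
    j_sensor_sensor: float = 0.0
    temperature_c: float = 30.0
    v_m_mv: float = -65.0
    gamma_ps: tuple[float, float] = (20.0, 20.0)
    e_rev_mv: tuple[float, float] = (50.0, -77.0)
    move_mix: tuple[float, float, float, float] = (0.5, 0.3, 0.15, 0.05)

    def __post_init__(self) -> None:
        self.j_lipid = np.asarray(self.j_lipid, dtype=np.float64)
        self.j_sensor_lipid = np.asarray(self.j_sensor_lipid, dtype=np.float64)
        if self.j_lipid.shape != (2, 2):
            raise ValueError("j_lipid must be a 2x2 matrix")
        if not np.allclose(self.j_lipid, self.j_lipid.T):
            raise ValueError("j_lipid must be symmetric")
        if self.j_sensor_lipid.shape != (2, 2):
            raise ValueError("j_sensor_lipid must be 2x2 (state x species)")
        mix = np.asarray(self.move_mix, dtype=np.float64)
        if mix.shape != (4,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("move_mix must be 4 nonnegative probabilities summing to 1")
        celsius_to_kelvin(self.temperature_c)  # validates > 0 K

    @property
    def beta(self) -> float:
        return beta_ref(self.temperature_c)

    def with_(self, **kwargs) -> "GatingParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "q_gate": list(self.q_gate),
            "eps_g": list(self.eps_g),
            "j_lipid": self.j_lipid.tolist(),
            "j_sensor_lipid": self.j_sensor_lipid.tolist(),
            "j_sensor_sensor": self.j_sensor_sensor,
            "temperature_c": self.temperature_c,
            "v_m_mv": self.v_m_mv,
            "gamma_ps": list(self.gamma_ps),
            "e_rev_mv": list(self.e_rev_mv),
            "move_mix": list(self.move_mix),
        }


@dataclass
class MembranePatch:
    """State of the lattice: site occupancy plus the channel registry."""

    side_length: int
    occ: np.ndarray  # (L, L) int64, OCC_* encoding
    ch_sel: np.ndarray  # (n_ch,) int64, NA/K
    ch_pos: np.ndarray  # (n_ch, 2) int64
    ch_orient: np.ndarray  # (n_ch,) int64 in {0..3}
    ch_sensors: np.ndarray  # (n_ch, 4) int64 in {0 resting, 1 activated}
    rng: np.random.Generator

    @property
    def n_channels(self) -> int:
        return len(self.ch_sel)

    def composition(self) -> dict[str, int]:
        return {
            "saturated": int(np.sum(self.occ == OCC_SAT)),
            "unsaturated": int(np.sum(self.occ == OCC_UNSAT)),
            "channels": int(np.sum(self.occ >= OCC_CHANNEL_BASE)),
        }

    def validate(self) -> None:
        L = self.side_length
        if self.occ.shape != (L, L):
            raise ValueError("occupancy grid shape mismatch")
        for c in range(self.n_channels):
            i, j = self.ch_pos[c]
            if self.occ[i, j] != OCC_CHANNEL_BASE + c:
                raise ValueError(f"channel {c} registry/grid position mismatch")
        n_ref = int(np.sum(self.occ >= OCC_CHANNEL_BASE))
        if n_ref != self.n_channels:
            raise ValueError("grid channel references do not match registry size")


@dataclass
class PatchObservables:
    sweep_index: int
    n_open_na: int
    n_open_k: int
    current_pa: float
    energy: float


@dataclass
class PatchTrace:
    """Per-sweep observable series plus sampling accumulators."""

    observables: pd.DataFrame  # sweep, n_open_na, n_open_k, current_pA, energy
    sensor_hist: np.ndarray  # (16,) visit counts of channel-0 sensor configs
    n_sensors_active: np.ndarray  # per-sweep total activated sensors
    final_energy: float


def build_patch(
    L: int,
    n_na: int,
    n_k: int,
    frac_unsaturated: float,
    seed: int,
) -> MembranePatch:
    """Assemble a patch: channels placed uniformly at random without overlap
    (all sensors resting, random orientations), remaining sites filled with
    the binary lipid mixture at ``frac_unsaturated`` using largest-remainder
    rounding of the unsaturated count."""
    if n_na < 0 or n_k < 0:
        raise ValueError("channel counts must be nonnegative")
    n_ch = n_na + n_k
    if n_ch > L * L:
        raise ValueError(
            f"capacity error: {n_ch} channels do not fit on a {L}x{L} lattice"
        )
    if not 0.0 <= frac_unsaturated <= 1.0:
        raise ValueError("frac_unsaturated must be within [0, 1]")

    rng = np.random.default_rng(seed)
    n_lipid = L * L - n_ch
    n_unsat = int(np.floor(frac_unsaturated * n_lipid + 0.5))

    flat = np.full(L * L, OCC_SAT, dtype=np.int64)
    perm = rng.permutation(L * L)
    ch_sites = perm[:n_ch]
    lipid_sites = perm[n_ch:]
    flat[lipid_sites[:n_unsat]] = OCC_UNSAT
    for c, s in enumerate(ch_sites):
        flat[s] = OCC_CHANNEL_BASE + c
    occ = flat.reshape(L, L)

    ch_sel = np.concatenate(
        [np.full(n_na, NA, dtype=np.int64), np.full(n_k, K, dtype=np.int64)]
    )
    ch_pos = np.column_stack(np.unravel_index(ch_sites, (L, L))).astype(np.int64)
    if n_ch == 0:
        ch_pos = np.zeros((0, 2), dtype=np.int64)
    ch_orient = rng.integers(0, 4, size=n_ch).astype(np.int64)
    ch_sensors = np.zeros((n_ch, 4), dtype=np.int64)

    patch = MembranePatch(L, occ, ch_sel, ch_pos, ch_orient, ch_sensors, rng)
    patch.validate()
    return patch


# ---------------------------------------------------------------------------
# jitted Hamiltonian and dynamics


@njit(cache=True)
def _pair_energy(
    occ, ch_sel, ch_orient, ch_sensors, i, j, d, L, j_lipid, j_sensor_lipid
):
    """Energy of the bond between site (i, j) and its neighbour in
    direction d.  Channel-channel bonds carry zero energy."""
    ni = (i + _DI[d]) % L
    nj = (j + _DJ[d]) % L
    a = occ[i, j]
    b = occ[ni, nj]
    if a < OCC_CHANNEL_BASE and b < OCC_CHANNEL_BASE:
        return j_lipid[a, b]
    if a >= OCC_CHANNEL_BASE and b >= OCC_CHANNEL_BASE:
        return 0.0
    if a >= OCC_CHANNEL_BASE:
        c = a - OCC_CHANNEL_BASE
        s = (d - ch_orient[c]) % 4  # sensor facing direction d
        return j_sensor_lipid[ch_sensors[c, s], b]
    c = b - OCC_CHANNEL_BASE
    rd = (d + 2) % 4  # direction from neighbour back to (i, j)
    s = (rd - ch_orient[c]) % 4
    return j_sensor_lipid[ch_sensors[c, s], a]


@njit(cache=True)
def _gating_energy_channel(ch_sel, ch_sensors, c, eps_g, q_gate, v_m, j_ss):
    e = 0.0
    sel = ch_sel[c]
    per_sensor = eps_g[sel] - q_gate[sel] * v_m * F_V
    for s in range(4):
        if ch_sensors[c, s] == 1:
            e += per_sensor
    if j_ss != 0.0:
        for s in range(4):
            e += j_ss * ch_sensors[c, s] * ch_sensors[c, (s + 1) % 4]
    return e


@njit(cache=True)
def _total_energy_jit(
    occ, ch_sel, ch_orient, ch_sensors, L, eps_g, q_gate, v_m,
    j_lipid, j_sensor_lipid, j_ss,
):
    e = 0.0
    for i in range(L):
        for j in range(L):
            # count each unordered pair once: +row and +col bonds
            e += _pair_energy(
                occ, ch_sel, ch_orient, ch_sensors, i, j, 0, L, j_lipid, j_sensor_lipid
            )
            e += _pair_energy(
                occ, ch_sel, ch_orient, ch_sensors, i, j, 1, L, j_lipid, j_sensor_lipid
            )
    for c in range(len(ch_sel)):
        e += _gating_energy_channel(ch_sel, ch_sensors, c, eps_g, q_gate, v_m, j_ss)
    return e


@njit(cache=True)
def _site_local_energy(
    occ, ch_sel, ch_orient, ch_sensors, i, j, L, j_lipid, j_sensor_lipid
):
    """Sum of the four bonds incident to one site."""
    e = 0.0
    for d in range(4):
        e += _pair_energy(
            occ, ch_sel, ch_orient, ch_sensors, i, j, d, L, j_lipid, j_sensor_lipid
        )
    return e


@njit(cache=True)
def _two_site_local_energy(
    occ, ch_sel, ch_orient, ch_sensors, i, j, ni, nj, L, j_lipid, j_sensor_lipid
):
    """Bonds incident to the pair of (neighbouring) sites, shared bond once."""
    e = (
        _site_local_energy(occ, ch_sel, ch_orient, ch_sensors, i, j, L,
                           j_lipid, j_sensor_lipid)
        + _site_local_energy(occ, ch_sel, ch_orient, ch_sensors, ni, nj, L,
                             j_lipid, j_sensor_lipid)
    )
    # the a-b bond was counted from both ends; subtract one copy
    for d in range(4):
        if (i + _DI[d]) % L == ni and (j + _DJ[d]) % L == nj:
            e -= _pair_energy(
                occ, ch_sel, ch_orient, ch_sensors, i, j, d, L,
                j_lipid, j_sensor_lipid
            )
            break
    return e


@njit(cache=True)
def _run_kernel(
    occ, ch_sel, ch_pos, ch_orient, ch_sensors,
    n_sweeps, eps_g, q_gate, v_m, beta,
    j_lipid, j_sensor_lipid, j_ss,
    move_cum, gamma, e_rev, energy0, seed,
    out_nopen, out_current, out_energy, out_nact, sensor_hist,
):
    """Run ``n_sweeps`` sweeps of L^2 attempted moves each; returns the
    incrementally tracked total energy.  Per-sweep observables and the
    channel-0 sensor-configuration histogram are accumulated in place."""
    np.random.seed(seed)
    L = occ.shape[0]
    n_ch = len(ch_sel)
    energy = energy0
    attempts = L * L
    for sweep in range(n_sweeps):
        for _ in range(attempts):
            r = np.random.random()
            if r < move_cum[0]:
                move = 0
            elif r < move_cum[1]:
                move = 1
            elif r < move_cum[2]:
                move = 2
            else:
                move = 3

            if move == 0:
                # sensor flip
                if n_ch == 0:
                    continue
                c = np.random.randint(0, n_ch)
                s = np.random.randint(0, 4)
                i, j = ch_pos[c, 0], ch_pos[c, 1]
                d = (s + ch_orient[c]) % 4
                e_before = _gating_energy_channel(
                    ch_sel, ch_sensors, c, eps_g, q_gate, v_m, j_ss
                ) + _pair_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, d, L,
                    j_lipid, j_sensor_lipid,
                )
                ch_sensors[c, s] = 1 - ch_sensors[c, s]
                e_after = _gating_energy_channel(
                    ch_sel, ch_sensors, c, eps_g, q_gate, v_m, j_ss
                ) + _pair_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, d, L,
                    j_lipid, j_sensor_lipid,
                )
                dh = e_after - e_before
                if dh <= 0.0 or np.random.random() < np.exp(-dh * beta):
                    energy += dh
                else:
                    ch_sensors[c, s] = 1 - ch_sensors[c, s]

            elif move == 1:
                # Kawasaki lipid swap
                i = np.random.randint(0, L)
                j = np.random.randint(0, L)
                d = np.random.randint(0, 4)
                ni = (i + _DI[d]) % L
                nj = (j + _DJ[d]) % L
                a = occ[i, j]
                b = occ[ni, nj]
                if a >= OCC_CHANNEL_BASE or b >= OCC_CHANNEL_BASE:
                    continue  # attempted, rejected: not a lipid pair
                if a == b:
                    continue  # dH = 0 no-op exchange, always "accepted"
                e_before = _two_site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, ni, nj, L,
                    j_lipid, j_sensor_lipid,
                )
                occ[i, j], occ[ni, nj] = b, a
                e_after = _two_site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, ni, nj, L,
                    j_lipid, j_sensor_lipid,
                )
                dh = e_after - e_before
                if dh <= 0.0 or np.random.random() < np.exp(-dh * beta):
                    energy += dh
                else:
                    occ[i, j], occ[ni, nj] = a, b

            elif move == 2:
                # channel translation into a neighbouring lipid site
                if n_ch == 0:
                    continue
                c = np.random.randint(0, n_ch)
                d = np.random.randint(0, 4)
                i, j = ch_pos[c, 0], ch_pos[c, 1]
                ni = (i + _DI[d]) % L
                nj = (j + _DJ[d]) % L
                if occ[ni, nj] >= OCC_CHANNEL_BASE:
                    continue  # attempted, rejected outright
                lip = occ[ni, nj]
                e_before = _two_site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, ni, nj, L,
                    j_lipid, j_sensor_lipid,
                )
                occ[ni, nj] = occ[i, j]
                occ[i, j] = lip
                ch_pos[c, 0], ch_pos[c, 1] = ni, nj
                e_after = _two_site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, ni, nj, L,
                    j_lipid, j_sensor_lipid,
                )
                dh = e_after - e_before
                if dh <= 0.0 or np.random.random() < np.exp(-dh * beta):
                    energy += dh
                else:
                    occ[i, j] = occ[ni, nj]
                    occ[ni, nj] = lip
                    ch_pos[c, 0], ch_pos[c, 1] = i, j

            else:
                # channel rotation by +/- 90 degrees
                if n_ch == 0:
                    continue
                c = np.random.randint(0, n_ch)
                rot = 1 if np.random.random() < 0.5 else 3
                i, j = ch_pos[c, 0], ch_pos[c, 1]
                e_before = _site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, L,
                    j_lipid, j_sensor_lipid,
                )
                old = ch_orient[c]
                ch_orient[c] = (old + rot) % 4
                e_after = _site_local_energy(
                    occ, ch_sel, ch_orient, ch_sensors, i, j, L,
                    j_lipid, j_sensor_lipid,
                )
                dh = e_after - e_before
                if dh <= 0.0 or np.random.random() < np.exp(-dh * beta):
                    energy += dh
                else:
                    ch_orient[c] = old

        # per-sweep observables
        n_open_na = 0
        n_open_k = 0
        n_act = 0
        for c in range(n_ch):
            tot = (
                ch_sensors[c, 0] + ch_sensors[c, 1]
                + ch_sensors[c, 2] + ch_sensors[c, 3]
            )
            n_act += tot
            if tot == 4:
                if ch_sel[c] == 0:
                    n_open_na += 1
                else:
                    n_open_k += 1
        out_nopen[sweep, 0] = n_open_na
        out_nopen[sweep, 1] = n_open_k
        out_current[sweep] = (
            n_open_na * gamma[0] * (v_m - e_rev[0])
            + n_open_k * gamma[1] * (v_m - e_rev[1])
        ) * PS_MV_TO_PA
        out_energy[sweep] = energy
        out_nact[sweep] = n_act
        if n_ch > 0:
            code = (
                ch_sensors[0, 0]
                + 2 * ch_sensors[0, 1]
                + 4 * ch_sensors[0, 2]
                + 8 * ch_sensors[0, 3]
            )
            sensor_hist[code] += 1
    return energy


def _params_arrays(params: GatingParams):
    eps_g = np.asarray(params.eps_g, dtype=np.float64)
    q_gate = np.asarray(params.q_gate, dtype=np.float64)
    gamma = np.asarray(params.gamma_ps, dtype=np.float64)
    e_rev = np.asarray(params.e_rev_mv, dtype=np.float64)
    move_cum = np.cumsum(np.asarray(params.move_mix, dtype=np.float64))
    return eps_g, q_gate, gamma, e_rev, move_cum


def total_energy(patch: MembranePatch, params: GatingParams) -> float:
    """Full Hamiltonian recomputed from scratch, in k_B*T_REF units."""
    patch.validate()
    eps_g, q_gate, _, _, _ = _params_arrays(params)
    return float(
        _total_energy_jit(
            patch.occ, patch.ch_sel, patch.ch_orient, patch.ch_sensors,
            patch.side_length, eps_g, q_gate, params.v_m_mv,
            params.j_lipid, params.j_sensor_lipid, params.j_sensor_sensor,
        )
    )


def run_sweeps_raw(
    patch: MembranePatch, params: GatingParams, n_sweeps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Array-only variant of :func:`run_sweeps` for tight driver loops:
    returns (n_open (n,2), current_pA (n,), energy (n,), final_energy)."""
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    eps_g, q_gate, gamma, e_rev, move_cum = _params_arrays(params)
    out_nopen = np.zeros((n_sweeps, 2), dtype=np.int64)
    out_current = np.zeros(n_sweeps)
    out_energy = np.zeros(n_sweeps)
    out_nact = np.zeros(n_sweeps, dtype=np.int64)
    sensor_hist = np.zeros(16, dtype=np.int64)
    energy0 = _total_energy_jit(
        patch.occ, patch.ch_sel, patch.ch_orient, patch.ch_sensors,
        patch.side_length, eps_g, q_gate, params.v_m_mv,
        params.j_lipid, params.j_sensor_lipid, params.j_sensor_sensor,
    )
    seed = int(patch.rng.integers(0, 2**31 - 1))
    final_energy = _run_kernel(
        patch.occ, patch.ch_sel, patch.ch_pos, patch.ch_orient, patch.ch_sensors,
        n_sweeps, eps_g, q_gate, params.v_m_mv, params.beta,
        params.j_lipid, params.j_sensor_lipid, params.j_sensor_sensor,
        move_cum, gamma, e_rev, energy0, seed,
        out_nopen, out_current, out_energy, out_nact, sensor_hist,
    )
    return out_nopen, out_current, out_energy, float(final_energy)


def run_sweeps(
    patch: MembranePatch, params: GatingParams, n_sweeps: int
) -> PatchTrace:
    """Advance the patch by ``n_sweeps`` Metropolis sweeps (L^2 attempted
    moves each), mutating it in place, and return per-sweep observables.

    The RNG seed for the jitted kernel is drawn from the patch's own
    stream, so repeated calls continue a single reproducible sequence.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    eps_g, q_gate, gamma, e_rev, move_cum = _params_arrays(params)
    out_nopen = np.zeros((n_sweeps, 2), dtype=np.int64)
    out_current = np.zeros(n_sweeps)
    out_energy = np.zeros(n_sweeps)
    out_nact = np.zeros(n_sweeps, dtype=np.int64)
    sensor_hist = np.zeros(16, dtype=np.int64)
    energy0 = total_energy(patch, params)
    seed = int(patch.rng.integers(0, 2**31 - 1))
    final_energy = _run_kernel(
        patch.occ, patch.ch_sel, patch.ch_pos, patch.ch_orient, patch.ch_sensors,
        n_sweeps, eps_g, q_gate, params.v_m_mv, params.beta,
        params.j_lipid, params.j_sensor_lipid, params.j_sensor_sensor,
        move_cum, gamma, e_rev, energy0, seed,
        out_nopen, out_current, out_energy, out_nact, sensor_hist,
    )
    df = pd.DataFrame(
        {
            "sweep": np.arange(n_sweeps),
            "n_open_na": out_nopen[:, 0],
            "n_open_k": out_nopen[:, 1],
            "current_pA": out_current,
            "energy": out_energy,
        }
    )
    return PatchTrace(df, sensor_hist, out_nact, float(final_energy))


def mc_sweep(patch: MembranePatch, params: GatingParams) -> PatchObservables:
    """Single Metropolis sweep; returns the post-sweep observables."""
    trace = run_sweeps(patch, params, 1)
    row = trace.observables.iloc[0]
    return PatchObservables(
        sweep_index=int(row["sweep"]),
        n_open_na=int(row["n_open_na"]),
        n_open_k=int(row["n_open_k"]),
        current_pa=float(row["current_pA"]),
        energy=float(row["energy"]),
    )


def count_open(patch: MembranePatch) -> tuple[int, int]:
    """Channels with all four sensors activated, per selectivity."""
    open_mask = patch.ch_sensors.sum(axis=1) == 4
    n_na = int(np.sum(open_mask & (patch.ch_sel == NA)))
    n_k = int(np.sum(open_mask & (patch.ch_sel == K)))
    return n_na, n_k


def patch_current(patch: MembranePatch, params: GatingParams) -> float:
    """Total transmembrane current in pA (outward positive):
    I = sum_X n_open,X * gamma_X * (v_m - E_X)."""
    n_na, n_k = count_open(patch)
    g = params.gamma_ps
    e = params.e_rev_mv
    v = params.v_m_mv
    return (n_na * g[NA] * (v - e[NA]) + n_k * g[K] * (v - e[K])) * PS_MV_TO_PA


def save_trace(trace: PatchTrace, params: GatingParams, path) -> None:
    """Write the observable series as delimited text with a JSON sidecar of
    the gating parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    trace.observables.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    sidecar.write_text(json.dumps(params.to_dict(), indent=2))
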