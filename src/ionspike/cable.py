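"""Compartmental cable-equation solver with leak and Hodgkin-Huxley
currents.

The membrane potential obeys C dV/dt = -I_leak - I_HH - I_syn + I_ext +
I_axial on a tree of control volumes obtained by discretising a
:class:`~ionspike.morphology.Morphology`.  Time stepping is backward Euler:
gate variables are advanced first by exponential integration of their
first-order kinetics (rates scaled by a Q10 factor), then the voltage
system — linear once the conductances are frozen at the new gate values —
is solved exactly by Hines-ordered Gaussian elimination on the tree.

Internal units: mV, ms, nA, uS, nF, um.  External stimulus amplitudes are
given in pA and converted once at assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .morphology import Morphology, frustum_area

__all__ = [
    "CompartmentGrid",
    "MembraneParams",
    "CurrentClamp",
    "ExternalCurrentSeries",
    "SynapticStimulus",
    "SolverState",
    "VoltageTrace",
    "CableModel",
    "discretize",
    "step",
    "run",
    "detect_spikes",
    "save_trace",
]


# ---------------------------------------------------------------------------
# discretisation


@dataclass
class CompartmentGrid:
    """Control volumes of a discretised morphology, in Hines order (every
    compartment's parent has a smaller index; the root is index 0)."""

    parent: np.ndarray  # (n,) int64, -1 for root
    length_um: np.ndarray
    area_um2: np.ndarray
    r_axial_per_ra: np.ndarray  # own axial resistance per unit resistivity, cm^-1
    g_ax_uS: np.ndarray  # axial conductance to parent (0 for root)
    region: list[str]
    midpoint_um: np.ndarray  # (n, 3)
    seg_id: np.ndarray  # originating morphology segment id per compartment

    @property
    def n(self) -> int:
        return len(self.parent)

    def compartments_in_region(self, region: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.region) if r == region])


def discretize(morph: Morphology, max_len: float, r_a: float = 150.0) -> CompartmentGrid:
    """Split every segment into ceil(length/max_len) equal slices.  Frustum
    slice areas are exact, so total membrane area is conserved; the axial
    conductance between adjacent compartments uses the half-resistance
    (midpoint-to-midpoint) scheme with the exact frustum axial integral
    R = r_a * l / (pi * r_prox * r_dist)."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    morph.validate()

    parent, length, area, r_ax, regions, mids, seg_ids = [], [], [], [], [], [], []
    last_comp_of_segment: dict[int, int] = {}

    for seg in morph.topological_order():
        L = seg.length
        n_slices = max(1, int(np.ceil(L / max_len)))
        axis = (seg.p1 - seg.p0) / n_slices
        for k in range(n_slices):
            f0, f1 = k / n_slices, (k + 1) / n_slices
            r0 = 0.5 * (seg.d0 + (seg.d1 - seg.d0) * f0)
            r1 = 0.5 * (seg.d0 + (seg.d1 - seg.d0) * f1)
            l_um = L / n_slices
            idx = len(parent)
            if k == 0:
                parent.append(last_comp_of_segment.get(seg.parent, -1))
            else:
                parent.append(idx - 1)
            length.append(l_um)
            area.append(frustum_area(l_um, r0, r1))
            mids.append(seg.p0 + axis * (k + 0.5))
            regions.append(seg.region)
            seg_ids.append(seg.id)
            # exact frustum axial resistance (placeholder r_a = 1; scaled later)
            r_ax.append(l_um * 1e-4 / (np.pi * (r0 * 1e-4) * (r1 * 1e-4)))  # 1/cm
        last_comp_of_segment[seg.id] = len(parent) - 1

    parent = np.asarray(parent, dtype=np.int64)
    r_ax_per_ra = np.asarray(r_ax)  # multiply by r_a (Ohm*cm) to get Ohm
    g_ax = np.zeros(len(parent))
    r_ohm = r_ax_per_ra * r_a
    for i in range(1, len(parent)):
        p = parent[i]
        if p >= 0:
            g_ax[i] = 2.0 / (r_ohm[i] + r_ohm[p]) * 1e6  # S -> uS
    grid = CompartmentGrid(
        parent=parent,
        length_um=np.asarray(length),
        area_um2=np.asarray(area),
        r_axial_per_ra=r_ax_per_ra,
        g_ax_uS=g_ax,
        region=regions,
        midpoint_um=np.asarray(mids),
        seg_id=np.asarray(seg_ids, dtype=np.int64),
    )
    return grid


# ---------------------------------------------------------------------------
# parameters, stimuli, state


@dataclass
class MembraneParams:
    """Passive and active membrane properties.

    ``hh_densities`` maps region name to (gbar_Na, gbar_K) in S/cm^2;
    regions absent from the map are passive.  Classic squid-axon rate
    functions (resting near -65 mV) are used, with rates scaled by
    q10 ** ((temperature - t_base)/10).
    """

    c_m: float = 1.0  # uF/cm^2
    r_a: float = 150.0  # Ohm*cm
    g_leak: float = 3e-4  # S/cm^2
    e_leak: float = -54.387  # mV
    hh_densities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"soma": (0.12, 0.036)}
    )
    e_na: float = 50.0
    e_k: float = -77.0
    v_init: float = -65.0
    temperature_c: float = 6.3
    t_base_c: float = 6.3
    q10: float = 3.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.g_leak < 0 or self.r_a <= 0:
            raise ValueError("conductances must be >= 0 and r_a > 0")
        for reg, (gna, gk) in self.hh_densities.items():
            if gna < 0 or gk < 0:
                raise ValueError(f"negative HH density for region {reg!r}")

    @property
    def rate_scale(self) -> float:
        return self.q10 ** ((self.temperature_c - self.t_base_c) / 10.0)


@dataclass
class CurrentClamp:
    compartment: int
    amp_pa: float
    t_on: float  # ms
    t_off: float  # ms

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError("clamp offset must be after onset")


@dataclass
class ExternalCurrentSeries:
    """Piecewise-constant injected current: values_pa[k] applies on
    [t0 + k*sample_dt, t0 + (k+1)*sample_dt); zero outside the series."""

    compartment: int
    t0: float
    sample_dt: float
    values_pa: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_dt <= 0:
            raise ValueError("series sample spacing must be positive")
        self.values_pa = np.asarray(self.values_pa, dtype=float)


@dataclass
class SynapticStimulus:
    """Double-exponential conductance synapse driven by an event train.
    ``weight_uS`` is the peak conductance of one event (already including
    any variant scaling factor)."""

    compartment: int
    weight_uS: float
    tau_rise: float = 0.2
    tau_decay: float = 1.7
    e_rev: float = 0.0
    events_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.weight_uS < 0:
            raise ValueError("weight must be >= 0")
        self.events_ms = np.sort(np.asarray(self.events_ms, dtype=float))


@dataclass
class SolverState:
    t: float
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    syn_a: np.ndarray
    syn_b: np.ndarray
    ev_ptr: np.ndarray

    def copy(self) -> "SolverState":
        return SolverState(
            self.t, self.v.copy(), self.m.copy(), self.h.copy(), self.n.copy(),
            self.syn_a.copy(), self.syn_b.copy(), self.ev_ptr.copy(),
        )


@dataclass
class VoltageTrace:
    times: np.ndarray  # (T,) ms
    v: np.ndarray  # (T, n_recorded) mV
    recorded: list[int]  # compartment indices, column order
    spike_times: np.ndarray | None = None

    def v_at(self, compartment: int) -> np.ndarray:
        return self.v[:, self.recorded.index(compartment)]


class NumericalDivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# jitted integrator


@njit(cache=True)
def _hh_gate_steady_tau(v):
    # classic squid rates, modern (-65 mV rest) voltage convention
    if abs(v + 40.0) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * (v + 40.0) / (1.0 - np.exp(-(v + 40.0) / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    if abs(v + 55.0) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * (v + 55.0) / (1.0 - np.exp(-(v + 55.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _advance_kernel(
    parent, cm_nF, gl_uS, el, gna_uS, gk_uS, ena, ek, g_ax,
    v, m, h, n_gate, phi,
    clamp_comp, clamp_amp_nA, clamp_on, clamp_off,
    ser_comp, ser_t0, ser_dt, ser_off, ser_vals_nA,
    syn_comp, syn_w, syn_erev, syn_dec_r, syn_dec_d, syn_norm,
    syn_a, syn_b, ev_times, ev_off, ev_ptr,
    i_ext_const_nA,
    t0, dt, n_steps, rec_idx, rec_out,
):
    nc = len(parent)
    diag = np.empty(nc)
    rhs = np.empty(nc)
    for step_i in range(n_steps):
        t = t0 + step_i * dt
        t_new = t0 + (step_i + 1) * dt

        # 1. gate variables at the current voltage (exponential integrator)
        for i in range(nc):
            if gna_uS[i] > 0.0 or gk_uS[i] > 0.0:
                am, bm, ah, bh, an, bn = _hh_gate_steady_tau(v[i])
                s = phi * dt
                m[i] += (am / (am + bm) - m[i]) * (1.0 - np.exp(-s * (am + bm)))
                h[i] += (ah / (ah + bh) - h[i]) * (1.0 - np.exp(-s * (ah + bh)))
                n_gate[i] += (an / (an + bn) - n_gate[i]) * (
                    1.0 - np.exp(-s * (an + bn))
                )

        # 2. synaptic states: decay, then deliver events in (t, t_new]
        for s_i in range(len(syn_comp)):
            syn_a[s_i] *= syn_dec_r[s_i]
            syn_b[s_i] *= syn_dec_d[s_i]
            p = ev_ptr[s_i]
            end = ev_off[s_i + 1]
            while p < end and ev_times[p] <= t_new:
                syn_a[s_i] += 1.0
                syn_b[s_i] += 1.0
                p += 1
            ev_ptr[s_i] = p

        # 3. assemble the implicit voltage system
        for i in range(nc):
            diag[i] = cm_nF[i] / dt + gl_uS[i] + g_ax[i]
            rhs[i] = cm_nF[i] / dt * v[i] + gl_uS[i] * el
            gna_eff = gna_uS[i] * m[i] ** 3 * h[i]
            gk_eff = gk_uS[i] * n_gate[i] ** 4
            diag[i] += gna_eff + gk_eff
            rhs[i] += gna_eff * ena + gk_eff * ek
            rhs[i] += i_ext_const_nA[i]
        for i in range(1, nc):
            diag[parent[i]] += g_ax[i]  # children couplings on the diagonal

        for c_i in range(len(clamp_comp)):
            if clamp_on[c_i] <= t_new < clamp_off[c_i]:
                rhs[clamp_comp[c_i]] += clamp_amp_nA[c_i]
        for c_i in range(len(ser_comp)):
            k = int(np.floor((t_new - ser_t0[c_i]) / ser_dt[c_i]))
            if 0 <= k < ser_off[c_i + 1] - ser_off[c_i]:
                rhs[ser_comp[c_i]] += ser_vals_nA[ser_off[c_i] + k]
        for s_i in range(len(syn_comp)):
            g = syn_w[s_i] * syn_norm[s_i] * (syn_b[s_i] - syn_a[s_i])
            if g < 0.0:
                g = 0.0
            diag[syn_comp[s_i]] += g
            rhs[syn_comp[s_i]] += g * syn_erev[s_i]

        # 4. Hines elimination (parents have smaller indices)
        for i in range(nc - 1, 0, -1):
            ratio = g_ax[i] / diag[i]
            diag[parent[i]] -= g_ax[i] * ratio
            rhs[parent[i]] += rhs[i] * ratio
        v[0] = rhs[0] / diag[0]
        for i in range(1, nc):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        for i in range(nc):
            if not np.isfinite(v[i]):
                return step_i, i  # divergence: step and compartment
        for r_i in range(len(rec_idx)):
            rec_out[step_i, r_i] = v[rec_idx[r_i]]
    return -1, -1


# ---------------------------------------------------------------------------
# model wrapper


class CableModel:
    """Precompiled arrays for one (grid, params, stimuli) combination.

    Exposes :meth:`initial_state` and :meth:`advance`; :func:`run` and the
    coupling loop are built on top of it.
    """

    def __init__(
        self,
        grid: CompartmentGrid,
        params: MembraneParams,
        stimuli: list | None = None,
    ):
        stimuli = stimuli or []
        self.grid = grid
        self.params = params
        n = grid.n
        area_cm2 = grid.area_um2 * 1e-8
        self.cm_nF = params.c_m * area_cm2 * 1e3
        self.gl_uS = params.g_leak * area_cm2 * 1e6
        gna = np.zeros(n)
        gk = np.zeros(n)
        for i, reg in enumerate(grid.region):
            dens = params.hh_densities.get(reg)
            if dens is not None:
                gna[i] = dens[0] * area_cm2[i] * 1e6
                gk[i] = dens[1] * area_cm2[i] * 1e6
        self.gna_uS, self.gk_uS = gna, gk

        r_ohm = grid.r_axial_per_ra * params.r_a  # per-compartment axial R, Ohm
        g_ax = np.zeros(n)
        for i in range(1, n):
            p = grid.parent[i]
            if p >= 0:
                g_ax[i] = 2.0 / (r_ohm[i] + r_ohm[p]) * 1e6  # S -> uS
        self.g_ax_uS = g_ax
        grid.g_ax_uS = g_ax

        clamps = [s for s in stimuli if isinstance(s, CurrentClamp)]
        series = [s for s in stimuli if isinstance(s, ExternalCurrentSeries)]
        syns = [s for s in stimuli if isinstance(s, SynapticStimulus)]
        for s in stimuli:
            if not isinstance(
                s, (CurrentClamp, ExternalCurrentSeries, SynapticStimulus)
            ):
                raise TypeError(f"unknown stimulus type {type(s)!r}")
            if not 0 <= s.compartment < n:
                raise ValueError(f"stimulus targets invalid compartment {s.compartment}")

        self.clamp_comp = np.array([s.compartment for s in clamps], dtype=np.int64)
        self.clamp_amp_nA = np.array([s.amp_pa * 1e-3 for s in clamps])
        self.clamp_on = np.array([s.t_on for s in clamps])
        self.clamp_off = np.array([s.t_off for s in clamps])

        self.ser_comp = np.array([s.compartment for s in series], dtype=np.int64)
        self.ser_t0 = np.array([s.t0 for s in series])
        self.ser_dt = np.array([s.sample_dt for s in series])
        lens = [len(s.values_pa) for s in series]
        self.ser_off = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        self.ser_vals_nA = (
            np.concatenate([s.values_pa for s in series]) * 1e-3
            if series
            else np.empty(0)
        )

        self.syns = syns
        self.syn_comp = np.array([s.compartment for s in syns], dtype=np.int64)
        self.syn_w = np.array([s.weight_uS for s in syns])
        self.syn_erev = np.array([s.e_rev for s in syns])
        self.syn_taur = np.array([s.tau_rise for s in syns])
        self.syn_taud = np.array([s.tau_decay for s in syns])
        self.syn_norm = np.array(
            [double_exp_norm(s.tau_rise, s.tau_decay) for s in syns]
        )
        ev_lens = [len(s.events_ms) for s in syns]
        self.ev_off = np.concatenate([[0], np.cumsum(ev_lens)]).astype(np.int64)
        self.ev_times = (
            np.concatenate([s.events_ms for s in syns]) if syns else np.empty(0)
        )

    def initial_state(self) -> SolverState:
        n = self.grid.n
        v0 = self.params.v_init
        am, bm, ah, bh, an, bn = _hh_gate_steady_tau(v0)
        return SolverState(
            t=0.0,
            v=np.full(n, v0),
            m=np.full(n, am / (am + bm)),
            h=np.full(n, ah / (ah + bh)),
            n=np.full(n, an / (an + bn)),
            syn_a=np.zeros(len(self.syns)),
            syn_b=np.zeros(len(self.syns)),
            ev_ptr=self.ev_off[:-1].copy(),  # each synapse reads its own slice
        )

    def advance(
        self,
        state: SolverState,
        n_steps: int,
        dt: float,
        record: np.ndarray | None = None,
        i_ext_const_pa: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance ``n_steps`` backward-Euler steps in place; returns the
        recorded voltages (n_steps, len(record))."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        rec_idx = (
            np.asarray(record, dtype=np.int64)
            if record is not None
            else np.empty(0, dtype=np.int64)
        )
        rec_out = np.empty((n_steps, len(rec_idx)))
        i_ext = (
            np.asarray(i_ext_const_pa) * 1e-3
            if i_ext_const_pa is not None
            else np.zeros(self.grid.n)
        )
        bad_step, bad_comp = _advance_kernel(
            self.grid.parent, self.cm_nF, self.gl_uS, self.params.e_leak,
            self.gna_uS, self.gk_uS, self.params.e_na, self.params.e_k,
            self.g_ax_uS,
            state.v, state.m, state.h, state.n, self.params.rate_scale,
            self.clamp_comp, self.clamp_amp_nA, self.clamp_on, self.clamp_off,
            self.ser_comp, self.ser_t0, self.ser_dt, self.ser_off, self.ser_vals_nA,
            self.syn_comp, self.syn_w, self.syn_erev,
            np.exp(-dt / self.syn_taur) if len(self.syns) else np.empty(0),
            np.exp(-dt / self.syn_taud) if len(self.syns) else np.empty(0),
            self.syn_norm, state.syn_a, state.syn_b,
            self.ev_times, self.ev_off, state.ev_ptr,
            i_ext,
            state.t, dt, n_steps, rec_idx, rec_out,
        )
        if bad_step >= 0:
            raise NumericalDivergenceError(
                f"non-finite voltage in compartment {bad_comp} "
                f"at t = {state.t + (bad_step + 1) * dt:.3f} ms"
            )
        state.t += n_steps * dt
        return rec_out


def double_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalisation making a single double-exponential event peak at 1."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return 1.0 / (np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise))


# ---------------------------------------------------------------------------
# public operations


def step(grid, params, stimuli, state: SolverState, dt: float) -> SolverState:
    """One backward-Euler step; returns the advanced state (in place)."""
    model = CableModel(grid, params, stimuli)
    model.advance(state, 1, dt)
    return state


def run(
    grid: CompartmentGrid,
    params: MembraneParams,
    stimuli: list,
    t_stop: float,
    dt: float = 0.025,
    record: list[int] | None = None,
    state: SolverState | None = None,
) -> VoltageTrace:
    """Integrate to ``t_stop`` recording the requested compartments every
    step (default: compartment 0).  Deterministic for fixed inputs."""
    if t_stop < 0:
        raise ValueError("t_stop must be >= 0")
    record = list(record) if record is not None else [0]
    model = CableModel(grid, params, stimuli)
    if state is None:
        state = model.initial_state()
    n_steps = int(np.round(t_stop / dt))
    rec_idx = np.asarray(record, dtype=np.int64)
    first = state.v[rec_idx].copy()
    if n_steps == 0:
        return VoltageTrace(np.array([state.t]), first[None, :], record)
    t_start = state.t
    out = model.advance(state, n_steps, dt, record=rec_idx)
    times = t_start + dt * np.arange(n_steps + 1)
    v = np.vstack([first[None, :], out])
    return VoltageTrace(times, v, record)


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = -20.0,
    min_isi: float = 2.0,
    compartment: int | None = None,
) -> np.ndarray:
    """Upward threshold crossings, suppressing crossings within ``min_isi``
    ms of the previously accepted spike."""
    if min_isi < 0:
        raise ValueError("min_isi must be >= 0")
    if trace.v.size == 0 or len(trace.times) == 0:
        return np.empty(0)
    col = 0 if compartment is None else trace.recorded.index(compartment)
    v = trace.v[:, col]
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    spikes = []
    last = -np.inf
    for k in up:
        t = trace.times[k]
        if t - last >= min_isi:
            spikes.append(t)
            last = t
    return np.asarray(spikes)


def save_trace(trace: VoltageTrace, path, metadata: dict | None = None) -> None:
    """Delimited-text trace (time_ms, v_mV per recorded site) with an
    optional JSON metadata sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    cols = {"time_ms": trace.times}
    for j, comp in enumerate(trace.recorded):
        cols[f"v_mV_comp{comp}"] = trace.v[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, default=str)
        )
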