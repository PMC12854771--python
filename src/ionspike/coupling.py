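"""Bidirectional coupling between the lattice Monte Carlo channel model
and the compartmental membrane solver.

The loop alternates, on a fixed exchange cadence: (a) run the lattice MC
for a window at the current somatic membrane potential; (b) inject the
window-mean patch current (scaled by ``area_scale``) into the soma as a
piecewise-constant membrane current; (c) advance the cable solver over the
same window; (d) feed the end-of-window somatic voltage back into the MC
gating energetics.  Replica ensembles differ only in the MC seed; the
solver itself is deterministic.  Ensembles are summarised by the pointwise
median and first/third quartiles of V_m(t), and spikes by their peak
depolarisation and repolarization time (peak until first return to within
a band of the pre-stimulus baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lattice
from .cable import (
    CableModel,
    CompartmentGrid,
    CurrentClamp,
    MembraneParams,
    NumericalDivergenceError,
    VoltageTrace,
    detect_spikes,
)
from .lattice import GatingParams, MembranePatch, build_patch

__all__ = [
    "CouplingConfig",
    "EnsembleResult",
    "default_two_compartment",
    "run_coupled",
    "repolarization_time",
    "temperature_scan",
]


def default_two_compartment() -> tuple[CompartmentGrid, MembraneParams]:
    """Soma + dendrite cell, one control volume each, with Hodgkin-Huxley
    kinetics referenced at 30 degC so the 20-40 degC scans bracket the
    reference rather than sit far above it."""
    from . import cable as _cable
    from .synthetic import make_ball_and_stick

    morph = make_ball_and_stick(20.0, 100.0, 1.0)
    grid = _cable.discretize(morph, max_len=1000.0)  # one volume per region
    membrane = MembraneParams(t_base_c=30.0, temperature_c=30.0)
    return grid, membrane


@dataclass
class CouplingConfig:
    """Exchange cadence, replica count and stimulation protocol."""

    exchange_dt: float = 0.05  # ms between I <-> V exchanges
    sweeps_per_ms: float = 40.0  # MC sweeps mapped onto 1 ms of physical time
    n_replicas: int = 100
    temperatures: tuple[float, ...] = (40.0, 30.0, 20.0)
    clamp_pa: float = 80.0
    clamp_on: float = 50.0
    clamp_off: float = 150.0
    t_stop: float = 400.0
    dt: float = 0.025  # solver step, ms
    area_scale: float = 1.0  # patch current -> whole-cell current factor
    soma_compartment: int = 0
    couple_solver_temperature: bool = True
    max_abort_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.exchange_dt <= 0:
            raise ValueError("exchange_dt must be positive")
        if self.sweeps_per_ms < 1:
            raise ValueError("sweeps_per_ms must be >= 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


@dataclass
class EnsembleResult:
    times: np.ndarray  # (T,) ms
    traces: np.ndarray  # (n_replicas_completed, T) somatic V_m, mV
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    repolarization_ms: list[np.ndarray]  # per replica, per spike
    peaks_mv: list[np.ndarray]
    censored: int
    aborted: int
    temperature_c: float

    def median_repolarization(self) -> float:
        pooled = np.concatenate([r for r in self.repolarization_ms]) if any(
            len(r) for r in self.repolarization_ms
        ) else np.empty(0)
        return float(np.median(pooled)) if pooled.size else np.nan

    def median_peak(self) -> float:
        pooled = np.concatenate([p for p in self.peaks_mv]) if any(
            len(p) for p in self.peaks_mv
        ) else np.empty(0)
        return float(np.median(pooled)) if pooled.size else np.nan


def _coupled_replica(
    patch: MembranePatch,
    gating: GatingParams,
    model: CableModel,
    cfg: CouplingConfig,
) -> np.ndarray:
    """One replica of the exchange loop; returns the somatic trace
    including the initial sample."""
    steps_per_window = max(1, int(round(cfg.exchange_dt / cfg.dt)))
    sweeps_per_window = max(1, int(round(cfg.sweeps_per_ms * cfg.exchange_dt)))
    n_windows = int(round(cfg.t_stop / cfg.exchange_dt))
    soma = cfg.soma_compartment
    rec = np.array([soma], dtype=np.int64)

    state = model.initial_state()
    v_m = float(state.v[soma])
    out = [np.array([v_m])]
    i_ext = np.zeros(model.grid.n)
    for _ in range(n_windows):
        g = gating.with_(v_m_mv=v_m)
        _, current, _, _ = lattice.run_sweeps_raw(patch, g, sweeps_per_window)
        mean_i = float(current.mean())
        # patch current is a transmembrane (outward-positive) current: it
        # enters the voltage equation with a minus sign, so inward (negative)
        # patch current depolarises the soma.
        i_ext[:] = 0.0
        i_ext[soma] = -mean_i * cfg.area_scale
        rec_out = model.advance(
            state, steps_per_window, cfg.dt, record=rec, i_ext_const_pa=i_ext
        )
        out.append(rec_out[:, 0])
        v_m = float(state.v[soma])
    return np.concatenate(out)


def run_coupled(
    patch_template: dict,
    gating: GatingParams,
    grid: CompartmentGrid,
    membrane: MembraneParams,
    cfg: CouplingConfig,
    seed: int,
    temperature_c: float | None = None,
) -> EnsembleResult:
    """Run the replica ensemble of the bidirectional loop.

    ``patch_template`` holds the :func:`~ionspike.lattice.build_patch`
    arguments except the seed; replica r uses seed ``seed + r``.  If
    ``temperature_c`` is given it overrides both the MC temperature and
    (when ``cfg.couple_solver_temperature``) the solver temperature.
    """
    temp = temperature_c if temperature_c is not None else gating.temperature_c
    gating = gating.with_(temperature_c=temp)
    if cfg.couple_solver_temperature:
        membrane = replace(membrane, temperature_c=temp)
    clamp = CurrentClamp(cfg.soma_compartment, cfg.clamp_pa, cfg.clamp_on, cfg.clamp_off)
    model = CableModel(grid, membrane, [clamp])

    steps_per_window = max(1, int(round(cfg.exchange_dt / cfg.dt)))
    n_windows = int(round(cfg.t_stop / cfg.exchange_dt))
    times = np.concatenate(
        [[0.0], cfg.dt * np.arange(1, n_windows * steps_per_window + 1)]
    )

    traces = []
    aborted = 0
    for r in range(cfg.n_replicas):
        patch = build_patch(seed=seed + r, **patch_template)
        try:
            traces.append(_coupled_replica(patch, gating, model, cfg))
        except NumericalDivergenceError:
            aborted += 1
    if aborted > cfg.max_abort_fraction * cfg.n_replicas:
        raise RuntimeError(
            f"{aborted}/{cfg.n_replicas} replicas diverged; ensemble rejected"
        )
    arr = np.asarray(traces)
    median = np.median(arr, axis=0)
    q1 = np.quantile(arr, 0.25, axis=0)
    q3 = np.quantile(arr, 0.75, axis=0)

    repol, peaks = [], []
    censored = 0
    for tr in arr:
        vt = VoltageTrace(times, tr[:, None], [cfg.soma_compartment])
        r_ms, p_mv, cens = repolarization_time(
            vt, baseline_band=5.0, baseline_until=cfg.clamp_on
        )
        repol.append(r_ms)
        peaks.append(p_mv)
        censored += cens
    return EnsembleResult(
        times, arr, median, q1, q3, repol, peaks, censored, aborted, temp
    )


def repolarization_time(
    trace: VoltageTrace,
    baseline_band: float = 5.0,
    baseline_until: float | None = None,
    threshold: float = -20.0,
    min_isi: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-spike repolarization times and peak depolarisations.

    For each detected spike, the peak is the voltage maximum between the
    threshold crossing and the next spike (or trace end); the
    repolarization time runs from the peak until the voltage first returns
    to within ``baseline_band`` mV of the pre-stimulus baseline (the mean
    voltage before ``baseline_until``, or the first sample).  Spikes that
    never return within the trace are right-censored and excluded; their
    count is returned.
    """
    t = trace.times
    v = trace.v[:, 0]
    spikes = detect_spikes(trace, threshold, min_isi)
    if len(spikes) == 0:
        return np.empty(0), np.empty(0), 0
    if baseline_until is not None and np.any(t < baseline_until):
        baseline = float(np.mean(v[t < baseline_until]))
    else:
        baseline = float(v[0])

    bounds = np.concatenate([spikes, [t[-1] + 1.0]])
    repol, peaks = [], []
    censored = 0
    for k, ts in enumerate(spikes):
        in_spike = (t >= ts) & (t < bounds[k + 1])
        idx = np.flatnonzero(in_spike)
        pk_rel = int(np.argmax(v[idx]))
        pk_idx = idx[pk_rel]
        peaks.append(float(v[pk_idx]))
        after = np.flatnonzero(v[pk_idx:] <= baseline + baseline_band)
        if len(after) == 0:
            censored += 1
            continue
        repol.append(float(t[pk_idx + after[0]] - t[pk_idx]))
    return np.asarray(repol), np.asarray(peaks), censored


def temperature_scan(
    patch_template: dict,
    gating: GatingParams,
    grid: CompartmentGrid,
    membrane: MembraneParams,
    cfg: CouplingConfig,
    seed: int,
) -> tuple[dict[float, EnsembleResult], pd.DataFrame]:
    """Run the coupled ensemble at each configured temperature with matched
    seeds; returns per-temperature results and a summary table."""
    if len(cfg.temperatures) < 2:
        raise ValueError("temperature_scan needs at least 2 temperatures")
    results: dict[float, EnsembleResult] = {}
    rows = []
    for temp in cfg.temperatures:
        res = run_coupled(
            patch_template, gating, grid, membrane, cfg, seed, temperature_c=temp
        )
        results[temp] = res
        rows.append(
            {
                "temperature_c": temp,
                "median_repolarization_ms": res.median_repolarization(),
                "median_peak_mv": res.median_peak(),
                "censored": res.censored,
                "aborted": res.aborted,
            }
        )
    return results, pd.DataFrame(rows)
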