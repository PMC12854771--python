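"""Variant conductance scaling and synaptic stimulation experiments.

This module carries the molecular-to-cellular direction of the workflow:
single-channel conductances of GluA2 AMPA-receptor Q/R-site variants
(estimated from ion-permeation counting) are converted to dimensionless
synaptic scaling factors G = g_variant / g_baseline relative to the RNA-
edited Q586R baseline, which multiply a peak-normalised double-exponential
synaptic conductance g(t).  Synapses are placed on the dendritic tree
either clustered inside a 50 um sphere ("localized") or uniformly over the
tree ("distributed"), driven by correlated or uncorrelated homogeneous
Poisson event trains, and somatic spike counts are read out from the cable
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import cable
from .cable import (
    CableModel,
    CompartmentGrid,
    MembraneParams,
    SynapticStimulus,
    VoltageTrace,
    detect_spikes,
    discretize,
    double_exp_norm,
)
from .morphology import Morphology
from .units import US_MV_TO_PA

__all__ = [
    "VariantScaling",
    "SynapseSpec",
    "InputEnsemble",
    "GLUA2_QR_VARIANTS",
    "BASELINE_VARIANT",
    "compute_scaling",
    "scaling_table",
    "synaptic_conductance",
    "synaptic_current",
    "place_localized",
    "place_distributed",
    "generate_trains",
    "run_variant_experiment",
    "calibrate_baseline_weight",
]

#: MD-averaged single-channel conductances (pS) of the GluA2 Q/R-site
#: variants used as the workflow's molecular input.  Q586E.0/1/2 denote the
#: glutamate mutant with 4, 3 and 2 ionized E586 side chains.
GLUA2_QR_VARIANTS: dict[str, float] = {
    "wild-type": 10.2,
    "Q586R": 3.3,
    "Q586G": 11.7,
    "Q586E.0": 92.4,
    "Q586E.1": 19.8,
    "Q586E.2": 19.8,
}
BASELINE_VARIANT = "Q586R"


@dataclass
class VariantScaling:
    """Dimensionless synaptic scaling factor for one receptor variant."""

    label: str
    g_md: float  # pS
    g_baseline: float  # pS

    def __post_init__(self) -> None:
        if self.g_md <= 0 or self.g_baseline <= 0:
            raise ValueError("conductances must be positive")

    @property
    def G(self) -> float:
        return self.g_md / self.g_baseline

    @property
    def G_reported(self) -> float:
        """One-decimal reporting view (half away from zero)."""
        return math.floor(self.G * 10 + 0.5) / 10

    @property
    def G_integer(self) -> int:
        """Coarse integer factor used for neuronal runs: nearest integer
        with ties rounded down, except the 28-fold factor which is taken
        as 30."""
        g1 = self.G_reported
        if abs(g1 - 28.0) < 1e-9:
            return 30
        return int(math.ceil(g1 - 0.5))


def compute_scaling(g_md: float, g_baseline: float, label: str = "") -> VariantScaling:
    """G = g_md / g_baseline (ratio of variant to baseline single-channel
    conductance)."""
    return VariantScaling(label=label, g_md=g_md, g_baseline=g_baseline)


def scaling_table(
    variants: dict[str, float] | None = None,
    baseline: str = BASELINE_VARIANT,
) -> dict[str, VariantScaling]:
    """Scaling factors for a whole variant table (label -> g_md in pS)."""
    variants = dict(variants) if variants is not None else dict(GLUA2_QR_VARIANTS)
    if baseline not in variants:
        raise ValueError(f"baseline variant {baseline!r} missing from table")
    g0 = variants[baseline]
    return {lab: compute_scaling(g, g0, lab) for lab, g in variants.items()}


@dataclass
class SynapseSpec:
    """Location, kinetics and scaled strength of one synapse."""

    compartment: int
    weight: float  # uS, peak conductance of one unscaled event
    tau_rise: float = 0.2
    tau_decay: float = 1.7
    e_rev: float = 0.0
    scaling: VariantScaling | None = None

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def G(self) -> float:
        return self.scaling.G if self.scaling is not None else 1.0


def synaptic_conductance(spec: SynapseSpec, events_ms, t) -> np.ndarray | float:
    """g(t) = G * weight * N * sum_{e <= t} (exp(-(t-e)/tau_d) -
    exp(-(t-e)/tau_r)), with N normalising a single event's peak to 1, so a
    lone event peaks at exactly G * weight."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    events = np.asarray(events_ms, dtype=float)
    norm = double_exp_norm(spec.tau_rise, spec.tau_decay)
    dt = t_arr[:, None] - events[None, :]
    active = dt >= 0
    with np.errstate(over="ignore"):
        prof = np.where(
            active,
            np.exp(-dt / spec.tau_decay) - np.exp(-dt / spec.tau_rise),
            0.0,
        )
    g = spec.G * spec.weight * norm * prof.sum(axis=1)
    g = np.maximum(g, 0.0)
    return g if np.ndim(t) else float(g[0])


def synaptic_current(g_uS: float, v_mv: float, e_rev_mv: float = 0.0) -> float:
    """I_syn = g * (V_m - E) in pA; negative (inward) for V_m < E = 0,
    i.e. depolarising."""
    if np.any(np.asarray(g_uS) < 0):
        raise ValueError("conductance must be >= 0")
    return g_uS * (v_mv - e_rev_mv) * US_MV_TO_PA


@dataclass
class InputEnsemble:
    trains: list[np.ndarray]  # event times per synapse, ms
    rate: float
    correlated: bool
    duration: float
    seed: int


def generate_trains(
    rate: float,
    duration: float,
    n: int,
    correlated: bool,
    seed: int,
) -> InputEnsemble:
    """Homogeneous Poisson event trains at ``rate`` Hz over ``duration``
    ms; correlated input shares one identical train across all synapses."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    mean_count = rate * duration / 1000.0

    def one() -> np.ndarray:
        k = rng.poisson(mean_count)
        return np.sort(rng.uniform(0.0, duration, size=k))

    if correlated:
        shared = one()
        trains = [shared.copy() for _ in range(n)]
    else:
        trains = [one() for _ in range(n)]
    return InputEnsemble(trains, rate, correlated, duration, seed)


# ---------------------------------------------------------------------------
# synapse placement on the discretised dendrite


def _dendrite_compartments(grid: CompartmentGrid) -> np.ndarray:
    comps = grid.compartments_in_region("dendrite")
    if len(comps) == 0:
        raise ValueError("morphology has no dendrite compartments")
    return comps


def place_localized(
    grid: CompartmentGrid,
    n: int = 10,
    radius: float = 50.0,
    seed: int = 0,
    max_attempts: int = 50,
) -> np.ndarray:
    """Pick a random dendritic compartment as the cluster centre, then
    sample ``n`` dendritic compartments (with replacement) whose midpoints
    lie within ``radius`` um of the centre midpoint.  Retries with a new
    centre when the sphere holds fewer than ``n`` candidates."""
    rng = np.random.default_rng(seed)
    dend = _dendrite_compartments(grid)
    needed = min(n, len(dend))  # small cells: allow repeated compartments
    for _ in range(max_attempts):
        center = rng.choice(dend)
        c_mid = grid.midpoint_um[center]
        dist = np.linalg.norm(grid.midpoint_um[dend] - c_mid, axis=1)
        candidates = dend[dist <= radius]
        if len(candidates) >= needed:
            return rng.choice(candidates, size=n, replace=len(candidates) < n)
    raise RuntimeError(
        f"could not find {n} dendritic compartments within {radius} um "
        f"after {max_attempts} centre draws"
    )


def place_distributed(grid: CompartmentGrid, n: int = 10, seed: int = 0) -> np.ndarray:
    """Uniform choice of ``n`` dendritic compartments (with replacement)."""
    rng = np.random.default_rng(seed)
    dend = _dendrite_compartments(grid)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(dend, size=n, replace=True)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class ExperimentConfig:
    """Knobs of one spike-count experiment; defaults follow the study
    protocol (10 synapses at 10 Hz, fast AMPA-like kinetics, E = 0 mV)."""

    n_synapses: int = 10
    rate: float = 10.0
    radius: float = 50.0
    tau_rise: float = 0.2
    tau_decay: float = 1.7
    e_rev: float = 0.0
    dt: float = 0.025
    max_len: float = 20.0
    threshold: float = -20.0
    min_isi: float = 2.0
    record_extra: tuple = ()


def _experiment_components(morph, placement, cfg, seed, correlated, duration):
    grid = discretize(morph, cfg.max_len)
    ss = np.random.SeedSequence(seed)
    place_seed, train_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    if placement == "localized":
        comps = place_localized(grid, cfg.n_synapses, cfg.radius, place_seed)
    elif placement == "distributed":
        comps = place_distributed(grid, cfg.n_synapses, place_seed)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    ensemble = generate_trains(
        cfg.rate, duration, cfg.n_synapses, correlated, train_seed
    )
    return grid, comps, ensemble


def run_variant_experiment(
    morph: Morphology,
    params: MembraneParams,
    scaling: VariantScaling | float,
    placement: str,
    correlated: bool,
    weight: float,
    duration: float,
    seed: int,
    cfg: ExperimentConfig | None = None,
) -> tuple[VoltageTrace, int]:
    """Compose placement, Poisson trains, scaled synapses and the cable
    solver; returns the somatic trace (spike times attached) and the spike
    count.  Fully reproducible for a fixed seed."""
    cfg = cfg or ExperimentConfig()
    G = scaling.G if isinstance(scaling, VariantScaling) else float(scaling)
    grid, comps, ensemble = _experiment_components(
        morph, placement, cfg, seed, correlated, duration
    )
    stimuli = [
        SynapticStimulus(
            compartment=int(c),
            weight_uS=G * weight,
            tau_rise=cfg.tau_rise,
            tau_decay=cfg.tau_decay,
            e_rev=cfg.e_rev,
            events_ms=tr,
        )
        for c, tr in zip(comps, ensemble.trains)
    ]
    record = [0, *cfg.record_extra]
    trace = cable.run(grid, params, stimuli, duration, cfg.dt, record=record)
    spikes = detect_spikes(trace, cfg.threshold, cfg.min_isi)
    trace.spike_times = spikes
    return trace, len(spikes)


class CalibrationError(RuntimeError):
    pass


def calibrate_baseline_weight(
    morph: Morphology,
    params: MembraneParams,
    duration: float,
    seed: int,
    G_probe: float = 30.0,
    placement: str = "distributed",
    w_lo: float = 1e-6,
    w_hi: float = 1.0,
    tol: float = 0.05,
    cfg: ExperimentConfig | None = None,
) -> float:
    """Bisection for the largest synaptic weight (to ``tol`` relative) at
    which baseline input (G = 1, uncorrelated) elicits no spikes, verified
    to elicit at least one spike when scaled by ``G_probe``.  This is the
    "threshold baseline" that makes gain-of-function variants visible."""
    if G_probe <= 1:
        raise ValueError("G_probe must exceed 1")

    def spikes_at(w: float, G: float) -> int:
        _, count = run_variant_experiment(
            morph, params, G, placement, False, w, duration, seed, cfg
        )
        return count

    if spikes_at(w_lo, 1.0) > 0:
        raise CalibrationError(
            f"baseline already spikes at the lower bracket w = {w_lo} uS"
        )
    if spikes_at(w_hi, 1.0) == 0:
        raise CalibrationError(
            f"baseline never spikes up to the upper bracket w = {w_hi} uS; "
            "cannot locate the firing threshold"
        )
    lo, hi = w_lo, w_hi
    while (hi - lo) / lo > tol:
        mid = math.sqrt(lo * hi)  # geometric bisection over decades
        if spikes_at(mid, 1.0) == 0:
            lo = mid
        else:
            hi = mid
    if spikes_at(lo, G_probe) < 1:
        raise CalibrationError(
            f"calibrated weight {lo:.3g} uS does not spike at G = {G_probe}; "
            "morphology or parameters leave no gain-of-function window"
        )
    return lo
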