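"""Lattice Monte Carlo: construction bookkeeping, Hamiltonian correctness
against a brute-force oracle, move invariants and equilibrium limits."""

import numpy as np
import pytest

from ionspike import lattice
from ionspike.lattice import (
    K,
    NA,
    GatingParams,
    build_patch,
    count_open,
    eps_for_vhalf,
    mc_sweep,
    patch_current,
    run_sweeps,
    total_energy,
)
from ionspike.units import F_V

# --------------------------------------------------------------------------
# independent brute-force Hamiltonian (test-side reference implementation)

_DIRS = [(1, 0), (0, 1), (-1, 0), (0, -1)]


def brute_force_energy(patch, params: GatingParams) -> float:
    """Naive sum over every nearest-neighbour pair and every sensor,
    written directly from the model definition."""
    L = patch.side_length
    e = 0.0
    for i in range(L):
        for j in range(L):
            for d in (0, 1):  # +row and +col: each unordered pair once
                di, dj = _DIRS[d]
                ni, nj = (i + di) % L, (j + dj) % L
                e += _bond(patch, params, i, j, ni, nj, d)
    for c in range(patch.n_channels):
        sel = patch.ch_sel[c]
        per = params.eps_g[sel] - params.q_gate[sel] * params.v_m_mv * F_V
        for s in range(4):
            if patch.ch_sensors[c, s]:
                e += per
        for s in range(4):
            e += (
                params.j_sensor_sensor
                * patch.ch_sensors[c, s]
                * patch.ch_sensors[c, (s + 1) % 4]
            )
    return e


def _bond(patch, params, i, j, ni, nj, d):
    a, b = patch.occ[i, j], patch.occ[ni, nj]
    a_ch, b_ch = a >= 2, b >= 2
    if not a_ch and not b_ch:
        return params.j_lipid[a, b]
    if a_ch and b_ch:
        return 0.0
    if a_ch:
        c = a - 2
        s = (d - patch.ch_orient[c]) % 4
        return params.j_sensor_lipid[patch.ch_sensors[c, s], b]
    c = b - 2
    rd = (d + 2) % 4
    s = (rd - patch.ch_orient[c]) % 4
    return params.j_sensor_lipid[patch.ch_sensors[c, s], a]


ZERO_J = dict(j_lipid=np.zeros((2, 2)), j_sensor_lipid=np.zeros((2, 2)))


# --------------------------------------------------------------------------
# construction


def test_build_patch_counts_and_composition():
    empty = build_patch(20, 0, 0, 1.0, seed=1)
    assert empty.composition() == {
        "saturated": 0,
        "unsaturated": 400,
        "channels": 0,
    }
    p = build_patch(20, 5, 5, 0.5, seed=7)
    assert p.composition() == {
        "saturated": 195,
        "unsaturated": 195,
        "channels": 10,
    }
    assert np.all(p.ch_sensors == 0)
    assert list(p.ch_sel) == [NA] * 5 + [K] * 5


def test_build_patch_reproducible_and_errors():
    a = build_patch(12, 3, 4, 0.3, seed=9)
    b = build_patch(12, 3, 4, 0.3, seed=9)
    assert np.array_equal(a.occ, b.occ)
    assert np.array_equal(a.ch_orient, b.ch_orient)
    with pytest.raises(ValueError, match="capacity"):
        build_patch(2, 5, 0, 0.5, seed=0)
    with pytest.raises(ValueError):
        build_patch(10, 1, 1, 1.5, seed=0)


def test_gating_params_validation():
    with pytest.raises(ValueError, match="symmetric"):
        GatingParams(j_lipid=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="move_mix"):
        GatingParams(move_mix=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        GatingParams(temperature_c=-400.0)


# --------------------------------------------------------------------------
# Hamiltonian


def test_total_energy_trivial_limits():
    p = build_patch(6, 1, 0, 0.5, seed=2)
    params = GatingParams(**ZERO_J)
    assert total_energy(p, params) == pytest.approx(0.0)  # all resting, J = 0
    p.ch_sensors[0, :] = 1
    params0 = GatingParams(v_m_mv=0.0, **ZERO_J)
    assert total_energy(p, params0) == pytest.approx(4 * params0.eps_g[NA])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_total_energy_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = build_patch(6, 2, 2, 0.4, seed=seed)
    p.ch_sensors[:] = rng.integers(0, 2, size=p.ch_sensors.shape)
    params = GatingParams(j_sensor_sensor=0.2, v_m_mv=-50.0)
    assert total_energy(p, params) == pytest.approx(
        brute_force_energy(p, params), rel=1e-12
    )


# --------------------------------------------------------------------------
# open-channel counting and current


def test_count_open_strict_all_four_rule():
    p = build_patch(8, 2, 1, 0.5, seed=3)
    assert count_open(p) == (0, 0)
    p.ch_sensors[0, :] = 1  # Na channel fully activated
    p.ch_sensors[1, :] = [1, 1, 1, 0]  # one sensor resting
    assert count_open(p) == (1, 0)
    p.ch_sensors[2, :] = 1  # the K channel
    assert count_open(p) == (1, 1)


def test_count_open_matches_registry_scan():
    rng = np.random.default_rng(5)
    p = build_patch(10, 6, 7, 0.5, seed=5)
    p.ch_sensors[:] = rng.integers(0, 2, size=p.ch_sensors.shape)
    n_na = sum(
        1
        for c in range(p.n_channels)
        if p.ch_sel[c] == NA and all(p.ch_sensors[c])
    )
    n_k = sum(
        1
        for c in range(p.n_channels)
        if p.ch_sel[c] == K and all(p.ch_sensors[c])
    )
    assert count_open(p) == (n_na, n_k)


def test_patch_current_hand_arithmetic():
    p = build_patch(6, 1, 0, 0.5, seed=1)
    params = GatingParams(v_m_mv=-65.0)
    assert patch_current(p, params) == 0.0  # nothing open
    p.ch_sensors[0, :] = 1
    # 1 open Na channel, 20 pS, driving force -115 mV -> -2.3 pA
    assert patch_current(p, params) == pytest.approx(-2.3)
    at_rev = GatingParams(v_m_mv=50.0)  # at E_Na with only Na open
    assert patch_current(p, at_rev) == pytest.approx(0.0)


# --------------------------------------------------------------------------
# dynamics invariants


def test_sweeps_conserve_composition_and_energy_bookkeeping():
    p = build_patch(12, 4, 4, 0.5, seed=11)
    params = GatingParams(v_m_mv=-40.0, j_sensor_sensor=0.1)
    before = p.composition()
    trace = run_sweeps(p, params, 500)
    assert p.composition() == before
    p.validate()  # registry still consistent with the grid
    recomputed = total_energy(p, params)
    assert trace.final_energy == pytest.approx(recomputed, rel=1e-8)
    assert trace.final_energy == pytest.approx(
        brute_force_energy(p, params), rel=1e-8
    )


def test_sweep_determinism_per_seed():
    params = GatingParams()
    runs = []
    for _ in range(2):
        p = build_patch(10, 3, 3, 0.5, seed=21)
        tr = run_sweeps(p, params, 200)
        runs.append((tr.observables, p.occ.copy(), p.ch_sensors.copy()))
    assert runs[0][0].equals(runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])
    assert np.array_equal(runs[0][2], runs[1][2])


def test_zero_energy_moves_are_accepted():
    """With all couplings and fields zero every proposal has dH = 0 and is
    always accepted, so sensors randomise away from the all-resting start."""
    p = build_patch(5, 2, 0, 0.5, seed=4)
    params = GatingParams(
        eps_g=(0.0, 0.0), v_m_mv=0.0, move_mix=(1.0, 0, 0, 0), **ZERO_J
    )
    run_sweeps(p, params, 50)
    assert p.ch_sensors.sum() > 0


def test_mc_sweep_returns_observables():
    p = build_patch(8, 2, 2, 0.5, seed=6)
    obs = mc_sweep(p, GatingParams())
    assert obs.sweep_index == 0
    assert 0 <= obs.n_open_na <= 2 and 0 <= obs.n_open_k <= 2


def test_sensor_activation_matches_two_state_boltzmann():
    """Zero-coupling limit: activation frequency follows the two-state
    sigmoid 1/(1 + exp((eps - q V F)/kT)); checked at the half-activation
    voltage and one flank."""
    q = 1.5
    for v_m, n_sweeps in [(-45.0, 6000), (-30.0, 6000)]:
        params = GatingParams(
            eps_g=(eps_for_vhalf(q, -45.0),) * 2,
            q_gate=(q, q),
            v_m_mv=v_m,
            move_mix=(1.0, 0, 0, 0),
            **ZERO_J,
        )
        p = build_patch(6, 6, 0, 0.5, seed=31)
        tr = run_sweeps(p, params, n_sweeps)
        burn = n_sweeps // 3
        # per-sweep total activated sensors out of 4 * n_channels
        act = tr.n_sensors_active[burn:] / (4 * p.n_channels)
        batches = np.array_split(act, 30)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / np.sqrt(len(means))
        x = (params.eps_g[0] - q * v_m * F_V) * params.beta
        expected = 1.0 / (1.0 + np.exp(x))
        assert abs(act.mean() - expected) < 3 * se + 1e-3


def test_open_fraction_monotone_in_voltage():
    """With J = 0 the mean open-channel count is non-decreasing in V_m."""
    means = []
    for v in [-80.0, -55.0, -30.0, -5.0]:
        params = GatingParams(v_m_mv=v, move_mix=(1.0, 0, 0, 0), **ZERO_J)
        p = build_patch(6, 0, 8, 0.5, seed=17)
        tr = run_sweeps(p, params, 4000)
        means.append(tr.observables["n_open_k"][1000:].mean())
    assert all(b >= a - 0.3 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]
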