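"""Hindmarsh-Rose simulation and ISI extraction."""

import numpy as np
import pytest

from chaossensor import (
    HRParams, SpikeTimes, Trajectory,
    bifurcation_scan, detect_spike_peaks, generate_isi_series,
    hr_derivatives, isi_from_spike_times, simulate_trajectory,
)
from chaossensor.characteristics import CHAOTIC_R, REGULAR_R


@pytest.mark.parametrize(
    "state, r, i_ex, expected",
    [
        ((0, 0, 0), 0.01, 3.25, (3.25, 1.0, 0.064)),
        ((1, 0, 0), 0.01, 0.0, (2.0, -4.0, 0.104)),
        ((-1.6, 0.7, 0), 0.02, 3.25, None),  # third component must vanish
    ],
)
def test_derivatives_closed_form(state, r, i_ex, expected):
    got = hr_derivatives(state, HRParams(r=r, i_ex=i_ex))
    if expected is None:
        assert got[2] == pytest.approx(0.0, abs=1e-15)
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_derivatives_match_independent_formula():
    """The RHS agrees with a formula written out independently at random states."""
    rng = np.random.default_rng(0)
    p = HRParams(r=0.0123, i_ex=3.31)
    for _ in range(100):
        x, y, z = rng.uniform(-2, 2, 3)
        ref = (
            y + 3 * x**2 - x**3 - z + p.i_ex,
            1 - 5 * x**2 - y,
            p.r * (4 * (x + 8 / 5) - z),
        )
        assert hr_derivatives((x, y, z), p) == pytest.approx(ref, abs=1e-10)


def test_derivatives_reject_nonfinite():
    with pytest.raises(ValueError):
        hr_derivatives((np.nan, 0, 0), HRParams())


def test_integrator_consistent_with_derivatives():
    """One small RK4 step reproduces the first-order Taylor expansion."""
    p = HRParams(r=0.0055, dt=1e-6)
    traj = simulate_trajectory(p, 10 * p.dt)
    step = (traj.states[1] - traj.states[0]) / p.dt
    deriv = np.array(hr_derivatives(traj.states[0], p))
    assert np.allclose(step, deriv, atol=1e-5)


def test_sustained_spiking_at_reference_parameters():
    """r=0.0055, I_ex=3.25 gives repetitive spiking well above baseline."""
    traj = simulate_trajectory(HRParams(r=0.0055, i_ex=3.25), 3000.0)
    spikes = detect_spike_peaks(traj)
    assert len(spikes) > 50
    assert traj.x.max() > 1.5
    # spike peaks clearly exceed the inter-spike baseline
    assert traj.x.max() - np.median(traj.x) > 1.0


def test_simulation_deterministic():
    p = HRParams(r=0.0055)
    a = simulate_trajectory(p, 500.0)
    b = simulate_trajectory(p, 500.0)
    assert np.array_equal(a.states, b.states)


def test_step_refinement_stability():
    """Halving the step changes each early ISI by < 1%.

    Exponential divergence of the chaotic orbit at r=0.0055 limits how
    far step-refinement agreement can reach (any solver tolerance is
    amplified to O(1) within a few tens of intervals), so only the first
    intervals are compared.
    """
    coarse = generate_isi_series(HRParams(r=0.0055, dt=0.01), 15)
    fine = generate_isi_series(HRParams(r=0.0055, dt=0.005), 15)
    rel = np.abs(coarse.values - fine.values) / fine.values
    assert rel.max() < 0.01


def test_early_isis_match_adaptive_reference_solver():
    """The fixed-step integrator agrees with an independent adaptive
    RK45 run at tight tolerance on the first intervals."""
    from scipy.integrate import solve_ivp
    from scipy.signal import find_peaks

    def rhs(t, s, iex, r):
        x, y, z = s
        return (y + 3 * x * x - x**3 - z + iex,
                1 - 5 * x * x - y,
                r * (4 * (x + 1.6) - z))

    sol = solve_ivp(rhs, (0, 1300), (0, 0, 0), args=(3.25, 0.0055),
                    method="RK45", rtol=1e-9, atol=1e-11, max_step=0.05,
                    t_eval=np.arange(0, 1300, 0.01))
    peaks, _ = find_peaks(sol.y[0], height=1.0, distance=500)
    reference = np.diff(sol.t[peaks])[20:35]
    mine = generate_isi_series(HRParams(r=0.0055), 15).values
    assert np.abs(mine - reference).max() / reference.min() < 0.01


def test_detect_peaks_on_sine():
    t = np.linspace(0, 4 * np.pi, 4001)
    x = np.sin(t)
    traj = Trajectory(t, np.column_stack([x, x, x]))
    spikes = detect_spike_peaks(traj, threshold=0.5, min_separation=1.0)
    assert len(spikes) == 2
    assert spikes.peak_times == pytest.approx(
        [np.pi / 2, np.pi / 2 + 2 * np.pi], abs=1e-3)


def test_detect_peaks_constant_trace():
    t = np.linspace(0, 10, 101)
    traj = Trajectory(t, np.ones((101, 3)))
    assert len(detect_spike_peaks(traj)) == 0


def test_isi_differences_and_errors():
    assert np.array_equal(
        isi_from_spike_times(SpikeTimes(np.array([1.0, 3, 6, 10]))).values,
        [2.0, 3.0, 4.0],
    )
    with pytest.raises(ValueError, match="insufficient spikes"):
        isi_from_spike_times(SpikeTimes(np.array([5.0])))
    with pytest.raises(ValueError):
        SpikeTimes(np.array([3.0, 2.0]))


def test_generate_isi_contract_and_determinism():
    p = HRParams(r=0.0055, i_ex=3.25)
    a = generate_isi_series(p, 500)
    assert len(a) == 500
    assert np.all(a.values > 0)
    b = generate_isi_series(p, 500)
    assert np.array_equal(a.values, b.values)
    assert (a.r, a.i_ex) == (0.0055, 3.25)


def _cycle_dispersion(values, max_lag=8):
    """Dispersion after removing periodic structure: the minimum over
    small lags of the lag-difference standard deviation.  A period-p
    burst pattern (e.g. the perfect 3-cycle at r=0.0105) scores ~0 even
    though its raw ISI std is large; chaotic series stay large at every
    lag."""
    return min(np.std(values[lag:] - values[:-lag])
               for lag in range(1, max_lag + 1))


def test_regular_vs_chaotic_dispersion():
    """Periodicity-removed ISI dispersion at a chaotic r dwarfs a
    regular (period-3 bursting) r."""
    chaotic = generate_isi_series(HRParams(r=0.0141), 500)
    regular = generate_isi_series(HRParams(r=0.0105), 500)
    assert _cycle_dispersion(chaotic.values) > 5 * _cycle_dispersion(regular.values)


def test_regime_ordering_over_reference_series():
    """Mean periodicity-removed dispersion over the chaotic r values
    exceeds the regular ones."""
    chaos = np.mean([
        _cycle_dispersion(generate_isi_series(HRParams(r=r), 500).values)
        for r in CHAOTIC_R])
    order = np.mean([
        _cycle_dispersion(generate_isi_series(HRParams(r=r), 500).values)
        for r in REGULAR_R])
    assert chaos > order


def test_bifurcation_scan_structure():
    grid = [0.0055, 0.0105, 0.0141]
    scan = bifurcation_scan(grid, 3.25, n_isi=200)
    assert [r for r, _ in scan] == grid
    for _, series in scan:
        assert np.all(series.values > 0)
    # rerun is byte-identical
    again = bifurcation_scan(grid, 3.25, n_isi=200)
    for (_, s1), (_, s2) in zip(scan, again):
        assert np.array_equal(s1.values, s2.values)


def test_bifurcation_scan_collects_failures():
    """A non-spiking grid point yields an exception entry, not an abort."""
    scan = bifurcation_scan([0.0055, 0.01], i_ex=0.0, n_isi=5)
    assert all(isinstance(s, Exception) for _, s in scan)


def test_mean_isi_near_reference_scale(base1):
    """Grid-averaged mean ISI lands near 32 time units (within 2%)."""
    assert base1.windows.mean() == pytest.approx(32.27, rel=0.02)
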