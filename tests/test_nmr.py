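import numpy as np
import pytest
from scipy.integrate import solve_ivp

from protoncage.nmr import (ExchangeSite, TwoSiteExchangeModel,
                            coalescence_rate, exsy_intensities,
                            fast_exchange_shift, fit_rate_from_exsy,
                            two_site_lineshape)


def _model(k_ex, p_a=0.5, r2=200.0, r1=0.0, da=13.2, db=12.2, field=800.0):
    return TwoSiteExchangeModel(
        ExchangeSite(da, p_a, r2=r2, r1=r1, label="A"),
        ExchangeSite(db, 1.0 - p_a, r2=r2, r1=r1, label="B"),
        k_ex=k_ex, field_mhz=field)


def _lorentzian(ppm, center_ppm, r2, field, weight=1.0):
    dw = 2 * np.pi * (ppm - center_ppm) * field
    return weight * r2 / (dw ** 2 + r2 ** 2)


# -- population-weighted shift ----------------------------------------------

def test_fast_exchange_shift_examples():
    a = ExchangeSite(13.2, 0.5)
    b = ExchangeSite(12.2, 0.5)
    assert fast_exchange_shift([a, b]) == pytest.approx(12.7)
    assert fast_exchange_shift([ExchangeSite(11.0, 1.0)]) == pytest.approx(11.0)
    a40 = ExchangeSite(13.2, 0.4)
    b60 = ExchangeSite(12.2, 0.6)
    assert fast_exchange_shift([a40, b60]) == pytest.approx(12.6)
    with pytest.raises(ValueError, match="sum"):
        fast_exchange_shift([ExchangeSite(1.0, 0.4), ExchangeSite(2.0, 0.4)])


# -- lineshape ---------------------------------------------------------------

def test_slow_limit_two_lorentzians():
    """k = 0 reduces exactly to two independent Lorentzians."""
    m = _model(0.0, p_a=0.3)
    grid = np.linspace(10.0, 15.0, 20001)
    spec = two_site_lineshape(m, grid)
    ref = (_lorentzian(grid, 13.2, 200.0, 800.0, 0.3)
           + _lorentzian(grid, 12.2, 200.0, 800.0, 0.7))
    np.testing.assert_allclose(spec.intensity, ref, rtol=1e-9, atol=1e-12)
    y = spec.intensity
    local_max = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    assert local_max.size == 2
    assert grid[local_max.min()] == pytest.approx(12.2, abs=5e-4)
    assert grid[local_max.max()] == pytest.approx(13.2, abs=5e-4)


def test_fast_limit_single_population_weighted_lorentzian():
    """k >> coalescence gives one Lorentzian at the weighted average shift."""
    m = _model(1e12)
    grid = np.linspace(10.0, 15.0, 20001)
    spec = two_site_lineshape(m, grid)
    ref = _lorentzian(grid, 12.7, 200.0, 800.0, 1.0)
    assert np.max(np.abs(spec.intensity - ref)) / ref.max() < 1e-6
    assert grid[np.argmax(spec.intensity)] == pytest.approx(
        fast_exchange_shift([m.site_a, m.site_b]), abs=3e-4)


def test_intermediate_k_matches_ode_oracle():
    """The closed-form spectrum equals direct integration of the coupled
    magnetization equations (rotating frame, Laplace integral)."""
    m = _model(2000.0, p_a=0.3)
    check_ppm = np.array([11.8, 12.2, 12.45, 12.7, 12.95, 13.2, 13.6])
    spec = two_site_lineshape(m, np.concatenate(([10.0, 15.0], check_ppm)))
    closed = spec.intensity[2:]
    a_mat = (np.diag(2j * np.pi * m.shifts_hz
                     - np.array([m.site_a.r2, m.site_b.r2]))
             - m.kinetic_matrix())
    p = m.populations
    oracle = []
    for ppm in check_ppm:
        w = 2j * np.pi * ppm * m.field_mhz

        def rhs(t, y):
            z = y[:2]
            return np.concatenate(((a_mat - w * np.eye(2)) @ z,
                                   [z[0] + z[1]]))

        sol = solve_ivp(rhs, (0.0, 0.12), np.array([p[0], p[1], 0.0],
                                                   dtype=complex),
                        rtol=1e-11, atol=1e-14, method="DOP853")
        oracle.append(float(np.real(sol.y[2, -1])))
    np.testing.assert_allclose(closed, np.asarray(oracle), rtol=1e-6)


def test_lineshape_integral_invariant_under_exchange():
    """Total absorption is conserved when the exchange rate changes."""
    center = 12.7
    dense = np.linspace(center - 5.0, center + 5.0, 1_600_001)
    offsets = np.geomspace(5.0, 25000.0, 4000)
    grid_ppm = np.unique(np.concatenate([center - offsets, dense,
                                         center + offsets]))
    integrals = []
    for k in (0.0, 2000.0, 1e7):
        spec = two_site_lineshape(_model(k), grid_ppm)
        integrals.append(np.trapezoid(spec.intensity, spec.freq_hz))
    assert integrals[1] == pytest.approx(integrals[0], rel=1e-6)
    assert integrals[2] == pytest.approx(integrals[0], rel=1e-6)


def test_grid_must_span_shifts():
    with pytest.raises(ValueError, match="span"):
        two_site_lineshape(_model(0.0), np.linspace(0.0, 5.0, 100))


# -- coalescence -------------------------------------------------------------

def test_coalescence_rate_arithmetic():
    """1 ppm at 800 MHz: dnu = 800 Hz, k_c = pi 800 / sqrt(2) = 1.78e3 /s."""
    kc = coalescence_rate(1.0, 800.0)
    assert kc == pytest.approx(np.pi * 800.0 / np.sqrt(2.0), rel=1e-12)
    assert kc == pytest.approx(1.777e3, rel=1e-3)
    assert coalescence_rate(1.0, 1600.0) == pytest.approx(2 * kc, rel=1e-12)
    with pytest.raises(ValueError):
        coalescence_rate(-1.0, 800.0)


def test_coalescence_bracketing_by_lineshape():
    """Spectra are bimodal at half the coalescence jump rate, unimodal at twice."""
    kc = coalescence_rate(1.0, 800.0)       # per-direction jump rate
    grid = np.linspace(11.2, 14.2, 60001)

    def n_maxima(k_jump):
        spec = two_site_lineshape(_model(2.0 * k_jump, r2=1.0), grid)
        y = spec.intensity
        return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])))

    assert n_maxima(0.5 * kc) == 2
    assert n_maxima(2.0 * kc) == 1


# -- EXSY --------------------------------------------------------------------

def test_exsy_zero_mixing_time():
    peaks = exsy_intensities(_model(5000.0, p_a=0.3), 0.0)
    np.testing.assert_allclose(peaks.cross, [0.0, 0.0], atol=1e-15)
    np.testing.assert_allclose(peaks.diag, [0.3, 0.7], atol=1e-15)


def test_exsy_conservation_without_relaxation():
    """With R1 = 0 total z-magnetization is conserved to <= 1e-12."""
    for k in (0.0, 10.0, 1e4, 1e9):
        for tau in (0.0, 1e-4, 0.01, 10.0):
            peaks = exsy_intensities(_model(k, p_a=0.3), tau)
            assert abs(peaks.intensities.sum() - 1.0) <= 1e-12


def test_exsy_long_mixing_equilibrium():
    """k_ex tau >> 1 with R1 = 0 drives every entry to p_i p_j."""
    p_a = 0.3
    peaks = exsy_intensities(_model(1e5, p_a=p_a), 1.0)
    expected = np.outer([p_a, 1 - p_a], [p_a, 1 - p_a])
    np.testing.assert_allclose(peaks.intensities, expected, atol=1e-12)


def test_exsy_matches_numerical_integration():
    m = _model(300.0, p_a=0.25, r1=2.0)
    tau = 0.01
    kmat = m.kinetic_matrix() + np.diag([2.0, 2.0])

    def rhs(t, y):
        return -kmat @ y

    expected = np.empty((2, 2))
    for j, e in enumerate(np.eye(2)):
        sol = solve_ivp(rhs, (0, tau), e, rtol=1e-12, atol=1e-14)
        expected[:, j] = sol.y[:, -1] * m.populations[j]
    peaks = exsy_intensities(m, tau)
    np.testing.assert_allclose(peaks.intensities, expected, rtol=1e-8)


def test_exsy_detailed_balance_symmetry():
    """Detailed balance with equal R1 makes the cross peaks equal."""
    for tau in (1e-4, 0.01, 0.1):
        peaks = exsy_intensities(_model(1000.0, p_a=0.3, r1=1.5), tau)
        assert peaks.intensities[0, 1] == pytest.approx(
            peaks.intensities[1, 0], rel=1e-12)


def test_fit_rate_round_trip():
    """Forward model -> ratio -> inverse recovers k_ex to <= 1e-6 relative."""
    for k_true in (50.0, 200.0, 500.0):
        m = _model(k_true, p_a=0.3, r1=3.0)
        inten = exsy_intensities(m, 0.01).intensities
        ratio = inten[0, 1] / inten[0, 0]
        k_fit, saturated = fit_rate_from_exsy(ratio, (0.3, 0.7), 0.01, r1=3.0)
        assert not saturated
        assert k_fit == pytest.approx(k_true, rel=1e-6)


def test_fit_rate_edge_cases():
    k, sat = fit_rate_from_exsy(0.0, (0.5, 0.5), 0.01)
    assert k == 0.0 and not sat
    # ratio beyond the p_B/p_A maximum -> saturation flag, no exception
    k, sat = fit_rate_from_exsy(10.0, (0.5, 0.5), 0.01)
    assert sat and np.isnan(k)
    with pytest.raises(ValueError):
        fit_rate_from_exsy(-0.1, (0.5, 0.5), 0.01)


def test_fast_proton_transfer_is_deep_fast_exchange():
    """A 1 ps residence time (k ~ 1e12 /s) exceeds the ppm-scale coalescence
    rate at 800-900 MHz by >= 6 orders of magnitude."""
    k_transfer = 1.0 / 1e-12
    for field in (800.0, 900.0):
        for delta_ppm in (0.5, 1.0, 2.0):
            assert k_transfer / coalescence_rate(delta_ppm, field) >= 1e6


def test_model_invariants():
    with pytest.raises(ValueError, match="sum"):
        TwoSiteExchangeModel(ExchangeSite(1.0, 0.6), ExchangeSite(2.0, 0.6),
                             k_ex=10.0)
    m = _model(1000.0, p_a=0.3)
    # detailed balance by construction
    assert m.site_a.population * m.k_ab == pytest.approx(
        m.site_b.population * m.k_ba)
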