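"""Two-site chemical-exchange forward models.

Implements the standard Bloch--McConnell description of two exchanging
proton sites A and B with chemical shifts delta_A, delta_B (ppm),
populations p_A + p_B = 1, per-direction jump rates k_AB, k_BA (s^-1,
detailed balance p_A k_AB = p_B k_BA) and relaxation rates R1/R2:

* 1D absorption lineshape, interpolating between two Lorentzians (slow
  exchange) and a single population-averaged Lorentzian (fast exchange),
  with coalescence in between;
* z-exchange (EXSY) diagonal/cross-peak intensities at a mixing time,
  I(tau_m) = exp(-(K + R1) tau_m) diag(p) -- diagonal peaks report
  populations, cross peaks additionally the exchange kinetics;
* the inverse problem of recovering the exchange rate from a measured
  cross/diagonal intensity ratio.

Conventions: ``coalescence_rate`` returns the per-direction jump rate of
the symmetric (equal-population) two-site problem, k_c = pi dnu / sqrt(2);
EXSY formulas use the total exchange rate k_ex = k_AB + k_BA.  The default
water proton shift, used when modelling exchange with water, is 4.8 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ExchangeSite", "TwoSiteExchangeModel", "Spectrum1D", "PeakMatrix",
    "fast_exchange_shift", "two_site_lineshape", "coalescence_rate",
    "exsy_intensities", "fit_rate_from_exsy", "WATER_SHIFT_PPM",
]

#: default water 1H chemical shift (ppm) for exchange-with-water models
WATER_SHIFT_PPM = 4.8


@dataclass(frozen=True)
class ExchangeSite:
    """One exchanging proton site."""

    shift_ppm: float
    population: float
    r2: float = 0.0          # transverse relaxation, s^-1
    r1: float = 0.0          # longitudinal relaxation, s^-1
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise ValueError("population must lie in [0, 1]")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("relaxation rates must be non-negative")


@dataclass(frozen=True)
class TwoSiteExchangeModel:
    """Two exchanging sites with detailed-balance jump rates.

    Constructed from the total exchange rate ``k_ex`` (s^-1); the
    per-direction rates k_AB = p_B k_ex and k_BA = p_A k_ex then satisfy
    detailed balance p_A k_AB = p_B k_BA by construction.
    """

    site_a: ExchangeSite
    site_b: ExchangeSite
    k_ex: float                      # total exchange rate k_AB + k_BA, s^-1
    field_mhz: float = 800.0         # 1H spectrometer frequency

    def __post_init__(self) -> None:
        psum = self.site_a.population + self.site_b.population
        if abs(psum - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {psum}")
        if self.k_ex < 0 or self.field_mhz <= 0:
            raise ValueError("k_ex must be >= 0 and field > 0")

    @property
    def k_ab(self) -> float:
        """A -> B jump rate, s^-1."""
        return self.site_b.population * self.k_ex

    @property
    def k_ba(self) -> float:
        """B -> A jump rate, s^-1."""
        return self.site_a.population * self.k_ex

    @property
    def populations(self) -> np.ndarray:
        return np.array([self.site_a.population, self.site_b.population])

    @property
    def shifts_hz(self) -> np.ndarray:
        return np.array([self.site_a.shift_ppm, self.site_b.shift_ppm]) \
            * self.field_mhz

    def kinetic_matrix(self) -> np.ndarray:
        """K with off-diagonal -k rates and zero column sums (dM/dt = -K M)."""
        return np.array([[self.k_ab, -self.k_ba],
                         [-self.k_ab, self.k_ba]])


@dataclass
class Spectrum1D:
    """Absorption-mode 1D spectrum."""

    freq_hz: np.ndarray
    ppm: np.ndarray
    intensity: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class PeakMatrix:
    """EXSY peak intensities at one mixing time: [[AA, AB], [BA, BB]].

    Entry (i, j) is the intensity of magnetization that started on site j
    and is detected on site i.
    """

    intensities: np.ndarray          # 2x2
    tau_m: float                     # s

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.intensities)

    @property
    def cross(self) -> tuple[float, float]:
        """(I_AB, I_BA)."""
        return float(self.intensities[0, 1]), float(self.intensities[1, 0])


def fast_exchange_shift(sites) -> float:
    """Population-weighted average shift (ppm) in the fast-exchange limit."""
    p = np.array([s.population for s in sites])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"populations must sum to 1, got {p.sum()}")
    d = np.array([s.shift_ppm for s in sites])
    return float(p @ d)


def two_site_lineshape(model: TwoSiteExchangeModel, ppm_grid) -> Spectrum1D:
    """Absorption lineshape of the two-site exchange problem.

    The FID is s(t) = 1^T exp(A t) p with the complex evolution matrix
    A = diag(i 2 pi nu_j - R2_j) - K; the spectrum is the real part of its
    Laplace transform, Re[1^T (i omega I - A)^{-1} p], evaluated in closed
    form for the 2x2 problem.
    """
    ppm_grid = np.asarray(ppm_grid, float)
    lo, hi = ppm_grid.min(), ppm_grid.max()
    d = sorted([model.site_a.shift_ppm, model.site_b.shift_ppm])
    if lo > d[0] or hi < d[1]:
        raise ValueError("frequency grid must span both chemical shifts")
    nu = model.shifts_hz
    r2 = np.array([model.site_a.r2, model.site_b.r2])
    p = model.populations
    a_mat = np.diag(2j * np.pi * nu - r2) - model.kinetic_matrix()
    omega = 2.0 * np.pi * ppm_grid * model.field_mhz
    # closed-form inverse of (i omega I - A), vectorised over omega
    m11 = 1j * omega - a_mat[0, 0]
    m22 = 1j * omega - a_mat[1, 1]
    m12 = -a_mat[0, 1]
    m21 = -a_mat[1, 0]
    det = m11 * m22 - m12 * m21
    v0 = (m22 * p[0] - m12 * p[1]) / det
    v1 = (-m21 * p[0] + m11 * p[1]) / det
    intensity = np.real(v0 + v1)
    return Spectrum1D(
        freq_hz=ppm_grid * model.field_mhz, ppm=ppm_grid, intensity=intensity,
        provenance={"model": {"shifts_ppm": [model.site_a.shift_ppm,
                                             model.site_b.shift_ppm],
                              "populations": p.tolist(), "k_ex": model.k_ex,
                              "r2": r2.tolist(),
                              "field_mhz": model.field_mhz}},
    )


def coalescence_rate(delta_ppm: float, field_mhz: float) -> float:
    """Coalescence jump rate k_c = pi dnu / sqrt(2) (s^-1).

    For the symmetric equal-population two-site problem with shift
    difference ``delta_ppm`` at the given 1H frequency; returns the
    per-direction jump rate (= half the total exchange rate at
    coalescence).
    """
    if delta_ppm <= 0 or field_mhz <= 0:
        raise ValueError("shift difference and field must be positive")
    dnu_hz = delta_ppm * field_mhz
    return float(np.pi * dnu_hz / np.sqrt(2.0))


def _propagator(model: TwoSiteExchangeModel, tau_m: float) -> np.ndarray:
    """exp(-(K + R1) tau_m), exact for the 2x2 problem via eigenprojectors.

    K + R1 has real eigenvalues lam1 <= lam2 (both >= 0), so
    exp(-M tau) = e^{-lam1 tau} P1 + e^{-lam2 tau} P2 is overflow-free for
    arbitrarily fast exchange.
    """
    r1 = np.diag([model.site_a.r1, model.site_b.r1])
    m = model.kinetic_matrix() + r1
    half_tr = np.trace(m) / 2.0
    det = float(np.linalg.det(m))
    disc = max(half_tr * half_tr - det, 0.0)
    d = np.sqrt(disc)
    lam1, lam2 = half_tr - d, half_tr + d
    if d * tau_m < 1e-12:
        # (near-)degenerate eigenvalues: first-order expansion
        return np.exp(-half_tr * tau_m) * (
            np.eye(2) + tau_m * (half_tr * np.eye(2) - m))
    p1 = (m - lam2 * np.eye(2)) / (lam1 - lam2)
    p2 = (m - lam1 * np.eye(2)) / (lam2 - lam1)
    return np.exp(-lam1 * tau_m) * p1 + np.exp(-lam2 * tau_m) * p2


def exsy_intensities(model: TwoSiteExchangeModel, tau_m: float) -> PeakMatrix:
    """EXSY peak matrix I(tau_m) = exp(-(K + R1) tau_m) diag(p).

    At tau_m = 0 the cross peaks vanish and the diagonals equal the
    populations; with R1 = 0 and k_ex tau_m >> 1 every entry tends to
    p_i p_j; with R1 = 0 the four entries sum to 1 for every tau_m.
    """
    if tau_m < 0:
        raise ValueError("mixing time must be non-negative")
    prop = _propagator(model, tau_m)
    return PeakMatrix(intensities=prop @ np.diag(model.populations),
                      tau_m=tau_m)


def fit_rate_from_exsy(cross_over_diag: float, populations, tau_m: float,
                       r1: float = 0.0,
                       k_max: float = 1e12) -> tuple[float, bool]:
    """Exchange rate k_ex reproducing a measured I_AB / I_AA ratio.

    Parameters
    ----------
    cross_over_diag : float
        Ratio of the cross peak (detected on A, originated on B) to the
        AA diagonal peak.
    populations : (p_A, p_B)
    tau_m : float
        Mixing time, s.
    r1 : float
        Common longitudinal relaxation rate (cancels in the ratio when
        equal on both sites).

    Returns
    -------
    (k_ex, saturated)
        ``saturated`` is True when the ratio exceeds the theoretical
        maximum p_B / p_A for the given populations; k_ex is then NaN.
    """
    if cross_over_diag < 0:
        raise ValueError("intensity ratio must be >= 0")
    p_a, p_b = populations
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("populations must lie strictly between 0 and 1")
    if tau_m <= 0:
        raise ValueError("mixing time must be positive")
    if cross_over_diag == 0:
        return 0.0, False

    def ratio(k: float) -> float:
        site_a = ExchangeSite(0.0, p_a, r1=r1)
        site_b = ExchangeSite(1.0, p_b, r1=r1)
        m = TwoSiteExchangeModel(site_a, site_b, k_ex=k)
        inten = exsy_intensities(m, tau_m).intensities
        return inten[0, 1] / inten[0, 0]

    if cross_over_diag >= ratio(k_max):
        return float("nan"), True
    k = brentq(lambda k: ratio(k) - cross_over_diag, 0.0, k_max,
               rtol=1e-12, maxiter=200)
    return float(k), False
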