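"""Analytic surrogate free-energy surface for the shared excess proton.

The two reaction coordinates are x = Ro_c_o_w, the distance between the
active carboxyl oxygen and the water oxygen, and q = Ro_c_h - Ro_w_h, the
proton asymmetry (q < 0: proton near the carboxyl oxygen; q > 0: near the
water oxygen).  The surface, in units of k_BT at the configured
temperature, is

    F(x, q) = 1/2 k_x (x - x0)^2  +  B(x) f(q / q0)  +  g(x) q

with f(u) = (u^2 - 1)^2 a unit-barrier symmetric quartic double well,
B(x) = B0 + c (x - x0) a linearly distance-coupled barrier, and
g(x) = s (x - x_c) a tilt that (for s < 0) lowers the water-side well at
large oxygen-oxygen separations.  This is the simplest form reproducing
the two regimes seen in the underlying model system: frequent
intermediate proton positions at short x (2.4-2.6 A) and water-side
localisation at large x.

The default ``barrier0`` and the Langevin friction default are calibrated
so that the q-projected forward (water-to-carboxyl) barrier is 3 k_BT and
the mean proton residence time is ~1 ps at 300 K; both constants can be
re-derived with ``scripts/calibrate_surrogate.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fes import FreeEnergyProfile, FreeEnergySurface, barrier_heights

__all__ = [
    "SurrogatePES",
    "analytic_fes",
    "analytic_profile",
    "analytic_forward_barrier",
    "calibrate_barrier0",
]

# threshold for the double-well invariant: the quartic + linear-tilt section
# B f(q/q0) + g q has two minima and one interior maximum iff
# |g| q0 / B < 8 / (3 sqrt(3))
DOUBLE_WELL_TILT_LIMIT = 8.0 / (3.0 * np.sqrt(3.0))


@dataclass(frozen=True)
class SurrogatePES:
    """Parameters of the analytic surrogate surface (energies in k_BT at `temperature`)."""

    x0: float = 2.5                 # reference O-O distance, A
    k_x: float = 40.0               # O-O stiffness, k_BT/A^2
    barrier0: float = 3.7120        # base barrier B0, k_BT; calibrated so the
                                    # q-projected forward barrier is 3.0 k_BT
                                    # (scripts/calibrate_surrogate.py)
    barrier_slope: float = 8.0      # barrier-distance coupling c, k_BT/A
    q0: float = 0.5                 # well position along q, A
    tilt: float = -2.0              # tilt coupling s, k_BT/A^2 (s<0: water side down at large x)
    x_c: float = 2.45               # tilt crossover distance, A
    temperature: float = 300.0      # K
    barrier_floor: float = 0.2      # k_BT; B(x) is clamped from below so the
                                    # q-section stays confining for rare O-O
                                    # excursions below the nominal domain
    x_range: tuple[float, float] = (2.2, 3.0)
    q_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.barrier0 <= 0 or self.q0 <= 0:
            raise ValueError("barrier0 and q0 must be positive")
        lo, hi = self.x_range
        if self.barrier(np.array([lo, hi])).min() <= 0:
            raise ValueError("B(x) must stay positive over x_range")

    # -- pieces -------------------------------------------------------------
    def barrier(self, x):
        """Distance-dependent transfer barrier B(x), k_BT (floored)."""
        b = self.barrier0 + self.barrier_slope * (np.asarray(x, float) - self.x0)
        return np.maximum(b, self.barrier_floor)

    def tilt_term(self, x):
        """Linear tilt coefficient g(x) = s (x - x_c), k_BT/A."""
        return self.tilt * (np.asarray(x, float) - self.x_c)

    def energy(self, x, q):
        """F(x, q) in k_BT (not shifted)."""
        x = np.asarray(x, float)
        q = np.asarray(q, float)
        u = q / self.q0
        return (0.5 * self.k_x * (x - self.x0) ** 2
                + self.barrier(x) * (u * u - 1.0) ** 2
                + self.tilt_term(x) * q)

    def grad(self, x, q):
        """(dF/dx, dF/dq) in k_BT/A."""
        x = np.asarray(x, float)
        q = np.asarray(q, float)
        u = q / self.q0
        raw_b = self.barrier0 + self.barrier_slope * (x - self.x0)
        slope = np.where(raw_b > self.barrier_floor, self.barrier_slope, 0.0)
        dfdx = (self.k_x * (x - self.x0)
                + slope * (u * u - 1.0) ** 2
                + self.tilt * q)
        dfdq = (self.barrier(x) * 4.0 * u * (u * u - 1.0) / self.q0
                + self.tilt_term(x))
        return dfdx, dfdq

    @property
    def x_integration_range(self) -> tuple[float, float]:
        """x-window carrying essentially all Boltzmann weight (x0 +- 0.7 A).

        Wider than ``x_range`` (the nominal grid domain) so that analytic
        q-projections account for rare short/long O-O excursions.
        """
        return (self.x0 - 0.7, self.x0 + 0.7)

    def is_double_well(self, x) -> np.ndarray:
        """True where the section along q at distance x has two minima."""
        g = np.abs(self.tilt_term(x))
        return g * self.q0 / self.barrier(x) < DOUBLE_WELL_TILT_LIMIT


def analytic_fes(pes: SurrogatePES, x_edges, q_edges) -> FreeEnergySurface:
    """Closed-form F(x, q) on bin centers, shifted so the global minimum is 0.

    This is the brute-force reference against which all sampling-based
    estimates are tested.
    """
    x_edges = np.asarray(x_edges, float)
    q_edges = np.asarray(q_edges, float)
    _check_domain(pes, x_edges, q_edges)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    qc = 0.5 * (q_edges[:-1] + q_edges[1:])
    vals = pes.energy(xc[:, None], qc[None, :])
    if not np.all(np.isfinite(vals)):
        raise ValueError("PES not finite on the requested grid")
    vals = vals - vals.min()
    return FreeEnergySurface(x_edges=x_edges, q_edges=q_edges, values=vals,
                             counts=None,
                             provenance={"analytic": True, "pes": vars(pes)})


def analytic_profile(pes: SurrogatePES, q_edges, n_x: int = 800) -> FreeEnergyProfile:
    """Exact q-projection F(q) = -ln int dx exp(-F(x, q)), min = 0.

    The x-integral is evaluated by the trapezoidal rule on ``n_x`` points
    spanning ``pes.x_integration_range``, which covers all thermally
    relevant O-O distances.
    """
    q_edges = np.asarray(q_edges, float)
    xg = np.linspace(*pes.x_integration_range, n_x)
    qc = 0.5 * (q_edges[:-1] + q_edges[1:])
    en = pes.energy(xg[:, None], qc[None, :])
    en = en - en.min()
    p = np.trapezoid(np.exp(-en), xg, axis=0)
    f = -np.log(p)
    f -= f.min()
    return FreeEnergyProfile(q_edges=q_edges, values=f,
                             errors=np.zeros_like(f), counts=None,
                             provenance={"analytic": True, "n_x": n_x})


def analytic_forward_barrier(pes: SurrogatePES, n_q: int = 2001) -> float:
    """Forward (water-to-carboxyl) barrier of the analytic q-projection, k_BT."""
    q_edges = np.linspace(pes.q_range[0], pes.q_range[1], n_q)
    prof = analytic_profile(pes, q_edges)
    est = barrier_heights(prof, smooth_window=0)
    if est.single_well:
        raise ValueError("analytic projection is single-welled")
    return est.forward


def calibrate_barrier0(target: float = 3.0, pes: SurrogatePES | None = None,
                       bracket: tuple[float, float] = (3.0, 9.0)) -> float:
    """Base barrier B0 for which the projected forward barrier equals *target* k_BT."""
    from scipy.optimize import brentq

    template = pes if pes is not None else SurrogatePES()

    def resid(b0: float) -> float:
        return analytic_forward_barrier(replace(template, barrier0=b0)) - target

    return float(brentq(resid, *bracket, xtol=1e-6))


def _check_domain(pes: SurrogatePES, x_edges: np.ndarray, q_edges: np.ndarray) -> None:
    if (x_edges.min() < pes.x_range[0] - 1e-9 or x_edges.max() > pes.x_range[1] + 1e-9
            or q_edges.min() < pes.q_range[0] - 1e-9
            or q_edges.max() > pes.q_range[1] + 1e-9):
        raise ValueError("grid extends outside the configured PES domain")
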