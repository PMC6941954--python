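"""Stochastic surrogate dynamics on the proton-transfer reaction coordinates.

Overdamped (position) Langevin dynamics are integrated on the two
coordinates (x, q) of the analytic surrogate surface with the
Euler--Maruyama scheme,

    dz = -(1/gamma_z) dF/dz dt + sqrt(2 tau dt / gamma_z) xi,

where F is in units of k_BT at the PES reference temperature and
tau = T / T_ref rescales the noise for other simulation temperatures
(tau -> 0 recovers deterministic steepest descent).  The friction
constants gamma (k_BT fs / A^2) set the coordinate mobilities; the default
gamma_q is calibrated so that the default surface yields a mean proton
residence time of ~1 ps at 300 K (scripts/calibrate_surrogate.py).

The sampling protocol mirrors a thermostatted production run (with an
initial equilibration segment that is flagged and excluded from analysis)
followed by a number of short replicas started from snapshots of the
production segment; all post-equilibration frames are pooled uniformly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import CARBOXYL, WATER, StateSeries
from .pes import SurrogatePES

__all__ = [
    "LangevinSettings",
    "SimulationProtocol",
    "RCTrajectory",
    "simulate_rc_langevin",
    "simulate_dwell_process",
    "protocol_total_time",
]

#: calibrated so the default PES gives ~1 ps mean residence time at 300 K
#: with the default time step (scripts/calibrate_surrogate.py)
DEFAULT_GAMMA_Q = 461.0   # k_BT fs / A^2
DEFAULT_GAMMA_X = 2000.0  # k_BT fs / A^2
#: chosen so that a * F'' stays ~0.05 at the well curvatures, keeping the
#: Euler-Maruyama stationary-density bias well below the sampling noise
DEFAULT_DT_FS = 0.25


@dataclass(frozen=True)
class LangevinSettings:
    """Integrator parameters for the overdamped dynamics."""

    dt_fs: float = DEFAULT_DT_FS
    gamma_x: float = DEFAULT_GAMMA_X   # friction on x, k_BT fs / A^2
    gamma_q: float = DEFAULT_GAMMA_Q   # friction on q, k_BT fs / A^2
    scheme: str = "euler-maruyama"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.gamma_x <= 0 or self.gamma_q <= 0:
            raise ValueError("friction must be positive")
        if self.scheme != "euler-maruyama":
            raise ValueError(f"unknown integrator scheme {self.scheme!r}")


@dataclass(frozen=True)
class SimulationProtocol:
    """Production/equilibration/replica layout of the sampling run."""

    production_ps: float = 40.0
    equilibration_ps: float = 5.0
    n_replicas: int = 9
    replica_ps: float = 5.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.production_ps <= 0:
            raise ValueError("production length must be positive")
        if not self.equilibration_ps < self.production_ps:
            raise ValueError("equilibration cut must be shorter than production")
        if self.equilibration_ps < 0 or self.n_replicas < 0:
            raise ValueError("negative protocol fields")
        if self.n_replicas > 0 and self.replica_ps <= 0:
            raise ValueError("replica length must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class RCTrajectory:
    """Reaction-coordinate trajectory: time (ps), x = Ro_c_o_w and q (A)."""

    time_ps: np.ndarray
    x: np.ndarray
    q: np.ndarray
    equilibrated: np.ndarray       # False inside the flagged equilibration cut
    segment: np.ndarray            # 0 = production, 1..n = replicas
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_ps) > 0):
            raise ValueError("time axis must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.q))):
            raise ValueError("non-finite coordinates")

    def production_frames(self) -> "RCTrajectory":
        """Post-equilibration view (all frames pooled for analysis)."""
        m = self.equilibrated
        return RCTrajectory(self.time_ps[m], self.x[m], self.q[m],
                            self.equilibrated[m], self.segment[m],
                            dict(self.provenance))


def protocol_total_time(p: SimulationProtocol) -> float:
    """Total analyzed simulation time in ps.

    (production - equilibration) + n_replicas * replica length; the default
    protocol gives (40 - 5) + 9 * 5 = 80 ps.
    """
    return (p.production_ps - p.equilibration_ps) + p.n_replicas * p.replica_ps


def _integrate(pes: SurrogatePES, settings: LangevinSettings, tau: float,
               x0: float, q0: float, n_steps: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration; returns arrays of length n_steps + 1."""
    dt = settings.dt_fs
    ax = dt / settings.gamma_x
    aq = dt / settings.gamma_q
    sx = math.sqrt(2.0 * tau * ax)
    sq = math.sqrt(2.0 * tau * aq)
    # PES parameters as plain floats for the tight loop
    px0, pkx, pb0, pc = pes.x0, pes.k_x, pes.barrier0, pes.barrier_slope
    pq0, ps_, pxc, pbf = pes.q0, pes.tilt, pes.x_c, pes.barrier_floor
    noise = rng.standard_normal((n_steps, 2)) if tau > 0 else np.zeros((n_steps, 2))
    xs = np.empty(n_steps + 1)
    qs = np.empty(n_steps + 1)
    x, q = x0, q0
    xs[0], qs[0] = x, q
    # divergence is reported via the isfinite check, not float warnings
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_steps):
            u = q / pq0
            uu1 = u * u - 1.0
            b = pb0 + pc * (x - px0)
            c_eff = pc if b > pbf else 0.0
            if b < pbf:
                b = pbf
            dfdx = pkx * (x - px0) + c_eff * uu1 * uu1 + ps_ * q
            dfdq = 4.0 * b * u * uu1 / pq0 + ps_ * (x - pxc)
            x = x - ax * dfdx + sx * noise[i, 0]
            q = q - aq * dfdq + sq * noise[i, 1]
            if not (math.isfinite(x) and math.isfinite(q)):
                raise RuntimeError(
                    f"Langevin step became non-finite at step {i + 1}: "
                    f"dt={dt} fs, gamma_x={settings.gamma_x}, "
                    f"gamma_q={settings.gamma_q} are likely unstable"
                )
            xs[i + 1], qs[i + 1] = x, q
    return xs, qs


def simulate_rc_langevin(pes: SurrogatePES, settings: LangevinSettings,
                         protocol: SimulationProtocol) -> RCTrajectory:
    """Overdamped Langevin sampling of (x, q) following the protocol.

    The production segment starts from the water-side minimum (x0, +q0);
    its first ``equilibration_ps`` are flagged unequilibrated.  Each
    replica starts from an evenly spaced snapshot of the post-equilibration
    production segment with a sub-seed spawned from the master seed, and is
    appended on a continuing time axis.  Identical inputs give bit-identical
    output.
    """
    dt_ps = settings.dt_fs * 1e-3
    tau = protocol.temperature / pes.temperature
    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(1 + protocol.n_replicas)

    n_prod = int(round(protocol.production_ps / dt_ps))
    xs, qs = _integrate(pes, settings, tau, pes.x0, pes.q0, n_prod,
                        np.random.default_rng(children[0]))
    time = np.arange(n_prod + 1) * dt_ps
    equil = time >= protocol.equilibration_ps
    seg = np.zeros(n_prod + 1, dtype=int)

    all_t = [time]
    all_x = [xs]
    all_q = [qs]
    all_e = [equil]
    all_s = [seg]
    t_offset = time[-1]

    if protocol.n_replicas > 0:
        pool = np.nonzero(equil)[0]
        starts = pool[np.linspace(0, pool.size - 1, protocol.n_replicas,
                                  dtype=int)]
        n_rep = int(round(protocol.replica_ps / dt_ps))
        for j in range(protocol.n_replicas):
            rng = np.random.default_rng(children[j + 1])
            rx, rq = _integrate(pes, settings, tau,
                                xs[starts[j]], qs[starts[j]], n_rep, rng)
            # drop the duplicated initial snapshot frame
            all_t.append(t_offset + np.arange(1, n_rep + 1) * dt_ps)
            all_x.append(rx[1:])
            all_q.append(rq[1:])
            all_e.append(np.ones(n_rep, dtype=bool))
            all_s.append(np.full(n_rep, j + 1, dtype=int))
            t_offset += n_rep * dt_ps

    provenance = {
        "pes": {k: getattr(pes, k) for k in
                ("x0", "k_x", "barrier0", "barrier_slope", "q0", "tilt",
                 "x_c", "temperature")},
        "settings": {"dt_fs": settings.dt_fs, "gamma_x": settings.gamma_x,
                     "gamma_q": settings.gamma_q, "scheme": settings.scheme},
        "protocol": vars(protocol),
        "seed": settings.seed,
        "sub_seeds": [list(c.spawn_key) for c in children],
    }
    return RCTrajectory(
        time_ps=np.concatenate(all_t), x=np.concatenate(all_x),
        q=np.concatenate(all_q), equilibrated=np.concatenate(all_e),
        segment=np.concatenate(all_s), provenance=provenance,
    )


def simulate_dwell_process(mean_dwell_a_ps: float, mean_dwell_b_ps: float,
                           dt_ps: float, duration_ps: float, seed: int = 0,
                           labels: tuple[str, str] = (CARBOXYL, WATER),
                           ) -> StateSeries:
    """Two-state Markov (exponential-dwell) jump process sampled at dt.

    State A (``labels[0]``) and B alternate with independent exponential
    dwell times of the given means; the realized continuous-time process is
    sampled on a uniform grid.  Ground-truth rates are recorded in the
    provenance.

    Raises / warns
    --------------
    ValueError if dt >= min mean dwell; UserWarning if dt > min mean
    dwell / 10 (discretization bias).
    """
    if mean_dwell_a_ps <= 0 or mean_dwell_b_ps <= 0:
        raise ValueError("mean dwell times must be positive")
    if dt_ps <= 0 or duration_ps <= 0:
        raise ValueError("dt and duration must be positive")
    min_dwell = min(mean_dwell_a_ps, mean_dwell_b_ps)
    if dt_ps >= min_dwell:
        raise ValueError(
            f"dt = {dt_ps} ps must be well below the shortest mean dwell "
            f"({min_dwell} ps)")
    if dt_ps > min_dwell / 10:
        warnings.warn("dt exceeds min mean dwell / 10; dwell statistics "
                      "will be discretization-biased", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    means = (mean_dwell_a_ps, mean_dwell_b_ps)
    boundaries = [0.0]
    states = []
    s = 0
    t = 0.0
    while t < duration_ps:
        dwell = rng.exponential(means[s])
        t += dwell
        boundaries.append(t)
        states.append(s)
        s = 1 - s
    grid = np.arange(0.0, duration_ps, dt_ps)
    which = np.searchsorted(np.asarray(boundaries), grid, side="right") - 1
    lab = np.asarray(labels)[np.asarray(states)[which]]
    return StateSeries(
        time_ps=grid, labels=lab,
        provenance={"mean_dwell_a_ps": mean_dwell_a_ps,
                    "mean_dwell_b_ps": mean_dwell_b_ps,
                    "rate_a_per_ps": 1.0 / mean_dwell_a_ps,
                    "rate_b_per_ps": 1.0 / mean_dwell_b_ps,
                    "dt_ps": dt_ps, "duration_ps": duration_ps,
                    "seed": seed, "labels": list(labels)},
    )
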