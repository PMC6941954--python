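"""Embed reaction-coordinate trajectories as Cartesian model-system frames.

The long axis of the model system is the x-axis.  For each frame the
active carboxyl oxygen O1a sits at the origin, the water oxygen Ow at
(x, 0, 0), and the transferable proton H2 colinear between them at
((x + q)/2, 0, 0), so that Ro_c_h = (x + q)/2 and Ro_w_h = (x - q)/2 and
coordinate extraction recovers (x, q) exactly.  The remaining seven atoms
sit at fixed template positions, with optional Gaussian jitter in y and z
whose variance matches a harmonic transverse restraint of the configured
stiffness at the configured temperature (sigma = sqrt(k_B T / k)); the
default stiffness of 50 meV/A^2 gives sigma = 0.719 A at 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import RCTrajectory
from .topology import ModelTopology, make_default_topology
from .xyz import Trajectory, format_comment

__all__ = ["EmbeddingSettings", "embed_frames", "template_positions",
           "transverse_sigma"]

KB_MEV_PER_K = 8.617333262e-2  # Boltzmann constant, meV/K


def transverse_sigma(stiffness_mev_a2: float, temperature: float) -> float:
    """Equilibrium transverse displacement sigma = sqrt(k_B T / k), Angstrom."""
    if stiffness_mev_a2 <= 0:
        raise ValueError("restraint stiffness must be positive")
    return float(np.sqrt(KB_MEV_PER_K * temperature / stiffness_mev_a2))


@dataclass(frozen=True)
class EmbeddingSettings:
    """Parameters of the Cartesian embedding."""

    jitter: bool = True
    stiffness_mev_a2: float = 50.0   # transverse restraint stiffness
    temperature: float = 300.0       # K
    seed: int = 0


def template_positions(x: float) -> dict[str, np.ndarray]:
    """Template coordinates of the seven non-axis atoms for O-O distance x.

    Geometry uses standard carboxyl/water bond lengths (C-O 1.25 A, O-H
    1.0 A, O-C-O 125 deg); the second carboxyl group is hydrogen-bond
    distance (2.5 A) beyond the water oxygen.  Positions are chosen so
    that, with default jitter, no hydrogen can approach two non-donor
    oxygens at once (the model system has no three-centred geometry).
    """
    return {r: np.array([dx + (x if rel else 0.0), dy, dz])
            for r, (rel, dx, dy, dz) in _TEMPLATE.items()}


_C125 = float(np.cos(np.deg2rad(125.0)))
_S125 = float(np.sin(np.deg2rad(125.0)))
# role -> (offset is relative to Ow position?, dx, dy, dz)
_TEMPLATE = {
    "C1": (False, -1.25, 0.0, 0.0),
    "O1b": (False, -1.25 + 1.25 * _C125, 1.25 * _S125, 0.0),
    "H1": (False, -0.45, -0.89, 0.0),
    "H3": (True, 0.32, 0.95, 0.0),
    "O2a": (True, 2.5, 0.0, 0.0),
    "C2": (True, 3.75, 0.0, 0.0),
    "O2b": (True, 3.75 - 1.25 * _C125, 1.25 * _S125, 0.0),
}


def embed_frames(rc: RCTrajectory, topo: ModelTopology | None = None,
                 settings: EmbeddingSettings | None = None) -> Trajectory:
    """Reconstruct Cartesian frames from a reaction-coordinate trajectory.

    Requires x > |q| in every frame (colinear placement solvable with
    positive distances); offending frames are rejected by index.  With
    jitter disabled the round trip through coordinate extraction recovers
    (x, q) exactly.
    """
    topo = topo if topo is not None else make_default_topology()
    settings = settings if settings is not None else EmbeddingSettings()
    x = np.asarray(rc.x, float)
    q = np.asarray(rc.q, float)
    bad = np.nonzero(x <= np.abs(q))[0]
    if bad.size:
        raise ValueError(
            f"frame {bad[0]}: x = {x[bad[0]]:.4f} <= |q| = "
            f"{abs(q[bad[0]]):.4f}; colinear embedding unsolvable")
    n = x.size
    n_atoms = len(topo.roles)
    coords = np.zeros((n, n_atoms, 3))

    i_o1a = topo.index("O1a")
    i_ow = topo.index("Ow")
    i_h2 = topo.index("H2")
    coords[:, i_o1a] = 0.0
    coords[:, i_ow, 0] = x
    coords[:, i_h2, 0] = 0.5 * (x + q)

    sigma = transverse_sigma(settings.stiffness_mev_a2, settings.temperature)
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    for r, (rel, dx, dy, dz) in _TEMPLATE.items():
        idx = topo.index(r)
        coords[:, idx, 0] = dx + (x if rel else 0.0)
        coords[:, idx, 1] = dy
        coords[:, idx, 2] = dz
        if settings.jitter:
            coords[:, idx, 1:] += sigma * rng.standard_normal((n, 2))

    seed = rc.provenance.get("seed", "NA")
    comments = [
        format_comment(time_ps=f"{t:.6f}", x_A=f"{xi:.6f}", q_A=f"{qi:.6f}",
                       seed=seed)
        for t, xi, qi in zip(rc.time_ps, x, q)
    ]
    return Trajectory(
        coords=coords, symbols=tuple(topo.elements), comments=comments,
        time_ps=np.asarray(rc.time_ps, float),
        provenance={"embedding": vars(settings), "sigma_A": sigma,
                    "rc_provenance": dict(rc.provenance)},
    )
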