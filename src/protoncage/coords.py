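"""Reaction coordinates and hydrogen-bond geometry from Cartesian frames.

For a chosen hydrogen the per-frame coordinates are

* ``Ro_c_h``   -- distance to the nearest carboxyl-group oxygen,
* ``Ro_w_h``   -- distance to the water oxygen,
* ``q``        -- asymmetry, Ro_c_h - Ro_w_h (negative: proton near the
  carboxyl oxygen; positive: near the water oxygen),
* ``Ro_c_o_w`` -- distance between the water oxygen and the carboxyl
  oxygen achieving Ro_c_h (frame-wise re-selection by default; a fixed
  carboxyl oxygen can be requested instead).

All distances are plain Euclidean (the model system is non-periodic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import ModelTopology, make_default_topology
from .xyz import Trajectory

__all__ = [
    "OwnerAssignment", "CoordinateSeries", "BifurcationCriteria",
    "BifurcationReport", "assign_proton_owners", "compute_rc_series",
    "detect_bifurcated", "write_series_tsv", "read_series_tsv",
]


@dataclass
class OwnerAssignment:
    """Nearest-oxygen owner of every hydrogen in one frame."""

    owners: dict[str, str]            # hydrogen role -> owner oxygen role
    distances: dict[str, float]       # hydrogen role -> distance to owner, A
    ties: dict[str, bool]             # exact-tie flag (broken to lowest index)


@dataclass
class CoordinateSeries:
    """Per-frame reaction coordinates for one hydrogen."""

    time_ps: np.ndarray
    r_co_w: np.ndarray                # Ro_c_o_w, A
    r_ch: np.ndarray                  # Ro_c_h, A
    r_wh: np.ndarray                  # Ro_w_h, A
    q: np.ndarray                     # Ro_c_h - Ro_w_h, A
    owner: np.ndarray                 # owner oxygen role per frame
    tie: np.ndarray                   # exact-tie flag per frame
    hydrogen: str = "H2"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.q, self.r_ch - self.r_wh, atol=1e-12):
            raise ValueError("q must equal Ro_c_h - Ro_w_h exactly")

    @classmethod
    def from_rc(cls, rc) -> "CoordinateSeries":
        """Coordinate series directly from a reaction-coordinate trajectory.

        Uses the colinear identities Ro_c_h = (x + q)/2, Ro_w_h = (x - q)/2
        of the generator's embedding convention.
        """
        x = np.asarray(rc.x, float)
        q = np.asarray(rc.q, float)
        n = x.size
        return cls(
            time_ps=np.asarray(rc.time_ps, float),
            r_co_w=x, r_ch=0.5 * (x + q), r_wh=0.5 * (x - q), q=q,
            owner=np.where(q < 0, "O1a", "Ow"),
            tie=np.zeros(n, dtype=bool), hydrogen="H2",
            provenance={"from_rc": True, **dict(rc.provenance)},
        )


@dataclass(frozen=True)
class BifurcationCriteria:
    """Geometric criteria for three-centred (bifurcated) hydrogen bonds.

    The nearest oxygen is the donor (covalent when closer than
    ``covalent_cutoff``) and is excluded; a hydrogen is flagged when at
    least two of the remaining oxygens fall inside the acceptor window
    [``acceptor_min``, ``acceptor_max``].  An optional
    donor-H...acceptor angle minimum is applied to each counted acceptor.
    """

    covalent_cutoff: float = 1.2     # A
    acceptor_min: float = 1.2        # A
    acceptor_max: float = 2.4        # A
    angle_min_deg: float | None = None

    def __post_init__(self) -> None:
        if min(self.covalent_cutoff, self.acceptor_min, self.acceptor_max) <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class BifurcationReport:
    criteria: BifurcationCriteria
    flags: dict[str, np.ndarray]      # hydrogen role -> per-frame bool
    occupancy: dict[str, float]       # hydrogen role -> flagged fraction
    n_frames: int


def _distance_matrix(frame: np.ndarray, h_idx, o_idx) -> np.ndarray:
    return np.linalg.norm(frame[h_idx][:, None, :] - frame[o_idx][None, :, :],
                          axis=-1)


def assign_proton_owners(frame: np.ndarray, topo: ModelTopology | None = None
                         ) -> OwnerAssignment:
    """Nearest-oxygen owner of each hydrogen in a single Cartesian frame.

    Exact ties are broken towards the lowest atom index and flagged.
    """
    topo = topo if topo is not None else make_default_topology()
    frame = np.asarray(frame, float)
    if frame.shape != (len(topo.roles), 3):
        missing = f"expected {len(topo.roles)} atoms"
        raise ValueError(f"frame shape {frame.shape} does not match topology "
                         f"({missing})")
    h_idx = [topo.index(h) for h in topo.hydrogens]
    o_idx = [topo.index(o) for o in topo.oxygens]
    d = _distance_matrix(frame, h_idx, o_idx)
    owners, dists, ties = {}, {}, {}
    for i, h in enumerate(topo.hydrogens):
        j = int(np.argmin(d[i]))      # argmin returns the lowest index on ties
        owners[h] = topo.oxygens[j]
        dists[h] = float(d[i, j])
        ties[h] = bool(np.sum(d[i] == d[i, j]) > 1)
    return OwnerAssignment(owners=owners, distances=dists, ties=ties)


def compute_rc_series(traj: Trajectory, topo: ModelTopology | None = None,
                      hydrogen: str = "H2",
                      fixed_oxygen: str | None = None) -> CoordinateSeries:
    """Extract the reaction coordinates of *hydrogen* from a trajectory.

    Parameters
    ----------
    fixed_oxygen : str, optional
        Measure Ro_c_o_w to this carboxyl oxygen in every frame instead of
        re-selecting the one achieving Ro_c_h.
    """
    topo = topo if topo is not None else make_default_topology()
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if hydrogen not in topo.hydrogens:
        raise ValueError(f"{hydrogen!r} is not a hydrogen of the topology")
    if fixed_oxygen is not None and fixed_oxygen not in topo.carboxyl_oxygens:
        raise ValueError(f"{fixed_oxygen!r} is not a carboxyl oxygen")

    h = traj.coords[:, topo.index(hydrogen)]
    ow = traj.coords[:, topo.index(topo.water_oxygen)]
    c_ox = topo.carboxyl_oxygens
    c_pos = np.stack([traj.coords[:, topo.index(o)] for o in c_ox], axis=1)
    d_c = np.linalg.norm(c_pos - h[:, None, :], axis=-1)   # (n, 4)
    k = np.argmin(d_c, axis=1)
    r_ch = d_c[np.arange(d_c.shape[0]), k]
    r_wh = np.linalg.norm(h - ow, axis=-1)
    tie = (np.sum(d_c == r_ch[:, None], axis=1) > 1) | (r_ch == r_wh)
    if fixed_oxygen is not None:
        sel = np.full(k.shape, c_ox.index(fixed_oxygen))
    else:
        sel = k
    r_co_w = np.linalg.norm(c_pos[np.arange(len(k)), sel] - ow, axis=-1)
    time = traj.time_ps if traj.time_ps is not None else np.arange(traj.n_frames, dtype=float)
    owner = np.where(r_ch <= r_wh, np.asarray(c_ox)[k], topo.water_oxygen)
    return CoordinateSeries(
        time_ps=np.asarray(time, float), r_co_w=r_co_w, r_ch=r_ch, r_wh=r_wh,
        q=r_ch - r_wh, owner=owner,
        tie=tie, hydrogen=hydrogen,
        provenance={"fixed_oxygen": fixed_oxygen, **dict(traj.provenance)},
    )


def detect_bifurcated(traj: Trajectory, topo: ModelTopology | None = None,
                      criteria: BifurcationCriteria | None = None
                      ) -> BifurcationReport:
    """Flag frames in which a hydrogen forms a three-centred hydrogen bond.

    See :class:`BifurcationCriteria` for the geometric definition.
    """
    topo = topo if topo is not None else make_default_topology()
    criteria = criteria if criteria is not None else BifurcationCriteria()
    h_roles = topo.hydrogens
    o_roles = topo.oxygens
    h_pos = np.stack([traj.coords[:, topo.index(r)] for r in h_roles], axis=1)
    o_pos = np.stack([traj.coords[:, topo.index(r)] for r in o_roles], axis=1)
    # (n_frames, n_h, n_o)
    d = np.linalg.norm(h_pos[:, :, None, :] - o_pos[:, None, :, :], axis=-1)
    donor = np.argmin(d, axis=2)                            # nearest oxygen
    in_window = (d >= criteria.acceptor_min) & (d <= criteria.acceptor_max)
    n, nh, no = d.shape
    donor_mask = np.zeros_like(in_window)
    fr, hy = np.meshgrid(np.arange(n), np.arange(nh), indexing="ij")
    donor_mask[fr, hy, donor] = True
    acceptable = in_window & ~donor_mask
    if criteria.angle_min_deg is not None:
        dvec = h_pos - o_pos[fr, donor]                     # donor -> H
        avec = o_pos[:, None, :, :] - h_pos[:, :, None, :]  # H -> acceptor
        cosang = np.einsum("fhx,fhox->fho", dvec, avec)
        norm = (np.linalg.norm(dvec, axis=-1)[:, :, None]
                * np.linalg.norm(avec, axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.degrees(np.arccos(np.clip(cosang / norm, -1, 1)))
        acceptable &= ang >= criteria.angle_min_deg
    flagged = np.sum(acceptable, axis=2) >= 2               # (n_frames, n_h)
    flags = {h: flagged[:, i] for i, h in enumerate(h_roles)}
    occupancy = {h: float(flagged[:, i].mean()) for i, h in enumerate(h_roles)}
    return BifurcationReport(criteria=criteria, flags=flags,
                             occupancy=occupancy, n_frames=n)


# -- tabular I/O ------------------------------------------------------------

_TSV_COLUMNS = {
    "time_ps": "time_ps", "r_co_w": "Ro_c_o_w_A", "r_ch": "Ro_c_h_A",
    "r_wh": "Ro_w_h_A", "q": "asymmetry_A", "owner": "owner", "tie": "tie",
}


def write_series_tsv(series: CoordinateSeries, path, header_lines=()) -> None:
    """Write a coordinate series as a tab-separated table with unit-bearing headers."""
    df = pd.DataFrame({col: getattr(series, attr)
                       for attr, col in _TSV_COLUMNS.items()})
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# hydrogen={series.hydrogen}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_series_tsv(path) -> CoordinateSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    hydrogen = "H2"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# hydrogen="):
                hydrogen = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    return CoordinateSeries(
        time_ps=df["time_ps"].to_numpy(), r_co_w=df["Ro_c_o_w_A"].to_numpy(),
        r_ch=df["Ro_c_h_A"].to_numpy(), r_wh=df["Ro_w_h_A"].to_numpy(),
        q=df["asymmetry_A"].to_numpy(), owner=df["owner"].to_numpy(),
        tie=df["tie"].to_numpy(dtype=bool), hydrogen=hydrogen,
        provenance={"source": str(path)},
    )
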