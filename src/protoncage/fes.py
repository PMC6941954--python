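"""Free-energy estimation by Boltzmann inversion.

Free energies are estimated from sampled reaction-coordinate series as
``F = -ln P + C`` (in units of k_BT), with the additive constant fixed so
that the minimum over sampled bins is zero.  Unsampled bins are masked
(infinite F), never interpolated.  Per-bin uncertainties come from block
averaging over contiguous trajectory blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FreeEnergySurface",
    "FreeEnergyProfile",
    "BarrierEstimate",
    "estimate_fes2d",
    "project_to_asymmetry",
    "barrier_heights",
    "default_q_edges",
    "default_x_edges",
]

#: default bin widths (Angstrom)
DEFAULT_DQ = 0.05
DEFAULT_DX = 0.02
DEFAULT_N_BLOCKS = 8


def default_q_edges(lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    n = int(round((hi - lo) / DEFAULT_DQ))
    return lo + DEFAULT_DQ * np.arange(n + 1)


def default_x_edges(lo: float = 2.1, hi: float = 3.1) -> np.ndarray:
    n = int(round((hi - lo) / DEFAULT_DX))
    return lo + DEFAULT_DX * np.arange(n + 1)


@dataclass
class FreeEnergySurface:
    """2D free-energy surface F(x, q) in k_BT.

    ``values`` is masked (np.inf) where ``counts`` is zero; the minimum over
    sampled bins is zero.  For analytic surfaces ``counts`` is None.
    """

    x_edges: np.ndarray
    q_edges: np.ndarray
    values: np.ndarray          # shape (nx, nq), k_BT
    counts: np.ndarray | None   # same shape, frame counts, or None (analytic)
    provenance: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is unsampled."""
        return ~np.isfinite(self.values)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile F(q) in k_BT with block-derived standard errors."""

    q_edges: np.ndarray
    values: np.ndarray          # k_BT, min over sampled bins = 0
    errors: np.ndarray          # k_BT, >= 0 (inf where not estimable)
    counts: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])


@dataclass
class BarrierEstimate:
    """Forward/reverse transfer barriers along the asymmetry coordinate.

    *Forward* is water-to-carboxyl: F(interior maximum) minus F(water-side
    minimum, q > 0).  ``single_well`` is True when no interior maximum
    separates two minima; the barrier fields are then NaN.
    """

    forward: float              # k_BT
    reverse: float              # k_BT
    q_min_carboxyl: float       # Angstrom, q < 0
    q_min_water: float          # Angstrom, q > 0
    q_max: float                # Angstrom, interior maximum
    forward_error: float        # k_BT
    reverse_error: float        # k_BT
    single_well: bool = False


def _hist_to_f(counts: np.ndarray) -> np.ndarray:
    """-ln(counts) shifted so the sampled minimum is 0; empty bins -> inf."""
    f = np.full(counts.shape, np.inf)
    sampled = counts > 0
    if not np.any(sampled):
        raise ValueError("no sampled bins")
    with np.errstate(divide="ignore"):
        f[sampled] = -np.log(counts[sampled])
    f -= f[sampled].min()
    return f


def estimate_fes2d(series, x_edges=None, q_edges=None) -> FreeEnergySurface:
    """Boltzmann-inversion F(x, q) from a CoordinateSeries.

    Parameters
    ----------
    series : CoordinateSeries
        Provides per-frame x = Ro_c_o_w and q = Ro_c_h - Ro_w_h.
    x_edges, q_edges : array-like, optional
        Bin edges; defaults span the data with 0.02 / 0.05 Angstrom bins.
    """
    x = np.asarray(series.r_co_w, dtype=float)
    q = np.asarray(series.q, dtype=float)
    if x.size == 0:
        raise ValueError("empty coordinate series")
    if x_edges is None:
        x_edges = default_x_edges(np.floor(x.min() / DEFAULT_DX) * DEFAULT_DX,
                                  np.ceil(x.max() / DEFAULT_DX) * DEFAULT_DX)
    if q_edges is None:
        q_edges = default_q_edges(np.floor(q.min() / DEFAULT_DQ) * DEFAULT_DQ,
                                  np.ceil(q.max() / DEFAULT_DQ) * DEFAULT_DQ)
    x_edges = np.asarray(x_edges, dtype=float)
    q_edges = np.asarray(q_edges, dtype=float)
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(q_edges) <= 0):
        raise ValueError("bin widths must be positive")
    counts, _, _ = np.histogram2d(x, q, bins=(x_edges, q_edges))
    values = _hist_to_f(counts)
    return FreeEnergySurface(
        x_edges=x_edges, q_edges=q_edges, values=values, counts=counts,
        provenance={"n_frames": int(x.size), "estimator": "boltzmann_inversion"},
    )


def project_to_asymmetry(series, q_edges=None,
                         n_blocks: int = DEFAULT_N_BLOCKS) -> FreeEnergyProfile:
    """Project onto the asymmetry coordinate: F(q) = -ln sum_x P(x, q) + C.

    Standard errors are obtained from ``n_blocks`` contiguous trajectory
    blocks; per-block profiles are aligned at the globally best-sampled bin
    before taking the across-block standard deviation.
    """
    q = np.asarray(series.q, dtype=float)
    if q.size == 0:
        raise ValueError("empty coordinate series")
    if q.size < 2 * n_blocks:
        raise ValueError(
            f"series of {q.size} frames too short for {n_blocks} blocks"
        )
    if q_edges is None:
        q_edges = default_q_edges(np.floor(q.min() / DEFAULT_DQ) * DEFAULT_DQ,
                                  np.ceil(q.max() / DEFAULT_DQ) * DEFAULT_DQ)
    q_edges = np.asarray(q_edges, dtype=float)
    counts, _ = np.histogram(q, bins=q_edges)
    values = _hist_to_f(counts)

    # block analysis: align each block's profile at the best-sampled bin so
    # the per-block normalisation constant cancels
    ref_bin = int(np.argmax(counts))
    blocks = np.array_split(q, n_blocks)
    block_f = np.full((n_blocks, counts.size), np.nan)
    for b, qb in enumerate(blocks):
        cb, _ = np.histogram(qb, bins=q_edges)
        ok = (cb > 0)
        if not ok[ref_bin]:
            continue
        with np.errstate(divide="ignore"):
            fb = -np.log(cb / cb.sum())
        fb -= fb[ref_bin]
        block_f[b, ok] = fb[ok]
    n_ok = np.sum(np.isfinite(block_f), axis=0)
    errors = np.full(counts.size, np.inf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(block_f, axis=0, ddof=1)
    est = n_ok >= 2
    errors[est] = sd[est] / np.sqrt(n_ok[est])
    return FreeEnergyProfile(
        q_edges=q_edges, values=values, errors=errors, counts=counts,
        provenance={"n_frames": int(q.size), "n_blocks": n_blocks,
                    "ref_bin": ref_bin},
    )


def _smooth3(f: np.ndarray) -> np.ndarray:
    """3-bin moving average over finite values, inf-preserving."""
    out = np.copy(f)
    finite = np.isfinite(f)
    for i in np.nonzero(finite)[0]:
        window = f[max(i - 1, 0): i + 2]
        w = window[np.isfinite(window)]
        out[i] = w.mean()
    return out


def barrier_heights(profile: FreeEnergyProfile,
                    smooth_window: int = 3) -> BarrierEstimate:
    """Locate the two minima and the interior maximum of F(q) and report barriers.

    Extrema are located on a 3-bin moving-average-smoothed profile (to
    suppress single-bin noise spikes); the reported free energies are the
    raw, unsmoothed values at those locations.  If no interior maximum
    separates a carboxyl-side (q < 0) and a water-side (q > 0) minimum the
    result is flagged ``single_well`` rather than raising.
    """
    f_raw = np.asarray(profile.values, dtype=float)
    qc = profile.q_centers
    finite = np.isfinite(f_raw)
    if finite.sum() < 3:
        raise ValueError("profile has fewer than 3 sampled bins")
    f_s = _smooth3(f_raw) if smooth_window and smooth_window > 1 else f_raw

    neg = finite & (qc < 0)
    pos = finite & (qc > 0)
    if not (neg.any() and pos.any()):
        return _single_well(f_raw, qc, finite)
    i_neg = np.nonzero(neg)[0][np.argmin(f_s[neg])]
    i_pos = np.nonzero(pos)[0][np.argmin(f_s[pos])]
    between = np.arange(i_neg + 1, i_pos)
    between = between[finite[between]]
    if between.size == 0:
        return _single_well(f_raw, qc, finite)
    i_max = between[np.argmax(f_s[between])]
    # genuine interior maximum must rise above both flanking minima
    if not (f_s[i_max] > f_s[i_neg] and f_s[i_max] > f_s[i_pos]):
        return _single_well(f_raw, qc, finite)

    err = profile.errors if profile.errors is not None else np.zeros_like(f_raw)
    fwd_err = float(np.hypot(err[i_max], err[i_pos]))
    rev_err = float(np.hypot(err[i_max], err[i_neg]))
    return BarrierEstimate(
        forward=float(f_raw[i_max] - f_raw[i_pos]),
        reverse=float(f_raw[i_max] - f_raw[i_neg]),
        q_min_carboxyl=float(qc[i_neg]),
        q_min_water=float(qc[i_pos]),
        q_max=float(qc[i_max]),
        forward_error=fwd_err,
        reverse_error=rev_err,
        single_well=False,
    )


def _single_well(f_raw, qc, finite) -> BarrierEstimate:
    i_min = np.nonzero(finite)[0][np.argmin(f_raw[finite])]
    return BarrierEstimate(
        forward=float("nan"), reverse=float("nan"),
        q_min_carboxyl=float("nan") if qc[i_min] > 0 else float(qc[i_min]),
        q_min_water=float(qc[i_min]) if qc[i_min] > 0 else float("nan"),
        q_max=float("nan"),
        forward_error=float("nan"), reverse_error=float("nan"),
        single_well=True,
    )
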