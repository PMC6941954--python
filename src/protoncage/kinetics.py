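"""Jump detection and residence-time statistics for proton transfer.

The proton's asymmetry coordinate q is discretized into two committed
states -- carboxyl-bound (q < -q_core) and water-bound (q > +q_core) --
with a hysteresis band |q| <= q_core in which the previous committed state
is retained.  Maximal constant-state runs become dwells; the first and
last dwell of a series are censored (their true length is unknown) and are
excluded from mean residence times by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CARBOXYL", "WATER", "AMBIGUOUS",
    "StateSeries", "Dwell", "DwellSet", "ResidenceStats",
    "discretize", "extract_dwells", "residence_stats", "q_core_sweep",
]

CARBOXYL = "carboxyl"
WATER = "water"
AMBIGUOUS = "ambiguous"
_LABELS = (CARBOXYL, WATER, AMBIGUOUS)

DEFAULT_Q_CORE = 0.4  # Angstrom


@dataclass
class StateSeries:
    """Per-frame discrete state labels on a uniform time axis."""

    time_ps: np.ndarray
    labels: np.ndarray           # dtype str, values from _LABELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, float)
        self.labels = np.asarray(self.labels)
        if self.time_ps.shape != self.labels.shape:
            raise ValueError("time axis and labels must have equal length")
        bad = set(np.unique(self.labels)) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def dt_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])


@dataclass(frozen=True)
class Dwell:
    state: str
    start_ps: float
    end_ps: float
    duration_ps: float
    censored: bool


@dataclass
class DwellSet:
    """Time-ordered, non-overlapping dwells plus the thresholds that made them."""

    dwells: list[Dwell]
    q_core: float | None = None
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.dwells)

    def __len__(self) -> int:
        return len(self.dwells)

    def uncensored(self) -> list[Dwell]:
        return [d for d in self.dwells if not d.censored]


@dataclass
class ResidenceStats:
    """Mean residence times, standard errors and derived exchange rates."""

    mean_ps: dict[str, float]        # per-state mean over uncensored dwells
    pooled_mean_ps: float
    pooled_se_ps: float
    se_ps: dict[str, float]
    n_events: dict[str, int]
    n_pooled: int
    rate_per_ps: dict[str, float]    # k = 1/tau
    includes_censored: bool = False


def discretize(series, q_core: float = DEFAULT_Q_CORE) -> StateSeries:
    """Two-threshold (hysteresis) state assignment from the asymmetry q.

    q < -q_core commits to carboxyl-bound, q > +q_core to water-bound;
    ambiguous frames (|q| <= q_core) keep the previous committed state, and
    leading ambiguous frames take the first committed state.

    Raises
    ------
    ValueError
        If q_core <= 0 or no frame ever commits.
    """
    if q_core <= 0:
        raise ValueError("q_core must be positive")
    q = np.asarray(series.q, float)
    t = np.asarray(series.time_ps, float)
    raw = np.where(q < -q_core, 0, np.where(q > q_core, 1, -1))
    committed = raw >= 0
    if not committed.any():
        raise ValueError("no committed frame: all |q| <= q_core")
    # forward-fill committed states; leading gap takes the first committed state
    idx = np.where(committed, np.arange(q.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = np.argmax(committed)
    idx[idx < 0] = first
    states = np.where(raw[idx] == 0, CARBOXYL, WATER)
    return StateSeries(time_ps=t, labels=states,
                       provenance={"q_core": q_core,
                                   "source": getattr(series, "provenance", {})})


def extract_dwells(states: StateSeries) -> DwellSet:
    """Convert maximal constant-state runs into dwells.

    A run of n frames has duration n * dt.  The first and last dwells are
    flagged censored: the series does not show when they began or ended.
    """
    labels = states.labels
    if labels.size == 0:
        raise ValueError("empty state series")
    dt = states.dt_ps if labels.size > 1 else float("nan")
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    t0 = states.time_ps[0]
    dwells = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        censored = (i == 0) or (i == len(starts) - 1)
        dwells.append(Dwell(
            state=str(labels[a]),
            start_ps=t0 + a * dt if labels.size > 1 else t0,
            end_ps=t0 + b * dt if labels.size > 1 else t0,
            duration_ps=(b - a) * dt if labels.size > 1 else float("nan"),
            censored=censored,
        ))
    return DwellSet(dwells=dwells,
                    q_core=states.provenance.get("q_core"),
                    provenance={"n_frames": int(labels.size), "dt_ps": dt})


def residence_stats(dwells: DwellSet, include_censored: bool = False) -> ResidenceStats:
    """Mean residence time per state and pooled, with SE = sample SD / sqrt(n).

    Censored (boundary) dwells are excluded unless ``include_censored`` is
    set, in which case the result is flagged accordingly.
    """
    pool = list(dwells) if include_censored else dwells.uncensored()
    if not pool:
        raise ValueError("no uncensored dwells to average")
    by_state: dict[str, list[float]] = {}
    for d in pool:
        by_state.setdefault(d.state, []).append(d.duration_ps)
    durations = np.array([d.duration_ps for d in pool])

    def _se(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0

    mean = {s: float(np.mean(v)) for s, v in by_state.items()}
    return ResidenceStats(
        mean_ps=mean,
        pooled_mean_ps=float(durations.mean()),
        pooled_se_ps=_se(durations),
        se_ps={s: _se(np.asarray(v)) for s, v in by_state.items()},
        n_events={s: len(v) for s, v in by_state.items()},
        n_pooled=len(pool),
        rate_per_ps={s: 1.0 / m for s, m in mean.items()},
        includes_censored=include_censored,
    )


def q_core_sweep(series, q_cores) -> dict[float, ResidenceStats]:
    """Sensitivity of the residence-time estimate to the core threshold."""
    out = {}
    for qc in q_cores:
        out[float(qc)] = residence_stats(extract_dwells(discretize(series, qc)))
    return out
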