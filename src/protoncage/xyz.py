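"""Extended-XYZ trajectory container and I/O.

Frames are written with a fixed 6-decimal coordinate precision and a
per-frame comment line of ``key=value`` pairs (e.g. ``time_ps=0.125
x_A=2.500000 q_A=0.5 seed=1``), so that a written trajectory reads back
bit-compatibly at the declared precision together with its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trajectory", "read_xyz", "write_xyz", "parse_comment", "format_comment"]

COORD_FMT = "{:.6f}"


@dataclass
class Trajectory:
    """Cartesian trajectory: (n_frames, n_atoms, 3) coordinates in Angstrom."""

    coords: np.ndarray
    symbols: tuple[str, ...]             # element symbols, one per atom
    comments: list[str] = field(default_factory=list)
    time_ps: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.symbols):
            raise ValueError("atom count does not match symbols")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.comments:
            self.comments = [""] * self.n_frames
        if len(self.comments) != self.n_frames:
            raise ValueError("one comment per frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def format_comment(**fields) -> str:
    return " ".join(f"{k}={v}" for k, v in fields.items())


def parse_comment(comment: str) -> dict[str, str]:
    """key=value tokens of a frame comment (non-token words are ignored)."""
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            out[k] = v
    return out


def write_xyz(traj: Trajectory, path) -> None:
    """Write an extended-XYZ file with 6-decimal coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(traj.comments[i].rstrip("\n") + "\n")
            for sym, (x, y, z) in zip(traj.symbols, traj.coords[i]):
                fh.write(f"{sym} {COORD_FMT.format(x)} {COORD_FMT.format(y)} "
                         f"{COORD_FMT.format(z)}\n")


def read_xyz(path) -> Trajectory:
    """Read an (extended-)XYZ trajectory.

    Raises
    ------
    ValueError
        On an empty file, a malformed frame header (with its line number),
        or a frame with the wrong atom count (with its frame index).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty trajectory file")
    frames: list[np.ndarray] = []
    comments: list[str] = []
    symbols: tuple[str, ...] | None = None
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():      # tolerate trailing blank lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ValueError(
                f"{path}: malformed frame header at line {i + 1}: "
                f"{lines[i]!r}") from None
        if i + 2 + n_atoms > len(lines):
            raise ValueError(
                f"{path}: frame {frame_idx} declares {n_atoms} atoms but the "
                f"file ends early")
        comments.append(lines[i + 1])
        syms = []
        xyz = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: frame {frame_idx}: bad atom line "
                    f"{i + 3 + a}: {lines[i + 2 + a]!r}")
            syms.append(parts[0])
            xyz[a] = [float(p) for p in parts[1:4]]
        if symbols is None:
            symbols = tuple(syms)
        elif tuple(syms) != symbols or n_atoms != len(symbols):
            raise ValueError(
                f"{path}: frame {frame_idx} atom count/order differs from "
                f"frame 0")
        frames.append(xyz)
        i += 2 + n_atoms
        frame_idx += 1
    coords = np.stack(frames)
    times = []
    for c in comments:
        meta = parse_comment(c)
        times.append(float(meta["time_ps"]) if "time_ps" in meta else np.nan)
    time_ps = np.asarray(times)
    if np.all(np.isnan(time_ps)):
        time_ps = None
    return Trajectory(coords=coords, symbols=symbols, comments=comments,
                      time_ps=time_ps, provenance={"source": str(path)})
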