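"""Shared in-memory containers for coarse-grained configurations.

Positions are in nm throughout; boxes are orthorhombic edge lengths in nm;
times are in ns; masses in amu. Bead metadata lives in a pandas DataFrame so
selections compose with ordinary boolean indexing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Standard 4:1-mapped bead mass (amu). MARTINI maps ~4 heavy atoms per bead.
BEAD_MASS = 72.0

#: Bead roles considered hydrophobic (form the micelle core).
HYDROPHOBIC_ROLES = frozenset({"tail", "ring"})
#: Bead roles forming the dendron head.
HEAD_ROLES = frozenset({"head-node", "terminal-amine"})

#: Columns every bead table carries.  siRNA frames additionally carry
#: ``resid`` (nucleotide index), ``strand`` (0 sense / 1 antisense) and
#: ``basepair`` (1-based pair index, -1 for overhang nucleotides).
BEAD_COLUMNS = (
    "name",
    "martini_type",
    "charge",
    "mass",
    "role",
    "molecule_id",
    "molecule_kind",
)


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Map displacement vectors to their minimum periodic image."""
    vectors = np.asarray(vectors, dtype=float)
    if box is None:
        return vectors
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    return float(np.linalg.norm(minimum_image(np.asarray(a) - np.asarray(b), box)))


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per dimension.

    Guards against the floating-point edge where ``(-eps) % L`` rounds to
    exactly L, which periodic KD-trees reject."""
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(positions, box)
    return np.where(wrapped >= box, 0.0, wrapped)


def group_com(
    positions: np.ndarray,
    masses: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted centre of mass of a compact group.

    Under periodic boundaries the COM is computed per dimension by the
    circular-mean construction (project each coordinate onto a circle of
    circumference L, average the phase), which is invariant to how the group
    happens to be wrapped.  For groups spanning less than half the box this
    agrees with the COM of the unwrapped coordinates.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("cannot compute the COM of an empty group")
    if masses is None:
        masses = np.ones(len(positions))
    masses = np.asarray(masses, dtype=float)
    w = masses / masses.sum()
    if box is None:
        return (positions * w[:, None]).sum(axis=0)
    box = np.asarray(box, dtype=float)
    theta = 2.0 * np.pi * positions / box
    cbar = (np.cos(theta) * w[:, None]).sum(axis=0)
    sbar = (np.sin(theta) * w[:, None]).sum(axis=0)
    ang = np.arctan2(sbar, cbar)
    return np.mod(ang / (2.0 * np.pi), 1.0) * box


@dataclass
class Frame:
    """One configuration: positions, orthorhombic box, per-bead metadata."""

    positions: np.ndarray
    box: np.ndarray | None
    beads: pd.DataFrame

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be positive")
        if len(self.beads) != len(self.positions):
            raise ValueError(
                f"bead table has {len(self.beads)} rows but positions has "
                f"{len(self.positions)} entries"
            )
        self.beads = self.beads.reset_index(drop=True)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrapped(self) -> np.ndarray:
        if self.box is None:
            return self.positions.copy()
        return wrap_positions(self.positions, self.box)

    def masses(self, indices: np.ndarray | None = None) -> np.ndarray:
        m = self.beads["mass"].to_numpy(dtype=float)
        return m if indices is None else m[indices]

    def select(
        self,
        role: str | set | None = None,
        molecule_kind: str | set | None = None,
        molecule_id: int | set | None = None,
    ) -> np.ndarray:
        """Bead indices matching every given criterion."""
        mask = np.ones(self.n_beads, dtype=bool)

        def _match(column, value):
            if isinstance(value, (set, frozenset, list, tuple)):
                return self.beads[column].isin(list(value)).to_numpy()
            return (self.beads[column] == value).to_numpy()

        if role is not None:
            mask &= _match("role", role)
        if molecule_kind is not None:
            mask &= _match("molecule_kind", molecule_kind)
        if molecule_id is not None:
            mask &= _match("molecule_id", molecule_id)
        return np.flatnonzero(mask)

    def total_charge(self) -> float:
        return float(self.beads["charge"].sum())

    def copy(self) -> "Frame":
        return Frame(
            self.positions.copy(),
            None if self.box is None else self.box.copy(),
            self.beads.copy(),
        )


@dataclass
class Trajectory:
    """An ordered sequence of frames at strictly increasing times (ns)."""

    frames: list
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        counts = {f.n_beads for f in self.frames}
        if len(counts) > 1:
            raise ValueError("bead count must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def window(self, last_fraction: float | None = None) -> "Trajectory":
        """The trailing portion of the trajectory (analysis window)."""
        if last_fraction is None:
            return self
        if not 0 < last_fraction <= 1:
            raise ValueError("last_fraction must be in (0, 1]")
        n = max(1, int(round(last_fraction * len(self.frames))))
        return Trajectory(self.frames[-n:], self.times[-n:])
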