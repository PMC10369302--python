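"""Electrode-grid geometry, recording container, and HDF5 I/O.

The sensing array is a regular rectangular lattice of square electrodes.
All downstream distance computations (soma centroids, conduction distances,
propagation areas) derive from the electrode center positions stored here.

Default geometry follows the 236,880-electrode CMOS array: 11.22 µm square
electrodes separated by 0.25 µm (pitch 11.47 µm) covering a 5.5 x 5.9 mm
sensing area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

#: electrode side length, µm
ELECTRODE_SIDE_UM = 11.22
#: gap between adjacent electrode edges, µm
ELECTRODE_SEPARATION_UM = 0.25
#: center-to-center pitch, µm
DEFAULT_PITCH_UM = ELECTRODE_SIDE_UM + ELECTRODE_SEPARATION_UM
#: sensing-area dimensions, mm (figure-level values)
SENSING_AREA_MM = (5.5, 5.9)
#: sensing-area dimensions, mm (methods-level values)
SENSING_AREA_MM_PRECISE = (5.51, 5.91)
#: electrode count of the full array
FULL_ARRAY_N_ELECTRODES = 236880


class GeometryError(ValueError):
    """Invalid grid geometry."""


class FormatError(ValueError):
    """Malformed recording container."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular lattice of square electrodes.

    Electrode indexing is row-major and 0-based:
    ``index = row * n_cols + col``.

    Attributes
    ----------
    n_rows, n_cols : int
        Lattice dimensions.
    pitch : float
        Center-to-center spacing, µm.
    electrode_side : float
        Electrode edge length, µm.
    """

    n_rows: int
    n_cols: int
    pitch: float = DEFAULT_PITCH_UM
    electrode_side: float = ELECTRODE_SIDE_UM

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid dimensions must be >= 1")
        if not (self.pitch >= self.electrode_side > 0):
            raise GeometryError("require pitch >= electrode_side > 0")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def positions(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) electrode centers in µm.

        x runs along columns, y along rows; origin at electrode 0.
        """
        rows, cols = np.divmod(np.arange(self.n_electrodes), self.n_cols)
        return np.column_stack([cols * self.pitch, rows * self.pitch]).astype(float)

    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, idx: int) -> tuple[int, int]:
        if not (0 <= idx < self.n_electrodes):
            raise IndexError(f"electrode index {idx} out of range")
        return divmod(idx, self.n_cols)

    def position(self, idx: int) -> np.ndarray:
        row, col = self.rowcol(idx)
        return np.array([col * self.pitch, row * self.pitch], dtype=float)

    def distance(self, i: int, j: int) -> float:
        """Euclidean center-to-center distance in µm."""
        return float(np.linalg.norm(self.position(i) - self.position(j)))

    def neighbors(self, idx: int) -> set[int]:
        """The <= 8 lattice neighbors of an electrode (Moore neighborhood)."""
        row, col = self.rowcol(idx)
        out = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r, c = row + dr, col + dc
                if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                    out.add(r * self.n_cols + c)
        return out

    def interior_electrodes(self) -> np.ndarray:
        """Indices of electrodes with a full 8-neighborhood."""
        if self.n_rows < 3 or self.n_cols < 3:
            return np.array([], dtype=int)
        rows = np.arange(1, self.n_rows - 1)
        cols = np.arange(1, self.n_cols - 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return (rr * self.n_cols + cc).ravel()

    def density(self, area_mm: tuple[float, float] | None = None) -> float:
        """Fraction of the sensing area covered by electrode metal.

        Parameters
        ----------
        area_mm : (width, height) in mm, optional
            Sensing-area dimensions. Defaults to the grid's own bounding
            area (n_cols x n_rows cells of pitch^2).
        """
        metal = self.n_electrodes * (self.electrode_side * 1e-3) ** 2  # mm^2
        if area_mm is None:
            area = (self.n_cols * self.pitch * 1e-3) * (self.n_rows * self.pitch * 1e-3)
        else:
            area = area_mm[0] * area_mm[1]
        return metal / area


def make_grid(
    n_rows: int,
    n_cols: int,
    pitch: float = DEFAULT_PITCH_UM,
    electrode_side: float = ELECTRODE_SIDE_UM,
) -> ElectrodeGrid:
    """Construct a regular electrode lattice (see :class:`ElectrodeGrid`)."""
    return ElectrodeGrid(n_rows=n_rows, n_cols=n_cols, pitch=pitch, electrode_side=electrode_side)


def electrode_density_pct(
    n_electrodes: int = FULL_ARRAY_N_ELECTRODES,
    electrode_side: float = ELECTRODE_SIDE_UM,
    area_mm: tuple[float, float] = SENSING_AREA_MM,
) -> float:
    """Electrode-metal coverage of the sensing area, in percent.

    With the full-array defaults (236880 electrodes of 11.22 µm side over
    5.5 x 5.9 mm) this evaluates to 91.9%.
    """
    return 100.0 * n_electrodes * (electrode_side * 1e-3) ** 2 / (area_mm[0] * area_mm[1])


@dataclass
class Recording:
    """Multichannel voltage recording on an electrode grid.

    Attributes
    ----------
    grid : ElectrodeGrid
    sampling_rate : float, Hz
    data : (n_electrodes, n_samples) voltage matrix, µV
    """

    grid: ElectrodeGrid
    sampling_rate: float
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError("data must be 2-D (electrodes x samples)")
        if self.data.shape[0] != self.grid.n_electrodes:
            raise FormatError(
                f"data has {self.data.shape[0]} rows but grid has "
                f"{self.grid.n_electrodes} electrodes"
            )
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("voltage matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class RegionMask:
    """Named electrode subset (stands in for an anatomical region)."""

    label: str
    electrodes: frozenset[int]

    def validate(self, grid: ElectrodeGrid) -> None:
        bad = [e for e in self.electrodes if not (0 <= e < grid.n_electrodes)]
        if bad:
            raise GeometryError(f"region '{self.label}' has invalid electrodes: {bad[:5]}")

    def to_json(self) -> str:
        return json.dumps({"label": self.label, "electrodes": sorted(self.electrodes)})

    @classmethod
    def from_json(cls, s: str) -> "RegionMask":
        d = json.loads(s)
        return cls(label=d["label"], electrodes=frozenset(d["electrodes"]))


_REQUIRED_ATTRS = ("sampling_rate", "n_rows", "n_cols", "pitch", "electrode_side")


def write_recording(rec: Recording, path) -> None:
    """Write a recording to an HDF5 container.

    Layout: /voltage (electrode-major, chunked), /meta JSON string, grid and
    rate as root attributes. Round-trips voltages bit-exactly.
    """
    with h5py.File(path, "w") as f:
        n_el, n_samp = rec.data.shape
        chunk = (1, min(n_samp, 65536))
        f.create_dataset("voltage", data=rec.data, chunks=chunk)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["n_rows"] = rec.grid.n_rows
        f.attrs["n_cols"] = rec.grid.n_cols
        f.attrs["pitch"] = rec.grid.pitch
        f.attrs["electrode_side"] = rec.grid.electrode_side
        f.create_dataset("meta", data=json.dumps(rec.meta))


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        Naming the missing field when the container is malformed.
    """
    with h5py.File(path, "r") as f:
        if "voltage" not in f:
            raise FormatError("container missing dataset 'voltage'")
        for a in _REQUIRED_ATTRS:
            if a not in f.attrs:
                raise FormatError(f"container missing attribute '{a}'")
        grid = ElectrodeGrid(
            n_rows=int(f.attrs["n_rows"]),
            n_cols=int(f.attrs["n_cols"]),
            pitch=float(f.attrs["pitch"]),
            electrode_side=float(f.attrs["electrode_side"]),
        )
        rate = float(f.attrs["sampling_rate"])
        data = f["voltage"][...]
        meta = json.loads(f["meta"][()]) if "meta" in f else {}
    return Recording(grid=grid, sampling_rate=rate, data=data, meta=meta)
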