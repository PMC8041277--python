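"""Ensemble-derived volumetric density maps and OpenDX grid I/O.

The docking representation is a scalar field on a regular, axis-aligned grid,
built by frame-averaging a Gaussian kernel density over a conformational
ensemble and normalizing the result so its maximum is 1.  The field plays the
role of an ensemble "influence" map: regions visited persistently by atoms
across frames carry high intensity, floppy or rarely visited regions decay
smoothly towards zero.  The published influence-density formulation (which
additionally folds in electrostatics) is deliberately kept behind the same
interface so it can be substituted without touching the rest of the pipeline.

Map files use the OpenDX "general array" regular-grid dialect with positive,
isotropic, axis-aligned deltas; anything else is rejected rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import MapParseError, UnsupportedDialectError
from .structio import Ensemble, StructureModel

#: Kernel support radius in units of sigma; the truncated mass is < 1e-4.
_KERNEL_CUTOFF_SIGMAS = 4.0


@dataclass
class VolumetricMap:
    """Scalar field on a regular grid.

    ``origin`` is the position (A) of the *center* of voxel ``[0, 0, 0]``;
    ``spacing`` the voxel edge length (A); ``values`` a non-negative 3D array
    indexed ``[ix, iy, iz]``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("values must be a 3D array, >= 2 voxels per axis")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("map values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis."""
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.values.shape[d])
            for d in range(3)
        )

    def integral(self) -> float:
        """Riemann-sum integral of the field over the grid (A^3 units)."""
        return float(self.values.sum() * self.spacing ** 3)

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            self.axes(), self.values, method="linear",
            bounds_error=False, fill_value=0.0,
        )


@dataclass
class DensityParams:
    """Parameters of the ensemble density model.

    grid_spacing : voxel edge, A.
    kernel_sigma : Gaussian kernel width, A.  1.8 A blurs atoms on roughly
        the scale of a heavy-atom van der Waals radius.
    atom_weighting : ``"uniform"`` (each atom counts 1) or ``"mass"``.
    padding : margin added around the ensemble bounding box, A; must cover
        the kernel tails (>= 4 sigma recommended).
    isovalue : cutoff on the max-normalized map used for surface extraction.
    """

    grid_spacing: float = 1.0
    kernel_sigma: float = 1.8
    atom_weighting: str = "uniform"
    padding: float = 8.0
    isovalue: float = 0.5

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.kernel_sigma <= 0 or self.padding <= 0:
            raise ValueError("grid_spacing, kernel_sigma, padding must be > 0")
        if not 0.0 < self.isovalue < 1.0:
            raise ValueError("isovalue must lie in (0, 1) for normalized maps")
        if self.atom_weighting not in ("uniform", "mass"):
            raise ValueError(f"unknown atom_weighting {self.atom_weighting!r}")


def build_density_map(topology: StructureModel, ens: Ensemble,
                      p: DensityParams | None = None,
                      max_normalize: bool = True) -> VolumetricMap:
    """Frame-averaged Gaussian kernel density of an ensemble.

    The value at a voxel center x is ``(1/F) sum_f sum_a w_a G(x - r_fa)``
    with ``G`` an isotropic Gaussian of width ``kernel_sigma`` (truncated at
    4 sigma) and ``w_a`` the atom weight.  With ``max_normalize`` (default)
    the array is then scaled so its maximum is exactly 1, which is the form
    the isovalue refers to.  Before normalization the integral of the field
    equals the total atom weight (up to truncation and discretization error).
    """
    p = p or DensityParams()
    if ens.n_atoms != topology.n_atoms:
        raise ValueError("ensemble is not congruent with topology")
    frames = ens.frames
    if p.atom_weighting == "mass":
        weights = topology.masses()
    else:
        weights = np.ones(topology.n_atoms)

    lo = frames.reshape(-1, 3).min(axis=0) - p.padding
    hi = frames.reshape(-1, 3).max(axis=0) + p.padding
    n = np.maximum(np.ceil((hi - lo) / p.grid_spacing).astype(int) + 1, 2)
    origin = lo
    axes = [origin[d] + p.grid_spacing * np.arange(n[d]) for d in range(3)]
    values = np.zeros(tuple(n), dtype=np.float64)

    sig2 = 2.0 * p.kernel_sigma ** 2
    cutoff = _KERNEL_CUTOFF_SIGMAS * p.kernel_sigma
    # Gaussian normalization so each atom contributes w_a to the integral
    norm = 1.0 / (2.0 * np.pi * p.kernel_sigma ** 2) ** 1.5

    for frame in frames:
        for r, w in zip(frame, weights):
            sub, gs = [], []
            for d in range(3):
                i0 = int(np.searchsorted(axes[d], r[d] - cutoff, side="left"))
                i1 = int(np.searchsorted(axes[d], r[d] + cutoff, side="right"))
                i0, i1 = max(i0, 0), min(i1, n[d])
                if i1 <= i0:
                    break
                d2 = (axes[d][i0:i1] - r[d]) ** 2
                sub.append((i0, i1))
                gs.append(np.exp(-d2 / sig2))
            else:
                block = w * norm * np.einsum("i,j,k->ijk", *gs)
                values[sub[0][0]:sub[0][1],
                       sub[1][0]:sub[1][1],
                       sub[2][0]:sub[2][1]] += block
    values /= ens.n_frames

    if max_normalize:
        peak = values.max()
        if peak <= 0:
            raise ValueError("density map is identically zero")
        values = values / peak
    return VolumetricMap(origin=origin, spacing=p.grid_spacing, values=values)


def map_value_at(m: VolumetricMap, points) -> np.ndarray | float:
    """Trilinear interpolation of the map; 0 outside the grid.

    Accepts a single 3-vector or an ``(n, 3)`` array.
    """
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    out = m.interpolator()(np.atleast_2d(pts))
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# OpenDX I/O
# ---------------------------------------------------------------------------

def write_dx(m: VolumetricMap, path) -> None:
    """Write a map in the OpenDX regular-grid dialect (C-order data)."""
    nx, ny, nz = m.shape
    d = m.spacing
    lines = [
        "# OpenDX density map written by tmdock",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {m.origin[0]:.6f} {m.origin[1]:.6f} {m.origin[2]:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz}"
        " data follows",
    ]
    flat = m.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.9g}" for v in flat[i:i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "density" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_dx(path) -> VolumetricMap:
    """Read an OpenDX regular-grid map.

    Only axis-aligned grids with one positive, isotropic delta per axis are
    supported; anything else raises :class:`UnsupportedDialectError`.
    """
    counts = origin = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    n_items = None
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_data and n_items is not None and len(data) < n_items:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                else:
                    data.extend(float(tok) for tok in line.split())
                    continue
            if line.startswith("object") and "gridpositions" in line:
                counts = [int(t) for t in line.split()[-3:]]
            elif line.startswith("origin"):
                origin = np.array([float(t) for t in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append(np.array([float(t) for t in line.split()[1:4]]))
            elif line.startswith("object") and "data follows" in line:
                toks = line.split()
                n_items = int(toks[toks.index("items") + 1])
                in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise MapParseError(f"{path} is not a parseable OpenDX grid file")
    D = np.array(deltas)
    diag = np.diagonal(D)
    if not np.allclose(D, np.diag(diag), atol=1e-9):
        raise UnsupportedDialectError("grid axes are not axis-aligned")
    if diag.min() <= 0 or not np.allclose(diag, diag[0], rtol=1e-9, atol=1e-9):
        raise UnsupportedDialectError(
            f"unsupported anisotropic/non-positive deltas {diag}"
        )
    if n_items is None or len(data) != n_items or n_items != np.prod(counts):
        raise MapParseError(f"{path}: expected {n_items} data items, "
                            f"got {len(data)}")
    values = np.asarray(data).reshape(counts, order="C")
    return VolumetricMap(origin=origin, spacing=float(diag[0]), values=values)
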