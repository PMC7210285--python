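"""Volumetric grid data model and Gaussian-cube / XYZ file I/O.

All in-memory quantities are in Hartree atomic units: lengths in Bohr,
densities in e/bohr**3.  Unit conversion happens only here, at the file
boundary.  Cube values are stored so that ``values[i, j, k]`` is the scalar
at ``origin + i*a1 + j*a2 + k*a3`` (third index fastest in the file, i.e.
C order), matching the Gaussian cube convention.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

__all__ = [
    "BOHR_PER_ANGSTROM",
    "Geometry",
    "ScalarGrid",
    "CubeParseError",
    "read_cube",
    "write_cube",
    "read_xyz",
    "write_xyz",
]

log = logging.getLogger(__name__)

#: CODATA conversion constant, 1 Angstrom in Bohr.
BOHR_PER_ANGSTROM = 1.8897259886

# Minimal symbol <-> Z table (H..Xe); volumetric densities of heavier
# elements are rare in the vdW-contact literature this tool targets.
_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}


class CubeParseError(ValueError):
    """Raised when a cube file deviates from the Gaussian cube convention."""


@dataclasses.dataclass(frozen=True)
class Geometry:
    """Nuclear framework: the nuclei whose QTAIM basins are resolved.

    Attributes
    ----------
    elements : tuple of str
        Chemical symbols.
    Z : ndarray of int
        Atomic numbers, one per atom.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian nuclear positions in Bohr.
    """

    elements: tuple
    Z: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=int))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != len(self.coords) or len(self.Z) != len(self.coords):
            raise ValueError("elements, Z and coords must have equal length")
        if np.any(self.Z < 1):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_symbols(cls, elements, coords_bohr) -> "Geometry":
        Z = []
        for sym in elements:
            try:
                Z.append(SYMBOL_TO_Z[sym])
            except KeyError:
                raise ValueError(
                    f"unknown element symbol {sym!r}; supported: "
                    + " ".join(_SYMBOLS)
                ) from None
        return cls(tuple(elements), np.array(Z), np.asarray(coords_bohr, float))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclasses.dataclass
class ScalarGrid:
    """A scalar field sampled on a (generally oblique) regular 3-D lattice.

    Attributes
    ----------
    origin : ndarray, shape (3,)
        Position of voxel (0, 0, 0) in Bohr.
    axes : ndarray, shape (3, 3)
        Row i is the step vector of grid axis i, in Bohr.
    values : ndarray, shape (n1, n2, n3)
        One scalar per voxel; densities in e/bohr**3.
    periodic : bool
        Whether the lattice tiles space (plane-wave densities) or is an
        isolated box (localized-basis densities).  The cube format cannot
        express this, so it is carried as a flag.
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    periodic: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if min(self.values.shape) < 1:
            raise ValueError("grid shape entries must be positive")
        if abs(np.linalg.det(self.axes)) <= 0.0:
            raise ValueError("grid axes are singular (voxel volume is zero)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must all be finite")
        if not np.all(np.isfinite(self.origin)) or not np.all(np.isfinite(self.axes)):
            raise ValueError("grid origin/axes must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume(self) -> float:
        """|det(axes)| in bohr**3."""
        return float(abs(np.linalg.det(self.axes)))

    def lattice_coords(self) -> np.ndarray:
        """Cartesian coordinates of every voxel, shape (n_voxels, 3), C order."""
        n1, n2, n3 = self.shape
        i, j, k = np.meshgrid(
            np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"
        )
        frac = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
        return self.origin + frac @ self.axes

    def point_to_fractional(self, points) -> np.ndarray:
        """Map Cartesian points to (possibly non-integer) grid indices."""
        p = np.atleast_2d(np.asarray(points, float))
        return (p - self.origin) @ np.linalg.inv(self.axes)

    def containing_voxel(self, points) -> np.ndarray:
        """Flat index of the voxel whose center is nearest each point."""
        frac = np.rint(self.point_to_fractional(points)).astype(np.int64)
        shape = np.array(self.shape)
        if self.periodic:
            frac %= shape
        else:
            frac = np.clip(frac, 0, shape - 1)
        return np.ravel_multi_index((frac[:, 0], frac[:, 1], frac[:, 2]), self.shape)

    def like(self, values: np.ndarray) -> "ScalarGrid":
        """A new grid with the same lattice carrying different values."""
        return ScalarGrid(self.origin.copy(), self.axes.copy(),
                          np.asarray(values, float).reshape(self.shape),
                          self.periodic)


def _parse_axis_line(line: str, lineno: int):
    parts = line.split()
    if len(parts) != 4:
        raise CubeParseError(
            f"line {lineno}: expected 'count vx vy vz', got {line.rstrip()!r}"
        )
    try:
        count = int(parts[0])
        vec = np.array([float(x) for x in parts[1:]])
    except ValueError:
        raise CubeParseError(
            f"line {lineno}: non-numeric axis entry in {line.rstrip()!r}"
        ) from None
    return count, vec


def read_cube(path, periodic: bool = False):
    """Read a Gaussian cube file.

    Returns ``(Geometry, ScalarGrid)`` with everything converted to Bohr.
    Negative axis voxel counts signal the Angstrom dialect for that axis
    (the widespread convention); positive counts mean Bohr.  A negative
    atom count (molecular-orbital cubes) is accepted: the orbital id line
    is skipped and the first data block is read.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise CubeParseError(f"{path}: fewer than 6 header lines")

    parts = lines[2].split()
    if len(parts) < 4:
        raise CubeParseError(f"line 3: expected 'natoms ox oy oz', got {lines[2]!r}")
    try:
        natoms_field = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
    except ValueError:
        raise CubeParseError(f"line 3: non-numeric entry in {lines[2]!r}") from None
    natoms = abs(natoms_field)

    counts, axes, angstrom = [], [], []
    for ax in range(3):
        count, vec = _parse_axis_line(lines[3 + ax], 4 + ax)
        if count == 0:
            raise CubeParseError(f"line {4 + ax}: zero voxel count")
        angstrom.append(count < 0)
        if count < 0:
            vec = vec * BOHR_PER_ANGSTROM
            count = -count
        counts.append(count)
        axes.append(vec)
    if all(angstrom):
        origin = origin * BOHR_PER_ANGSTROM
    if any(angstrom):
        log.info("cube %s: axis counts negative -> converted from Angstrom to Bohr",
                 path)

    elements, Zs, coords = [], [], []
    for a in range(natoms):
        lineno = 7 + a
        if 6 + a >= len(lines):
            raise CubeParseError(
                f"line {lineno}: expected {natoms} atom records, file ended after "
                f"{a}"
            )
        parts = lines[6 + a].split()
        if len(parts) < 5:
            raise CubeParseError(
                f"line {lineno}: expected 'Z charge x y z', got "
                f"{lines[6 + a].rstrip()!r}"
            )
        try:
            Z = int(float(parts[0]))
            xyz = [float(x) for x in parts[2:5]]
        except ValueError:
            raise CubeParseError(
                f"line {lineno}: non-numeric atom record {lines[6 + a].rstrip()!r}"
            ) from None
        if Z < 1:
            raise CubeParseError(f"line {lineno}: atomic number {Z} < 1")
        Zs.append(Z)
        elements.append(Z_TO_SYMBOL.get(Z, f"Z{Z}"))
        coords.append(xyz)

    first_data = 6 + natoms
    if natoms_field < 0:  # MO cube: skip the orbital-id line
        first_data += 1

    raw = []
    for lineno, line in enumerate(lines[first_data:], start=first_data + 1):
        for tok in line.split():
            try:
                raw.append(float(tok))
            except ValueError:
                raise CubeParseError(
                    f"line {lineno}: non-numeric value {tok!r}"
                ) from None
    nvox = counts[0] * counts[1] * counts[2]
    if len(raw) < nvox:
        raise CubeParseError(
            f"{path}: expected {nvox} voxel values, found {len(raw)}"
        )
    values = np.array(raw[:nvox]).reshape(counts)

    geom = Geometry(tuple(elements), np.array(Zs), np.array(coords, float))
    grid = ScalarGrid(origin, np.array(axes), values, periodic=periodic)
    return geom, grid


def write_cube(geometry: Geometry, grid: ScalarGrid, path,
               comment: str = "generated by vsf") -> None:
    """Write a Gaussian cube file (Bohr, positive axis counts, 6 values/line).

    Values are printed in scientific notation with 6 digits after the point,
    so a write/read round trip preserves them to ~1e-6 relative.
    """
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("refusing to write a grid containing non-finite values")
    if geometry.n_atoms < 1:
        raise ValueError("cube format requires at least one atom record")
    n1, n2, n3 = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("scalar field in e/bohr^3 on a Bohr lattice\n")
        fh.write(f"{geometry.n_atoms:5d} {grid.origin[0]:12.6f} "
                 f"{grid.origin[1]:12.6f} {grid.origin[2]:12.6f}\n")
        for count, vec in zip((n1, n2, n3), grid.axes):
            fh.write(f"{count:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}\n")
        for Z, xyz in zip(geometry.Z, geometry.coords):
            fh.write(f"{Z:5d} {float(Z):12.6f} {xyz[0]:12.6f} "
                     f"{xyz[1]:12.6f} {xyz[2]:12.6f}\n")
        flat = grid.values.ravel()  # C order: third index fastest
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write(" ".join(f"{v: .6E}" for v in chunk) + "\n")


def read_xyz(path) -> Geometry:
    """Read a standard XYZ file (count line, comment, 'El x y z' in Angstrom).

    Coordinates are converted to Bohr.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must be the atom count") from None
    records = [l for l in lines[2:] if l.strip()]
    if len(records) < count:
        raise ValueError(
            f"{path}: atom count {count} but only {len(records)} atom lines"
        )
    elements, coords = [], []
    for line in records[:count]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {line.rstrip()!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    coords = np.array(coords, float) * BOHR_PER_ANGSTROM
    return Geometry.from_symbols(elements, coords)


def write_xyz(geometry: Geometry, path, extra_column=None,
              comment: str = "written by vsf") -> None:
    """Write XYZ in Angstrom, optionally with one extra per-atom column
    (used to carry VSF% for coloring in external viewers)."""
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        coords = geometry.coords / BOHR_PER_ANGSTROM
        for i, (el, xyz) in enumerate(zip(geometry.elements, coords)):
            line = f"{el:2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}"
            if extra_column is not None:
                line += f" {extra_column[i]:12.6f}"
            fh.write(line + "\n")
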