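"""Analytic model densities with closed-form derivatives.

These serve two roles: (i) synthetic stand-ins for externally computed
electron densities, so the whole pipeline can be exercised without any
quantum-chemistry code, and (ii) oracles — every derivative the
finite-difference machinery produces can be checked against a closed form.

Two families are provided:

* :class:`GaussianDensity` — a sum of spherical Gaussian "atoms"
  ``rho_a(r) = n * (alpha/pi)^{3/2} * exp(-alpha |r-c|^2)``, each
  integrating exactly to ``n`` electrons.  The isotropic decay makes every
  field (gradient, Hessian eigenvalues, RDG) analytic and simple.
* :class:`PromolecularDensity` — a sum of unrelaxed spherical atomic
  densities built from 1-2 exponential shells per element
  ``c * exp(-r/zeta)``, the classic cheap surrogate used for NCI-style
  reduced-density-gradient analysis.  The built-in shell table (H, C, N,
  O) is an approximate Slater-like fit shipped with the package; each
  atom's density integrates exactly to its electron count Z.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .grid_io import Geometry, ScalarGrid, Z_TO_SYMBOL

__all__ = [
    "GaussianAtom",
    "GaussianDensity",
    "PromolecularDensity",
    "PROMOLECULAR_SHELLS",
    "density_at",
    "sample_to_grid",
    "make_vdw_dimer_fixture",
    "symmetric_fixture_grid",
    "BoundaryDensityWarning",
]


class BoundaryDensityWarning(UserWarning):
    """Grid boundary density too high for the closed-system contract."""


@dataclasses.dataclass(frozen=True)
class GaussianAtom:
    """One spherical Gaussian charge: center (Bohr), exponent alpha
    (1/bohr^2), electrons contributed."""

    center: np.ndarray
    alpha: float
    nelec: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center",
                           np.asarray(self.center, float).reshape(3))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.nelec <= 0:
            raise ValueError("nelec must be positive")

    @property
    def prefactor(self) -> float:
        return self.nelec * (self.alpha / np.pi) ** 1.5


class GaussianDensity:
    """Sum of :class:`GaussianAtom` terms with closed-form rho, grad,
    Hessian and Laplacian.

    For one term, with d = r - c and rho its density value:
    grad = -2*alpha*d*rho,  H = (4*alpha^2 * d d^T - 2*alpha*I) * rho,
    lap = (4*alpha^2 |d|^2 - 6*alpha) * rho.
    """

    def __init__(self, atoms):
        self.atoms = list(atoms)

    @property
    def total_electrons(self) -> float:
        return float(sum(a.nelec for a in self.atoms))

    def rho(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(p))
        for a in self.atoms:
            d2 = np.sum((p - a.center) ** 2, axis=1)
            out += a.prefactor * np.exp(-a.alpha * d2)
        return out

    def rho_grad_lap(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        rho = np.zeros(len(p))
        grad = np.zeros_like(p)
        lap = np.zeros(len(p))
        for a in self.atoms:
            d = p - a.center
            d2 = np.sum(d * d, axis=1)
            r = a.prefactor * np.exp(-a.alpha * d2)
            rho += r
            grad += -2.0 * a.alpha * d * r[:, None]
            lap += (4.0 * a.alpha**2 * d2 - 6.0 * a.alpha) * r
        return rho, grad, lap

    def hessian(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        H = np.zeros((len(p), 3, 3))
        eye = np.eye(3)
        for a in self.atoms:
            d = p - a.center
            d2 = np.sum(d * d, axis=1)
            r = a.prefactor * np.exp(-a.alpha * d2)
            outer = d[:, :, None] * d[:, None, :]
            H += (4.0 * a.alpha**2 * outer - 2.0 * a.alpha * eye) * r[:, None, None]
        return H


# Approximate Slater-like promolecular shells: element -> ((nelec, zeta), ...)
# with radial density  sum_i  c_i * exp(-r/zeta_i),  c_i = n_i/(8*pi*zeta_i^3)
# so each shell integrates to n_i electrons.  Hydrogen is the exact ground
# state; heavier elements use a core + valence split with decay lengths of
# Slater-screening magnitude.  This is a shipped fixture table, adequate for
# promolecular RDG analysis, not a reference atomic density.
PROMOLECULAR_SHELLS = {
    "H": ((1.0, 0.5),),
    "C": ((2.0, 0.0887), (4.0, 0.64)),
    "N": ((2.0, 0.0770), (5.0, 0.55)),
    "O": ((2.0, 0.0680), (6.0, 0.49)),
}


class PromolecularDensity:
    """Promolecular density: superposition of spherical exponential-shell
    atoms placed at a :class:`~vsf.grid_io.Geometry`."""

    #: below this radius (Bohr) the exponential cusp is evaluated at r_min
    #: to keep gradient/Hessian finite
    r_min = 1e-12

    def __init__(self, geometry: Geometry, shells=None):
        self.geometry = geometry
        table = shells if shells is not None else PROMOLECULAR_SHELLS
        self._shells = []
        for el in geometry.elements:
            if el not in table:
                raise ValueError(
                    f"no promolecular shells for element {el!r}; available: "
                    + " ".join(sorted(table))
                )
            self._shells.append(tuple(table[el]))

    @property
    def total_electrons(self) -> float:
        return float(sum(n for sh in self._shells for n, _ in sh))

    def _per_atom(self, points):
        """Yield (unit radial vectors, r, f, f', f'') per atom, summed over
        shells, where f(r) is the atomic radial density."""
        p = np.atleast_2d(np.asarray(points, float))
        for center, sh in zip(self.geometry.coords, self._shells):
            d = p - center
            r = np.sqrt(np.sum(d * d, axis=1))
            rc = np.maximum(r, self.r_min)
            f = np.zeros_like(r)
            fp = np.zeros_like(r)
            fpp = np.zeros_like(r)
            for n, zeta in sh:
                c = n / (8.0 * np.pi * zeta**3)
                e = c * np.exp(-rc / zeta)
                f += e
                fp += -e / zeta
                fpp += e / zeta**2
            yield d, rc, f, fp, fpp

    def rho(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(p))
        for _, _, f, _, _ in self._per_atom(p):
            out += f
        return out

    def rho_grad_lap(self, points):
        """rho, grad and Laplacian at Cartesian points.

        Exactly at a nucleus the cusp leaves the gradient direction
        undefined; the limiting magnitude |f'(0)| is returned along +z so
        that cusp-limit diagnostics (notably the RDG) stay continuous.
        """
        p = np.atleast_2d(np.asarray(points, float))
        rho = np.zeros(len(p))
        grad = np.zeros_like(p)
        lap = np.zeros(len(p))
        for d, r, f, fp, fpp in self._per_atom(p):
            rho += f
            u = d / r[:, None]
            at_nucleus = np.linalg.norm(d, axis=1) < self.r_min
            u[at_nucleus] = [0.0, 0.0, 1.0]
            grad += fp[:, None] * u
            lap += fpp + 2.0 * fp / r
        return rho, grad, lap

    def hessian(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        H = np.zeros((len(p), 3, 3))
        eye = np.eye(3)
        for d, r, f, fp, fpp in self._per_atom(p):
            u = d / r[:, None]
            outer = u[:, :, None] * u[:, None, :]
            H += fpp[:, None, None] * outer
            H += (fp / r)[:, None, None] * (eye - outer)
        return H


def density_at(model, points):
    """Evaluate (rho, grad, laplacian) of a model density at Cartesian
    points (Bohr).  Shapes: (N,), (N, 3), (N,)."""
    return model.rho_grad_lap(points)


def sample_to_grid(model, origin, axes, shape, periodic: bool = False,
                   boundary_tol: float = 1e-8) -> ScalarGrid:
    """Sample a model density onto a lattice.

    The closed-system contract requires the density to have decayed at the
    box boundary; if the maximum face density exceeds ``boundary_tol``
    (e/bohr^3) a :class:`BoundaryDensityWarning` names the value.
    """
    grid = ScalarGrid(np.asarray(origin, float), np.asarray(axes, float),
                      np.zeros(shape), periodic=periodic)
    coords = grid.lattice_coords()
    values = model.rho(coords).reshape(shape)
    grid.values = values
    if not periodic and min(shape) >= 2:
        faces = [values[0], values[-1], values[:, 0], values[:, -1],
                 values[:, :, 0], values[:, :, -1]]
        bmax = max(float(f.max()) for f in faces)
        if bmax > boundary_tol:
            warnings.warn(
                f"maximum boundary density {bmax:.3e} e/bohr^3 exceeds "
                f"{boundary_tol:.0e}; the closed-system (boundary at "
                "infinity) assumption is degraded",
                BoundaryDensityWarning,
            )
    return grid


def make_vdw_dimer_fixture(separation: float, alpha: float = 1.0,
                           nelec=(1.0, 1.0)):
    """Symmetric two-center Gaussian dimer emulating a vdW-bound pair.

    Centers sit at (+-separation/2, 0, 0).  The midpoint density
    ``sum_i n_i (alpha/pi)^{3/2} exp(-alpha (sep/2)^2)`` must fall below
    1e-3 e/bohr^3 (the upper edge of the vdW sampling window), otherwise
    the two atoms overlap too strongly to model a van der Waals contact
    and a ValueError cites the value.

    Returns ``(Geometry, GaussianDensity)``.
    """
    half = separation / 2.0
    mid_rho = sum(n * (alpha / np.pi) ** 1.5 * np.exp(-alpha * half**2)
                  for n in nelec)
    if mid_rho >= 1e-3:
        raise ValueError(
            f"separation {separation} too small: midpoint density "
            f"{mid_rho:.3e} e/bohr^3 >= 1e-3 (not a vdW-like contact)"
        )
    centers = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    atoms = [GaussianAtom(c, alpha, n) for c, n in zip(centers, nelec)]
    elements = tuple(Z_TO_SYMBOL.get(max(1, round(n)), "H") for n in nelec)
    geom = Geometry.from_symbols(elements, centers)
    return geom, GaussianDensity(atoms)


def symmetric_fixture_grid(model, spacing: float = 0.25, margin: float = 4.5,
                           geometry: Geometry | None = None) -> ScalarGrid:
    """Sample a model on an orthogonal grid symmetric about the origin.

    The lattice always contains the origin and mirror-image voxel pairs
    (odd voxel counts), so symmetric fixtures produce bitwise-symmetric
    grids — important when testing mirror-plane properties.  ``margin``
    (Bohr) pads beyond the outermost center on each axis.
    """
    if geometry is not None:
        centers = geometry.coords
    elif hasattr(model, "atoms"):
        centers = np.array([a.center for a in model.atoms]) \
            if model.atoms else np.zeros((1, 3))
    else:
        centers = model.geometry.coords
    half_extent = np.max(np.abs(centers), axis=0) + margin
    n_half = np.ceil(half_extent / spacing).astype(int)
    shape = tuple(2 * n_half + 1)
    origin = -n_half * spacing
    axes = np.diag([spacing] * 3)
    return sample_to_grid(model, origin, axes, shape)
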