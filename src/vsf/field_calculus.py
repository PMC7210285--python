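"""Density-derived fields: gradient, Hessian, Laplacian, RDG, NCI class.

The reduced density gradient

    s(r) = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})

is a dimensionless measure of the deviation from a homogeneous electron
gas; it vanishes at critical points and stays small over non-covalent
contact regions.  The interaction character at low-s points is read from
rho * sign(lambda2), with lambda2 the middle Hessian eigenvalue:
attractive (bonding) contacts have lambda2 < 0, steric clashes
lambda2 > 0, and van der Waals contacts lambda2 ~ 0, which motivates the
conventional +-0.02 a.u. band.

Grid derivatives use 4th-order central stencils in the interior and
2nd-order one-sided stencils at non-periodic boundaries; periodic grids
wrap.  Oblique lattices are handled by differentiating in fractional
coordinates and transforming with the inverse axis matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grid_io import ScalarGrid

__all__ = [
    "FieldBundle",
    "derivatives_fd",
    "field_bundle_from_model",
    "rdg",
    "hessian_eigen",
    "classify",
    "RHO_FLOOR",
    "LAMBDA2_SNAP",
]

#: densities below this (e/bohr^3) are treated as numerically zero; the
#: RDG there is reported as +inf and such voxels never enter vdW masks.
RHO_FLOOR = 1e-12

#: |lambda2| below this (e/bohr^5) is snapped to zero before taking its
#: sign (sign(0) := +1), since "lambda2 ~ 0" has no published tolerance.
LAMBDA2_SNAP = 1e-10

_RDG_CONST = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)


@dataclasses.dataclass
class FieldBundle:
    """All per-voxel fields derived from one density.

    rho (e/bohr^3), grad (..., 3) (e/bohr^4), laplacian (e/bohr^5),
    lambdas (..., 3) ascending Hessian eigenvalues (e/bohr^5),
    rdg (dimensionless, +inf where rho <= floor), signed_rho
    = rho * sign(lambda2) (a.u.).  ``grid`` keeps the lattice geometry.
    """

    grid: ScalarGrid
    rho: np.ndarray
    grad: np.ndarray
    laplacian: np.ndarray
    lambdas: np.ndarray
    rdg: np.ndarray
    signed_rho: np.ndarray

    @property
    def grad_norm(self) -> np.ndarray:
        return np.linalg.norm(self.grad, axis=-1)


def _d1(f: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """First derivative along one axis in index units (h = 1)."""
    if f.shape[axis] < 5:
        raise ValueError(
            f"axis {axis} has {f.shape[axis]} points; >= 5 required for "
            "the 5-point stencils"
        )
    f = np.moveaxis(f, axis, 0)
    out = np.empty_like(f)
    if periodic:
        fm2, fm1 = np.roll(f, 2, 0), np.roll(f, 1, 0)
        fp1, fp2 = np.roll(f, -1, 0), np.roll(f, -2, 0)
        out[:] = (fm2 - 8 * fm1 + 8 * fp1 - fp2) / 12.0
    else:
        out[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / 12.0
        out[0] = (-3 * f[0] + 4 * f[1] - f[2]) / 2.0
        out[1] = (f[2] - f[0]) / 2.0
        out[-2] = (f[-1] - f[-3]) / 2.0
        out[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / 2.0
    return np.moveaxis(out, 0, axis)


def _d2(f: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """Second derivative along one axis in index units (h = 1)."""
    if f.shape[axis] < 5:
        raise ValueError(
            f"axis {axis} has {f.shape[axis]} points; >= 5 required for "
            "the 5-point stencils"
        )
    f = np.moveaxis(f, axis, 0)
    out = np.empty_like(f)
    if periodic:
        fm2, fm1 = np.roll(f, 2, 0), np.roll(f, 1, 0)
        fp1, fp2 = np.roll(f, -1, 0), np.roll(f, -2, 0)
        out[:] = (-fm2 + 16 * fm1 - 30 * f + 16 * fp1 - fp2) / 12.0
    else:
        out[2:-2] = (-f[:-4] + 16 * f[1:-3] - 30 * f[2:-2]
                     + 16 * f[3:-1] - f[4:]) / 12.0
        out[0] = 2 * f[0] - 5 * f[1] + 4 * f[2] - f[3]
        out[1] = f[0] - 2 * f[1] + f[2]
        out[-2] = f[-3] - 2 * f[-2] + f[-1]
        out[-1] = 2 * f[-1] - 5 * f[-2] + 4 * f[-3] - f[-4]
    return np.moveaxis(out, 0, axis)


def rdg(rho, grad_norm, rho_floor: float = RHO_FLOOR):
    """Reduced density gradient; +inf sentinel where rho <= rho_floor."""
    rho = np.asarray(rho, float)
    grad_norm = np.asarray(grad_norm, float)
    out = np.full(np.broadcast(rho, grad_norm).shape, np.inf)
    ok = rho > rho_floor
    out[ok] = (np.broadcast_to(grad_norm, out.shape)[ok]
               / (_RDG_CONST * rho[ok] ** (4.0 / 3.0)))
    return out


def hessian_eigen(hessian, sym_tol: float = 1e-8):
    """Ascending eigenvalues (lambda1 <= lambda2 <= lambda3) of symmetric
    3x3 Hessians, batched over leading dimensions."""
    H = np.asarray(hessian, float)
    asym = np.max(np.abs(H - np.swapaxes(H, -1, -2)))
    scale = max(np.max(np.abs(H)), 1.0)
    if asym > sym_tol * scale:
        raise ValueError(
            f"Hessian asymmetric: max |H - H^T| = {asym:.3e} exceeds "
            f"tolerance {sym_tol:.0e} (relative to {scale:.3e})"
        )
    return np.linalg.eigvalsh(0.5 * (H + np.swapaxes(H, -1, -2)))


def _signed_rho(rho, lambdas, snap: float = LAMBDA2_SNAP):
    l2 = lambdas[..., 1].copy()
    l2[np.abs(l2) < snap] = 0.0
    sign = np.where(l2 < 0, -1.0, 1.0)  # sign(0) := +1
    return rho * sign


def classify(signed_rho, band: float = 0.02):
    """NCI class from rho*sign(lambda2): 'bonding' below -band, 'vdW'
    within [-band, band] (boundaries inclusive), 'repulsion' above."""
    x = np.asarray(signed_rho, float)
    out = np.where(x < -band, "bonding", np.where(x > band, "repulsion", "vdW"))
    return out if out.ndim else str(out)


def _bundle_from_parts(grid, rho, grad, lap, hessians,
                       lambda2_snap: float) -> FieldBundle:
    lambdas = hessian_eigen(hessians).reshape(grid.shape + (3,))
    s = rdg(rho, np.linalg.norm(grad, axis=-1))
    signed = _signed_rho(rho, lambdas, lambda2_snap)
    return FieldBundle(grid=grid, rho=rho, grad=grad, laplacian=lap,
                       lambdas=lambdas, rdg=s, signed_rho=signed)


def derivatives_fd(grid: ScalarGrid,
                   lambda2_snap: float = LAMBDA2_SNAP) -> FieldBundle:
    """Full field bundle from a gridded density by finite differences.

    The Laplacian is the trace of the Cartesian Hessian, so the
    eigenvalue sum reproduces it to rounding.
    """
    f = grid.values
    per = grid.periodic
    Ainv = np.linalg.inv(grid.axes)

    gu = np.stack([_d1(f, ax, per) for ax in range(3)], axis=-1)
    grad = gu @ Ainv  # d/dx_k = sum_i (A^-1)_{ik} d/du_i

    Hu = np.empty(grid.shape + (3, 3))
    for i in range(3):
        Hu[..., i, i] = _d2(f, i, per)
    for i in range(3):
        for j in range(i + 1, 3):
            Hu[..., i, j] = Hu[..., j, i] = _d1(gu[..., i], j, per)
    # H_x = A^-1 H_u A^-T
    Hx = np.einsum("ia,...ab,jb->...ij", Ainv.T, Hu, Ainv.T)
    lap = np.trace(Hx, axis1=-2, axis2=-1)
    return _bundle_from_parts(grid, f.copy(), grad, lap,
                              Hx.reshape(-1, 3, 3), lambda2_snap)


def field_bundle_from_model(model, grid: ScalarGrid,
                            lambda2_snap: float = LAMBDA2_SNAP) -> FieldBundle:
    """Field bundle with every derivative taken from the model's closed
    forms — the oracle route for the finite-difference path."""
    coords = grid.lattice_coords()
    rho, grad, lap = model.rho_grad_lap(coords)
    H = model.hessian(coords)
    return _bundle_from_parts(
        grid,
        rho.reshape(grid.shape),
        grad.reshape(grid.shape + (3,)),
        lap.reshape(grid.shape),
        H,
        lambda2_snap,
    )
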