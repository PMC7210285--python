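# Methods

`vsf` quantifies which atoms "source" the electron density inside a van
der Waals contact.  It combines three ingredients: QTAIM atomic basins
obtained by grid-based Bader partitioning, the NCI (reduced density
gradient) definition of the contact region, and the source function,
integrated over that region by Monte-Carlo sampling.

## Model and procedure

**Atomic basins.**  QTAIM partitions space into basins Ω, one per
nucleus, bounded by zero-flux surfaces of the density gradient
(∇ρ·n̂ = 0).  On a grid this is realized with the Yu–Trinkle weight
method: voxels are processed in order of descending density; a voxel
whose uphill flux all drains to one basin is assigned wholly to it,
while voxels straddling a boundary receive fractional weights
proportional to the density-difference-weighted flux through each voxel
facet.  Flux is exchanged through the six facet-sharing neighbors (the
Voronoi facets of a near-orthogonal lattice); local maxima are detected
against all 26 neighbors, with exact plateau ties broken by flat voxel
index so the partition is deterministic.  Voxels below 10⁻¹⁰ e/bohr³
are assigned whole to their steepest-ascent basin — their population is
negligible and skipping the fractional bookkeeping is much faster;
when several equally-steep neighbors tie bitwise (mirror-symmetric
grids) their weights are averaged, so exact symmetry survives.
Basin populations are the weight-contracted density quadrature; by
construction the per-voxel weights sum to one, so the populations
telescope exactly to the total grid quadrature.

**vdW volume.**  The reduced density gradient
s(r) = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}) vanishes at critical points and
stays small across non-covalent contacts.  The vdW volume V_vdW is the
set of voxels with s ≤ s_iso, ρ inside a low-density window, and
ρ·sign(λ₂) inside the vdW band, where λ₂ is the middle eigenvalue of
the density Hessian (λ₂ < 0 marks attraction, λ₂ > 0 steric clash,
λ₂ ≈ 0 dispersion).  Defaults: s_iso = 0.5, window
10⁻⁶ ≤ ρ ≤ 10⁻³ e/bohr³, band ±0.02 a.u.; the exact band edges ±0.02
are classed as vdW (a measure-zero choice fixed for reproducibility),
and |λ₂| below 10⁻¹⁰ is snapped to zero with sign(0) := +1 because no
published tolerance exists for "λ₂ ≈ 0" (the snap is a parameter).
Disjoint contacts are separated by 26-connected component labeling;
periodic grids merge components across faces, including diagonal wraps.

**Source function.**  For a density that decays at the boundary, the
Poisson Green identity reconstructs ρ at any point from the Laplacian:
ρ(r) = −(1/4π)∫ ∇²ρ(r′)/|r−r′| d³r′.  Restricting the integral to one
basin gives SF(r, Ω), the density at r sourced by Ω; negative-Laplacian
regions enrich ρ (sources), positive deplete it (sinks).  The
volumetric source function is the integral of SF over the vdW volume,
VSF(V_vdW, Ω) = ∫_{V_vdW} SF(r, Ω) d³r, estimated by Monte Carlo as
V_vdW · mean_i SF(r_i, Ω) over N points drawn uniformly from the voxel
union (voxel chosen uniformly, uniform jitter within it; points with
interpolated ρ < 10⁻⁶ e/bohr³ are rejected and redrawn).  A
Metropolis–Hastings sampler over member voxels (26-neighbor proposals,
uniform target, burn-in 100, thinning 5 — values not fixed by any
reference, chosen to damp the autocorrelation of the short-range walk)
is provided for convergence assessment.  Results are reported as
VSF% = 100·VSF/n_e and checked by the reliability parameter
f1 = 100·(n_e − Σ_Ω VSF)/n_e, with n_e the direct density quadrature
over V_vdW.  n_e is deliberately *not* the summed VSF, so f1 is a
genuine reconstruction check rather than a tautology.

## Numerical choices

**Derivatives.**  Grid derivatives use 4th-order central stencils in
the interior and 2nd-order one-sided stencils at non-periodic
boundaries; periodic grids wrap.  Oblique lattices are differentiated
in fractional coordinates and transformed with the inverse axis matrix.
The Laplacian is the trace of the Cartesian Hessian, so the eigenvalue
sum reproduces it to rounding.

**SF quadrature.**  The basin-restricted Green integral is a sum over
voxels of w(v,Ω)·∇²ρ(v)·V_voxel/|r−r_v| with no cutoff: every voxel
contributes to every evaluation.  Three refinements control its error,
which matters because vdW analysis reconstructs densities of order
10⁻⁵ e/bohr³ from a Laplacian of order 1:

1. *Near field* — cells within 1.5 step lengths of r are integrated on
   a 4³ subcell grid; a subcell whose center falls inside its own
   equal-volume-sphere radius contributes the sphere-rule value 2πR²,
   which removes the integrable 1/d singularity.
2. *Euler–Maclaurin correction* — the per-cell midpoint curvature
   errors (h²/24)∂²(lap/d) do not cancel globally: by the divergence
   theorem they aggregate to a bias of order h²·∇²ρ(r)/24.  The
   correction term is evaluated analytically for the kernel and by
   finite differences for the Laplacian, making the sum 4th-order
   accurate.
3. *Richardson extrapolation* — the same estimate on the 2×-subsampled
   grid (same pipeline: FD Laplacian, Yu–Trinkle partition seeded at
   the fine maxima) combines as (16·S_h − S_{2h})/15, cancelling the
   leading h⁴ term.  The evaluator falls back to the single-grid sum
   when the grid is too small to subsample or the coarse grid does not
   resolve the same maxima.

With all three, the Poisson identity on a unit-Gaussian fixture
(spacing 0.19 bohr) is reproduced to ~0.1 % at the density peak and
1–2 % at a contact-like point where ρ ≈ 4×10⁻⁵ e/bohr³.

**Consistent integrals.**  The Monte-Carlo estimator samples the true
within-voxel variation of SF, so its deterministic counterparts target
the same continuum integrals: n_e carries the per-voxel curvature term
Σᵢ hᵢ²(∂²ρ/∂xᵢ²)/24 (exactly zero for constant fields), and the
exhaustive oracle integrates SF per voxel with a composite 2-point
Gauss rule (subcell split up to 3³, auto-selected from the volume
size).  Without this the two routes disagree systematically on
strongly curved fixtures — by far more than the Monte-Carlo standard
error.

**Error diagnostic.**  The propagated RDG fluctuation
δs/s = (δρ/ρ)·√(1 + (4/3)²) is reported as a sampling-convergence
diagnostic only; its derivation collapses the gradient fluctuation onto
δρ/ρ and it should not be read as a rigorous error bar.

## Synthetic data

Externally computed densities enter only as cube files, so the test bed
is analytic: spherical Gaussian "atoms" ρ = n(α/π)^{3/2}e^{−α|r−c|²}
with closed-form gradient, Hessian and Laplacian, and a promolecular
model (sum of 1–2 exponential shells per element for H, C, N, O, each
integrating exactly to Z; hydrogen is the exact ground state, heavier
elements a core+valence split with Slater-magnitude decay lengths —
a shipped approximation, not a reference atomic density).

The standard fixture is a symmetric two-Gaussian "dimer" at separation
6 bohr with α = 1, whose midpoint density 2(1/π)^{3/2}e⁻⁹ ≈
4.4×10⁻⁵ e/bohr³ sits inside the vdW sampling window; grids are
odd-counted and mirror-symmetric so symmetry properties can be asserted
to rounding.  Construction enforces the closed-system contract
(boundary density < 10⁻⁸ e/bohr³, warned otherwise) and rejects
separations whose midpoint density reaches 10⁻³ e/bohr³.

What the fixtures do *not* emulate: nuclear cusps (Gaussians are
smooth; promolecular atoms have cusps but no shell structure),
self-consistent charge relaxation, static correlation, or the Fourier
ringing of plane-wave densities.  Passing tests therefore demonstrate
the correctness of the machinery — partitioning, masking, sampling,
integration, statistics — not the physical accuracy of any particular
electronic-structure input.  In particular the known degradation of
reconstruction quality for plane-wave densities in low-density regions
(f1 of tens of percent) is a property of such inputs that the package
reports (warning above a configurable f1 threshold, default 5 %) but
does not correct.

## Degenerate inputs and tie-breaks

Constant grids have no maxima and raise.  Exact density ties sort by
flat voxel index.  Voxels with all-equal facet neighbors inherit the
weights of their highest already-processed neighbor.  Empty vdW masks
warn and produce an empty report rather than an error.  ρ below
10⁻¹² e/bohr³ maps to an infinite-RDG sentinel that no mask can select.
Sampling from a volume whose admissible voxels all fall below the
density floor is an error, as is measuring an empty volume.

## Problem sizes

The shipped analyses run on grids of 0.125–0.375 bohr spacing
(≈ 25 000–900 000 voxels) with 10²–4×10³ Monte-Carlo points — sizes at
which every stage completes in seconds to a few minutes on one core,
while grid-refinement checks still have room to halve the spacing.
The per-point SF cost is linear in voxel count; the basin sweep is
effectively linear after an O(N log N) sort.

## Known limitations

* Yu–Trinkle flux prefactors and the Euler–Maclaurin kernel derivatives
  assume a near-orthogonal lattice; strongly sheared cells degrade both.
* Periodic densities are analyzed with the open-space 1/|r−r′| kernel;
  the surface term of the basin decomposition is dropped under the
  closed-system contract, so SF sums over a periodic cell reconstruct
  ρ only insofar as the density decays within the cell.
* Pseudo-valence (plane-wave) densities are integrated as given — no
  core augmentation; populations far from Z signal this.
* The promolecular shell table covers H, C, N, O only.
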