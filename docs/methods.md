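# Methods

## Model

`fiberlight` computes the stationary light-intensity field of an optical
fiber embedded in a homogeneous scattering medium, on a cylindrical (ρ, z)
grid, as the sum of a ballistic (direct) and a multiply-scattered
component.  The elementary object is an infinitesimal pencil beam; the
fiber field is assembled by two convolutions — angular (over the emission
cone) and spatial (over the disk-shaped emission face).

Assumptions: the medium is homogeneous and characterized by constant
(μₐ, μₛ, g, n); scattering is strongly forward-peaked so small-angle
(paraxial) closures for the multipath-time moments apply; emission is
uniform in angle within the cone and uniform across the disk face; the
field is azimuthally symmetric, so a 2-D (ρ, z) map fully represents the
3-D volume.  Time is integrated out — only the stationary intensity is
produced.

### Multipath-time moments

The scattered kernel needs the first two moments of the multipath time at
each depth.  Four parametrizations are available through the `mu_tau`
parameter:

* `eq4` (default): exact small-angle first moment
  μ_τ c/z = 1 − (1−e^(−x))/x with x = μₛ z (1−g), combined with the
  constant ratio σ_τ/μ_τ = √(2/3).  This ratio follows from the
  quadratic-approximation moment pair when the ⟨θ⁴⟩ term is dropped under
  the small-angle assumption.  This combination tracks experimental
  transmission profiles best.
* `table1_Lutomirski`: both moments from the quadratic approximations
  (μ_τ c/z = ¼ μₛ z ⟨θ²⟩, same √(2/3) ratio); closest to the historical
  closed-source implementation.
* `table1_vandeHulst`: μ_τ c/z = (1/12) μₛ z ⟨θ²⟩ with σ_τ/μ_τ = √1.4.
* `eq4_precise_sigma`: exact first and second moments; requires ⟨cos²θ⟩
  (`cos2_mean`), for which no defensible literature default exists — it is
  therefore a required user input in this mode.

Throughout, ⟨θ²⟩ = 2(1−g).  The multipath-time density is a gamma
distribution with shape μ_τ²/σ_τ² and rate μ_τ/σ_τ², evaluated through its
logarithm so that large shape parameters (possible in the precise-σ mode)
cannot overflow.

## Parameters

Defaults ship in `defaults.yml` (μm / fs units throughout):

| parameter | default | meaning |
|---|---|---|
| `ntissue` | 1.36 | refractive index of cortical tissue |
| `mu_a`, `mu_s` | 6e-5, 0.0211 μm⁻¹ | absorption / scattering coefficients (blue light, cortex) |
| `g` | 0.86 | anisotropy ⟨cos θ⟩ |
| `NA`, `opt_radius` | 0.37, 100 μm | fiber aperture and face radius |
| `xymax`, `dxy`, `zmax`, `dz` | 700, 5, 700, 5 μm | output grid |
| `rho_exp_min`, `n_rho_smpls` | 1 μm, 20 | shifted-log radial axis of the pencil field |
| `tau_min`, `tau_max`, `n_tau_smpls` | 5, 10⁴ fs, 100 | multipath-time integration window |
| `nsteps_theta`, `nsteps_phi` | 24, 24 | angular convolution resolution |
| `dxy_direct_disk`, `dxy_scattered_disk` | 3, 10 μm | disk-convolution steps |

The direct component is convolved over the disk at a finer step because it
is sharply peaked near the emission face; the scattered component is
smooth, so a coarser step loses little and saves time.

## Numerical choices

* **Depth axis.** Uniform from `z_start = min(1 μm, dz)` to `zmax`
  inclusive, with the sample count rounded so the effective step is as
  close as possible to `dz` (141 samples at defaults).  The axis never
  contains z = 0, where the on-axis direct cone is singular; `z_start` is
  exposed as a parameter.
* **τ quadrature.** Composite Simpson on the natural-log-spaced nodes.  At
  shallow depths the gamma density is narrow relative to the node spacing
  and a trapezoid rule there deviates by several percent from a dense
  reference; Simpson brings the maximum relative deviation against a
  10,000-node reference to ~3 × 10⁻⁴ while using the same samples.
* **Angular convolution.** Midpoint samples in both angles — this avoids
  the zero-weight θ′ = 0 node and φ endpoint double counting — with weight
  sin θ′ Δθ′ Δφ′/(2π); the weights sum to 1 − cos θ_div to O(Δθ²).  The
  printed normalization of the scattered-cone sum is kept as-is, which
  makes its total angular weight (1 − cos θ_div) while the analytic direct
  cone carries 1/(2π(1 − cos θ_div)); the direct:scattered balance would
  shift by that factor under the alternative reading.
* **Interpolation.** Bilinear on the native grids (the pencil field's
  shifted-log radial axis is not resampled, preserving near-axis
  resolution).  Queries below the first depth sample are linearly ramped
  to zero at the source plane, where the scattered field vanishes;
  queries at negative projected depth (point behind a tilted source
  plane) contribute zero.  Every query is counted, and in strict mode a
  query beyond the stored radial/depth extent is a hard error.
* **Extent expansion.** The cone grid extends radially to xymax + R so the
  disk convolution stays in-domain; the pencil grid extends to
  (xymax+R)·cos θ_div + zmax·sin θ_div radially and √((xymax+R)² + zmax²)
  in depth, the worst-case tilt projections from the cone grid.  The
  fiber radius appears in these formulas because disk-convolution shifts
  of up to R would otherwise push angular-convolution queries outside the
  pencil volume.  `legacy_truncation` clips these extents downward and
  switches out-of-domain handling to zero-fill, deliberately reproducing
  the edge (cone truncated at 400 μm) and corner (pencil truncated at
  500/700 μm) underestimation artifacts of truncated convolutions.
* **Disk lattice.** Cell centers at ((i+½)s, (j+½)s): no sample lies on
  y′ = 0, so doubling the y′ > 0 half-lattice is an exact mirror cover;
  a center is inside iff x′²+y′² ≤ R² (plain Riemann sum).  A disk smaller
  than the lattice pitch degenerates to a single centered emitter.
* **Determinism.** No stage draws random numbers; identical configurations
  give bit-identical fields.

## Verification, problem sizes, and what it shows

The test suite checks each stage against an independent route: gamma
properties against `scipy.stats.gamma` and adaptive quadrature, the
transverse kernel against its closed-form normalization, the analytic
cone against the closed-form cap-power integral, the τ and angular sums
against 100×-denser and 16×-denser references, and the half-disk shortcut
against full-disk enumeration.  The convergence checks run on a scaled
grid (xymax = zmax = 200 μm, Δ = 10 μm), which exercises the identical
code paths at a fraction of the cost; the full default grid is run
end-to-end once to check the output contract and the qualitative
transmission-profile properties (profile broadening with depth, monotone
on-axis decay beyond the near field).

All inputs are synthetic or analytic; no experimental data ships with the
package, so passing tests demonstrate internal consistency and numerical
convergence of the model, not agreement with measured tissue
transmission.

## Known limitations

* **Shallow-depth cutoff dependence.**  Where μ_τ(z) ≪ `tau_min`
  (z ≲ 30 μm at defaults) the gamma mass lies almost entirely below the
  integration window and the residual scattered intensity — of order 10⁻³
  of the field maximum — is governed by the lower cutoff itself: halving
  `tau_min` changes those values by orders of magnitude.  Scattered light
  is physically negligible there (the direct component dominates by far),
  but the scattered field at shallow depth should not be interpreted
  quantitatively.  The upper cutoff is benign: doubling `tau_max` moves
  the field by < 0.05% on the scaled grid.
* **Angular convergence at vacuous nodes.**  At nodes below ~10⁻⁶ of the
  field maximum (shallow depth, far off-axis) the 24×24 angular sum can
  deviate from a 96×96 reference by tens of percent, because the
  piecewise-bilinear pencil lookup varies over orders of magnitude within
  one angular cell.  Above that intensity level the deviation is ≤ 1.3%
  on the scaled grid.
* Homogeneous tissue only: no layered media, blood-vessel absorption or
  tissue heating; one wavelength per run (coefficients are inputs, not
  spectra); uniform emission only (non-uniform angular or surface
  profiles would enter through the two convolution weights).
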