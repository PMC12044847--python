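# Methods

## The model

`mbit` refines crystal structures against single-crystal X-ray intensities
using aspherical atomic form factors from the Hansen–Coppens multipole
model.  Each pseudoatom carries the density

```
rho(r) = Pc rho_core(r) + Pv kappa^3 rho_val(kappa r)
         + sum_{l=1}^{lmax} kappa'^3 R_l(kappa' r) sum_m P_lm d_lm(theta, phi)
```

with populations `Pc`, `Pv`, `P_lm` in electrons, radial scale parameters
`kappa`, `kappa'` (guarded to [0.5, 2.0]), density-normalized real spherical
harmonics `d_lm` (so a unit `P_lm` moves one electron between lobes; the
normalization constants are computed once by piecewise quadrature of
|y_lm|), and the angles taken in an atom-local Cartesian frame (z toward a
reference neighbour, x in the plane of a second; hydrogen z points along the
X–H bond, so a positive `P_10` is a bond-directed dipole).

### Radial functions

The package is self-contained: core and valence spherical densities are
built from single-zeta Slater shells with Clementi–Raimondi exponents, and
the deformation radials are normalized Slater functions `r^{n_l}
exp(-zeta_l r)` with `n_l = (1, 2, ...)` for H and `(2, 2, 3, 4)` for the
first row, `zeta_l` twice the valence exponent by default.  All exponents
are stored in bohr⁻¹ and may be overridden per atom.  These are documented,
reproducible defaults; the engine — not any particular exponent table — is
the point.  The same term list drives both the real-space density (values,
analytic gradients and Hessians via solid-harmonic polynomials) and the
reciprocal-space form factors (closed-form Fourier–Bessel transforms of
Slater functions, with a power series below `K = zeta/2` where the closed
form cancels; both branches validated against quadrature at ~1e-12).

### Structure factors

```
F(h) = sum_ops exp(2 pi i h·t) sum_atoms occ (f(h') + f' + i f'') T(U, h')
       exp(2 pi i h'·x),   h' = R^T h
```

ADPs use the CIF `U^ij` convention with the Debye–Waller exponent
`2 pi^2 sum U^ij h_i h_j a*_i a*_j`.  In the equivalent-reflection
formulation the image rotation is already absorbed into `h'`, so the local
direction entering `d_lm` is `unit(q(h'))` projected onto the *unrotated*
atom frame — an easy place for a double-rotation mistake, which is why the
engine is validated to 1e-13 against an explicit P1 expansion with
geometry-derived frames, and to 0.05% against a 128³ FFT of the model
density sampled in real space.  Dispersion uses International-Tables Mo
K-alpha `f'`, `f''`; theoretical static structure factors are dispersion-free
by contract.

## Refinement

Weighted least squares on F² minimizes `sum w (Fo² - k² Fc²_corr)²` by
Levenberg–Marquardt-damped Gauss–Newton with the SHELXL weighting
`w = 1/(sigma² + (aP)² + bP)`, `P = (max(Fo²,0) + 2Fc²)/3`, and fixed
`(a, b)` (default a = 0.01, b = 0; no automatic re-optimization — the
published protocols fix a scheme, and auto-tuning would add
irreproducibility).  Derivatives are analytic for scale, coordinates, ADPs
and the multipole populations (which enter F linearly); `kappa` and
`kappa'` use central differences with per-atom partial recomputation.  The
analytic coordinate derivatives neglect the dependence of the local frames
on the geometry; the damped iteration still descends and the residual bias
is far below the e.s.d.s (a single cycle from a 1e-5 A perturbation lands
at ~3e-8 A).  Standard uncertainties come from the inverse normal matrix
scaled by GooF².  Parameters with exactly zero signal (e.g. `kappa'` while
all `P_lm` are zero) are held fixed for the cycle rather than treated as a
fatal singularity; a genuinely ill-conditioned normal matrix raises an
error naming the most suspect parameters.

Two staged protocols mirror standard practice:

* **Multipole fit** (against theoretical static intensities, dispersion
  off): (1) all populations to the octupole level with kappas fixed, (2)
  per-atom kappas with populations fixed, (3) kappas plus the non-hydrogen
  populations jointly, hydrogen multipoles held to limit correlation.
  Because stages 1–3 are block-coordinate steps, they approach the minimum
  at a linear rate under strong `kappa'`–`P_lm` correlation; a final joint
  completion pass with every population and kappa free (default on)
  finishes convergence.  With exact model-class data the fit then reaches
  the generating parameters to ~1e-13.  A *cold-started* joint fit is
  singular by construction (`kappa'` has no gradient while `P_lm = 0`) and
  can fall into local minima — the staging is load-bearing, not cosmetic.
* **Coordinate/ADP refinement** (against experimental intensities,
  dispersion on, multipoles fixed): the conceptual three steps — (1)
  non-hydrogen xyz + anisotropic U, (2) plus hydrogen xyz with isotropic
  hydrogen U, (3) everything free and anisotropic — bracketed by two
  coordinates-only *locator* passes against the d >= 1.2 A subset with
  pure 1/sigma² weights.  The aspherical hydrogen density features are
  sharp (~0.25 A), so the full-resolution objective has narrow wells; the
  smooth low-resolution landscape guides atoms into the right wells before
  the statistical stages polish, and a second pass repairs the positional
  bias the isotropic-H approximation of step (2) can introduce.  The scale
  factor is free in every stage; an optional isotropic secondary-extinction
  scalar with the SHELXL angular kernel `0.001 lambda³/sin 2theta` can be
  refined alongside.

  On *noise-free* synthetic data the SHELXL `a`-term (which models
  experimental inadequacy) makes the weights purely relative and roughens
  the landscape for no statistical benefit; recovery studies therefore run
  with a = 0 (pure sigma weights), which is the exact scheme for that noise
  model.  The default for noisy/experimental data remains a = 0.01.

The IAM baseline uses the same engine with neutral spherical atoms and the
conventional treatment (isotropic hydrogens — free anisotropic hydrogen
ADPs would absorb exactly the bond density whose misfit the comparison is
meant to expose).

## The iterative loop

One cycle: density backend → staged multipole fit (warm-started from the
previous cycle by default) → staged coordinate/ADP refinement → convergence
test on `phi_diff`, the root-mean-square Cartesian coordinate change over
the asymmetric unit.  The loop stops when `phi_diff < 1e-4 A` (0.1 mA),
tested from the second cycle onwards, or at the cycle budget (reported as
`max_cycles`, not an exception).  The exact averaging behind a
"geometrically averaged change" is not uniquely determined by the phrase;
RMS is the default because it matches the "changed by less than 0.1 mA on
average" reading, and a geometric-mean variant is selectable for
sensitivity checks.  Per-atom squared displacements and ADP-change
amplitudes are recorded each cycle.

The density backend abstracts the periodic electronic-structure step: it
must return deterministic, dispersion-free static structure factors for a
requested reflection list at a given geometry (default resolution 0.8 A —
the parameters mainly describe valence density, so the fit is insensitive
to the cutoff over 0.9–0.3 A, which the acceptance suite verifies).  Two
backends ship: a file backend consuming `h k l Are Aim` TSV exports, and a
synthetic oracle holding a ground-truth multipole model.  The oracle's
`frozen` mode returns the truth density regardless of geometry (isolating
loop mechanics: the truth model is then a strict fixed point); `relaxed`
mode rides the truth parameters on the requested geometry, emulating a
theory code that recomputes the density for each new structure — genuine
iteration, used for recovery studies.

## Diagnostics

* **Difference Fourier maps**: coefficients `(|Fo|/k - |Fc|) exp(i phi_c)`
  (residual) or `Fc_multipole - Fc_spherical` (deformation), expanded over
  the full sphere via `F(R^T h) = exp(-2 pi i h·t) F(h)` plus Friedel
  completion; orbit images are averaged, which projects noisy coefficients
  of phase-restricted reflections onto the symmetry-consistent subspace.
  Map default 64³ (~0.1–0.15 A/voxel for the fixture cells).
* **Henn–Meindl analysis**: the fractal dimension `d^f(rho0)` of the
  rho0-isosurface voxel set (face-neighbour crossings, periodic) by
  box-counting over dyadic box edges 2..n/4 with an unweighted log–log LSQ
  slope; `egross = 1/2 sum |rho| dV`.  A flat map yields an empty curve,
  not an error.  For i.i.d. Gaussian noise the curve peaks at `d^f ~ 3` on
  a plateau around rho0 = 0 — tests assert the plateau, because the argmax
  position within it is not statistically pinned.
* **QTAIM**: Newton–Raphson on the analytic density gradient (|grad rho| <
  1e-8 e A⁻⁴, step cap 0.3 A), Hessian eigenvalues → rank/signature,
  ellipticity `epsilon = lambda1/lambda2 - 1` under |lambda1| >= |lambda2|.
  The bond table reports D as the straight internuclear distance and D1, D2
  as CP-to-nucleus distances (bond-path arc tracing is out of scope; for
  near-linear paths D ≈ D1 + D2).  Pairs resolve to the nearest symmetry
  image automatically, so intermolecular hydrogen bonds "just work";
  non-(3,−1) outcomes are flagged, never dropped.

## Synthetic fixtures

Two molecular crystals are generated from frozen constants (bit-identical
on every call): a 14-atom amino-acid-like zwitterion and a 22-atom
pentitol chain, both packed in P2₁2₁2₁ by a clash-penalized placement
search so that every intermolecular contact is chemically sane and at
least one intermolecular O–H···O bond sits at 1.85 A.  Ground-truth
multipole parameters are drawn once from literature-plausible ranges:
hydrogen bond dipoles `P_10` in +0.14..0.20 e with contracted valence
(`kappa` ~ 1.05–1.13), heavy-atom dipoles +0.01..0.04 e and higher
multipoles within ±0.04 e (±0.02 on O) — the pattern of refined organic
charge densities, where the X–H bond density is the dominant aspherical
feature near hydrogen.  ADP truth is random positive-definite with
realistic magnitudes.  Simulated intensities are `k²|F|² ext(x) +
N(0, sigma²)` with `sigma = max(rel_sigma k²|F|² ext, floor)`; 2% relative
noise mirrors a good low-temperature dataset.

What the fixtures do *not* emulate: real DFT-level densities (no
interaction density beyond what the multipole truth encodes), thermal
diffuse scattering, absorption, twinning, disorder.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery — oracle equivalence of the two density representations,
recovery of generating parameters, convergence behaviour, the qualitative
hydrogen systematics — not agreement with any particular published
refinement, which would require periodic DFT and experimental data.

## Numerical choices

* Merging tolerance for symmetry-equivalent sites: 1e-4 fractional (below
  refinement significance).
* Real-space grids: per-term cutoff radii such that truncated tails are
  below 1e-8 e A⁻³; lattice copies summed explicitly so maps are exactly
  periodic; the sharp 1s cores are point-sampled on a 3x-finer shifted
  subgrid and the fold's Dirichlet transfer function deconvolved exactly in
  Fourier space — without this the core tails alias ~1% errors into every
  structure factor of a 128³ map.
* LM damping: lambda starts at 1e-5 with 10x adaptation, accept-only-better
  steps; stages stop at max|shift|/esd < 0.005 or when no improving step
  exists at lambda = 1e12.
* Problem sizes in the test-suite: the 14-atom fixture with ~700
  reflections at 0.8 A (up to ~8700 at 0.3 A in the resolution sweep),
  chosen as the smallest configuration that exercises every code path —
  screw symmetry, intermolecular hydrogen bonds, all parameter classes —
  with wide data/parameter redundancy.
* Seeds: every stochastic step (noise, perturbations, random pseudoatoms)
  takes an explicit seed; fixture truth uses an internal frozen seed and
  never varies.

## Known limitations

* No riding-hydrogen constraints, TLS, twinning, solvent masking,
  anharmonic motion or multi-zeta radial functions.
* Local frames follow geometry but their derivatives are not in the
  Jacobian (see above).
* `kappa'` is shared across l per atom (per-l kappas are representable in
  the parameter set but not refined separately).
* Bond-path arc lengths and QTAIM basin integrals are not computed.
* Element coverage is H, C, N, O, F — the organic-crystal scope of the
  fixtures; the tables extend by adding Slater shells and dispersion
  values.
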