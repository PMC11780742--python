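# Methods

## Model

An external hydrostatic pressure is represented by repulsive Gaussian
potentials on the tesserae of a molecular cavity.  Tessera *j* contributes
`p_j G̃_j(r)` with `G̃_j(r) = N_j exp(−ω_j|r−r_j|²)`.  Three constructions fix
all per-tessera constants from the cavity geometry alone:

- **edge halving** — the potential falls to half its peak at the tessera edge
  radius `sqrt(a_j/π)`, giving `ω_j = π ln2 / a_j`;
- **normalization** — `N_j = (ω_j/π)^{3/2}` so that `∫G̃_j = 1`.  The total
  energy is invariant to this choice (it cancels between the two auxiliary
  vectors), but normalized Gaussians keep magnitudes balanced across tesserae
  of very different size, which stabilizes screening;
- **force balance** — the force the tessera potential exerts on the electron
  density through its patch equals pressure × area.  With
  `f̃_j = Σ D_μν n_j·∇_{r_j}⟨μ|G̃_j|ν⟩` this yields `p_j = −p_inp a_j / f̃_j`.
  For a well-formed cavity the density decays outward along the normal, so
  `f̃_j < 0` and all amplitudes are positive.  The sign convention is pinned
  by the physics tests (energy rises with pressure, bonds compress), since it
  is the one piece of the working equations not fixed by dimensional
  analysis.

Per SCF iteration the model makes two integral-direct passes: pass 1
contracts the density into `g̃, f̃` and forms amplitudes and energy
`E_G = Σ p_j g̃_j`; pass 2 assembles the Fock term
`F = dE_G/dD = Σ_j p_j [g_{μν,j} − (g̃_j/f̃_j) f_{μν,j}]`, which includes the
response of the amplitudes to the density.  A directional-derivative test
(`tr(F·ΔD)` versus finite differences of `E_G`) enforces this identity to
1e-7 relative in the suite.  The cavity is held fixed during the SCF.
`V_eff = E_G/p_inp` is reported as the pressure-conjugate volume; it is not
the geometric cavity volume, and the total energy should not be read as an
enthalpy.

## Cavity

Atom-centered spheres (Bondi radii by default, per-element overrides in Å)
sampled by Lebedev grids; supported sizes 6–194 points (default 110, a
common continuum-solvation default).  The Lebedev orbit tables are verified
in the test suite by monomial exactness to each rule's design degree, so a
corrupted constant cannot survive unnoticed.

Switching: a point on atom I is weighted by `Π_K s(x_K)` over all other
spheres K, where `s` is the C² quintic smooth-step `6x⁵−15x⁴+10x³` and
`x_K = (d_K − r_K(1−w)) / (r_K w)` with `d_K` the distance to center K and
switching-region width `w = 0.1 r_K` just *inside* sphere K.  Points outside
every foreign sphere keep weight exactly 1, so well-separated fragments
reproduce isolated-atom surfaces bit-for-bit.  Weights below 1e-8 (numerical
noise floor) are discarded with their tesserae.  Area
`a_j = (Lebedev weight) · 4π r_I² · (switching weight)`; normals are the
radial directions, rigidly attached to the parent atom.

OCC: the switching weight is evaluated for the one-to-one mapped point on
the inflated surface (all radii + r_ext, default 0.25 Å) against the
inflated neighbor spheres; the area factor still uses the inner sphere
radius.  Holes left by screened-away crevice points are accepted, not
re-normalized.  Larger r_ext can only remove more points.

Analytic derivatives: `∂a_j/∂R` differentiates the switching products
(through the outer surface for OCC); `∂r_j/∂R` is the identity on the parent
atom.  Both are validated against finite differences; rigid translations
leave all areas exactly invariant.

## Integrals

Tessera-side integrals are three-center Gaussian overlaps.  The two basis
primitives and the tessera Gaussian are collapsed by the product theorem;
each Cartesian direction is then a polynomial times a single Gaussian,
integrated exactly by Gauss–Hermite quadrature of order `deg/2 + 1`.  The
same machinery yields the normal-derivative (f-type), exponent-derivative
(d/f-type surface Gaussians, at fixed N_j) and bra-center-derivative blocks;
ket- and tessera-center derivatives come from translational invariance.
Angular momenta up to g are supported and validated against a brute-force
quadrature oracle; the built-in host basis uses only s/p Cartesian shells, so
no spherical-harmonic transformation is needed.

Screening: collapsing `|μν| G̃_j` exactly produces `exp(−ξ d²)` with `d` the
pair-center/tessera distance and `ξ` the reduced exponent; the remaining
polynomial-moment integral is bounded by binomial expansion with closed-form
absolute Gaussian moments.  The bound is provably conservative (never a
false skip; verified against direct evaluation), and enabling it never
changes a kept value.  Default threshold 1e-12 moves fixture energies by
< 1e-9 hartree.  Tesserae are processed in batches (default 2048) so the
working set stays fixed as the tessera count grows.

## Gradients

At convergence the explicit geometry derivative of `E_G` combines
constant-exponent integral derivatives, exponent/area variation through
`dω/da = −ω/a`, cavity area derivatives, and amplitude chain-rule terms;
density response is carried by the host's energy-weighted density built from
the full (pressure-including) Fock matrix.  Derivatives of the normalization
constants are never formed: `E_G` depends on N_j only through ratios from
which it cancels, and the finite-difference oracle confirms the cancellation
rather than trusting it.  The reported block decomposes into
integral / exponent-area / amplitude parts that sum to the total exactly,
and its per-axis atom sums vanish to 1e-10 (translational invariance).

Validation stencils: central differences, 1e-3 bohr steps for total
energies, 1e-5 bohr for integrals and auxiliary vectors, 1e-6 for exponent
derivatives — chosen so a failure is attributable to the analytic code, not
the stencil.

Geometry optimization drives scipy's BFGS with energy+gradient callbacks,
rebuilding the cavity at each geometry (tesserae may appear/disappear
*between* steps; the resulting sub-1e-8-hartree discontinuities are
tolerated).  Convergence: |ΔE| ≤ 1e-6 hartree and max gradient component
≤ 1e-3 hartree/Å.  Only the smooth vdW and vdW/OCC cavities are allowed;
surface constructions without consistent analytic derivatives
(solvent-excluded, isodensity, pseudo-isodensity) are refused.

## Host SCF engine

A self-contained closed-shell RHF: McMurchie–Davidson one- and two-electron
integrals (numba-compiled, Boys function by series + downward recursion),
symmetric orthogonalization, DIIS on the total Fock matrix (the pressure
term enters the standard extrapolation; no separate damping), energy
convergence 1e-7 hartree by default.  Basis: built-in STO-3G for
H/He/C/N/O/F/Ne.  The engine's absolute energies are anchored to published
STO-3G values (H₂ −1.1167 Eh at 0.74 Å, Ne −126.60452 Eh) and its analytic
gradient to finite differences.  Ghost atoms (basis, no charge, no
electrons, no cavity sphere) support counterpoise corrections; each
counterpoise sub-calculation builds its cavity from its own real atoms only,
the physically consistent choice for a pressure model (the medium presses on
the fragment, not on its ghost basis).

Amplitudes with `|f̃_j| < 1e-12` are regularized to zero and logged
(near-singular force balance on essentially density-free tesserae);
negative amplitudes are kept, counted and reported as the cavity-quality
diagnostic.

## Fixtures and what passing tests show

Fixture molecules are H₂ (0.74 Å), H₂O, CH₄, Ne₂ (3.1 Å) and a stacked
benzene dimer.  The dimer is constructed for the crevice regime: with
enlarged aromatic radii (H 1.4 Å, C 2.1 Å) and 3.6 Å ring separation the
carbon spheres of the two rings barely interpenetrate, so a narrow wedge of
surface points survives between the rings where each Gaussian overlaps the
*opposite* ring's density — flipping the sign of f̃ and producing negative
amplitudes (~20 at 5 GPa) and slower SCF convergence, which the OCC at
r_ext = 0.25 Å removes entirely.  At much closer stacking the wedge is
screened away and the artifact vanishes; the fixture sits deliberately in
the pathological window.

Everything runs in a minimal basis on small molecules.  That validates the
model's internal consistency (integrals, self-consistency, gradients,
diagnostics) exactly, but minimal-basis densities are stiff: compression
effects (V_eff decrease, bond shortening) are qualitatively right yet
smaller than polarized-basis values, and no claim is made about basis-set
converged pressure chemistry.  Problem sizes were chosen so the full suite
and the acceptance script each run in minutes on one CPU: the dimer
(72 basis functions, ~1000 tesserae) is the largest system exercised.

## Known limitations

- Host engine: RHF only (closed shells), STO-3G only, no DFT, no RI/multipole
  acceleration of the Coulomb problem.
- Cavities: vdW and vdW/OCC only; no solvent-excluded/isodensity surfaces,
  no symmetry-adapted construction, no cavity re-normalization of OCC holes.
- No post-SCF correlation, response properties, or vibrational analysis
  under pressure; no dispersion correction (binding energies of van der
  Waals complexes at plain HF are underbound).
- The OCC extension radius is a parameter: too small fails to heal crevices,
  too large thins the cavity; 0.25 Å is the validated default here.
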