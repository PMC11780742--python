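# hipres

Hydrostatic pressure for molecular electronic-structure calculations, as an
implicit environment: repulsive Gaussian potentials placed on the surface
elements (*tesserae*) of a van der Waals cavity compress the electron density
self-consistently during the SCF, contributing an energy, a Fock-matrix term
and analytic nuclear gradients.  The package is for computational chemists who
want to study how an external pressure of a few to a few tens of GPa deforms
molecular geometries and energetics, without simulating an explicit
compressing medium.

## The model

A cavity is built from atom-centered spheres of van der Waals radii,
discretized with Lebedev angular grids; points buried in neighboring spheres
are faded out by a smooth switching function.  Each retained tessera *j*
(center **r**_j, area *a*_j, outward normal **n**_j) carries a normalized
Gaussian potential

    V(r) = Σ_j p_j G̃_j(r),      G̃_j(r) = N_j exp(−ω_j |r − r_j|²),

with the exponent fixed by the edge-halving condition ω_j = π ln2 / a_j and
N_j = (ω_j/π)^{3/2}.  Only the amplitudes p_j are updated during the SCF: with
the density-contracted auxiliary vectors

    g̃_j = Σ_{μν} D_μν ⟨μ|G̃_j|ν⟩,
    f̃_j = Σ_{μν} D_μν  n_j·∇_{r_j}⟨μ|G̃_j|ν⟩,

the semiclassical force balance (each tessera pushes on the density with force
p·a_j) gives p_j = −p_inp a_j / f̃_j, the energy E_G = Σ_j p_j g̃_j, an
effective volume V_eff = E_G / p_inp, and the Fock contribution
F_μν = Σ_j p_j [g_μν,j − (g̃_j/f̃_j) f_μν,j].  All integrals are three-center
Gaussian overlaps evaluated by the Gaussian product theorem with Gauss–Hermite
quadrature, computed in batches and contracted on the fly (integral-direct:
nothing of size N_basis² × N_tess is stored), with a conservative
distance-based screening bound.

Negative amplitudes diagnose ill-formed cavity regions (crevices between
nearby spheres).  The *outer cavity correction* (OCC) takes each point's
switching weight from an inflated surface at r_vdW + r_ext, screening crevice
points away and restoring positive amplitudes and smooth convergence — the
cavity of choice for geometry optimization.

The host SCF is a built-in closed-shell restricted Hartree–Fock engine
(McMurchie–Davidson integrals, DIIS, analytic gradients) with STO-3G basis
data for H, He, C, N, O, F and Ne; ghost atoms support counterpoise-corrected
binding energies.

## Worked example

Water at 10 GPa with the OCC cavity:

```python
from hipres import make_fixture, run_scf
fx = make_fixture("h2o")
rec0 = run_scf(fx.mol, 0.0)
rec = run_scf(fx.mol, 10.0, cavity_type="vdw_occ", r_ext=0.25)
print(f"E(0 GPa)  = {rec0.energy:.8f} Eh")
print(f"E(10 GPa) = {rec.energy:.8f} Eh")
print(f"E_G = {rec.e_gost:.6f} Eh   V_eff = {rec.v_eff:.2f} bohr^3")
print(f"negative amplitudes: {rec.n_negative}")
```

prints

```
E(0 GPa)  = -74.96302314 Eh
E(10 GPa) = -74.94702491 Eh
E_G = 0.015997 Eh   V_eff = 47.07 bohr^3
negative amplitudes: 0
```

The confinement raises the total energy by 16 mEh; the effective volume
(the energy-to-pressure ratio, not the geometric cavity volume) is ~47 bohr³
and shrinks as the pressure grows.  The same machinery drives geometry
optimization — `optimize_geometry(fx.mol, 50.0, cavity_type="vdw_occ")`
shortens the H₂ bond from 0.712 Å (0 GPa) to 0.709 Å — and
counterpoise-corrected binding-energy studies versus pressure
(`run_binding_study`), which recover the linear pressure stabilization of a
compressed dimer and flag the non-linear response of crevice-bearing
cavities.

From a shell:

```sh
hipres scf h2o.xyz --pressure 10 --cavity vdw_occ --r-ext 0.25 --json out.json
hipres opt h2.xyz --pressure 50 --cavity vdw_occ
hipres bind ne2.xyz --fragments 1-1,2-2 --pressures 0,1,2,3,4,5
hipres fixtures list
```

## Layout

- `src/hipres/lebedev.py` — Lebedev angular grids (self-verified tables)
- `src/hipres/cavity.py` — vdW / vdW-OCC surfaces, switching, derivatives
- `src/hipres/hf.py`, `basis.py` — the built-in RHF host engine
- `src/hipres/tessint.py` — three-center tessera integrals + screening
- `src/hipres/pressure.py` — SCF coupling (aux vectors, amplitudes, Fock)
- `src/hipres/gradients.py` — analytic nuclear gradients, optimizer driver
- `src/hipres/binding.py` — counterpoise binding energies vs pressure
- `src/hipres/fixtures.py` — fixture molecules and independent oracles
- `docs/methods.md` — model details, defaults, numerical choices, limits
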