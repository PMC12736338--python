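# fqspec

Fluctuating-charge polarizable embedding and ensemble UV-Vis spectra
for solvated chromophores.

## The problem

The absorption spectrum of a dye in water is shaped by its solvation
shell: hydrogen bonds to a carbonyl acceptor shift the first bright
π→π* transition to the red, and snapshot-to-snapshot variation of the
solvent arrangement broadens the band inhomogeneously. A standard route
to such spectra samples solute–water configurations, cuts each to a
droplet, solves a polarizable embedding for the solvent response,
computes per-snapshot excitations, and Gaussian-broadens and
ensemble-averages them into the final profile, from which the
vacuo-to-water solvatochromic shift ΔE = E_vac − E_solv (positive for a
red shift) is read.

`fqspec` implements that workflow's classical machinery as a tested
library for method developers: the constrained
fluctuating-charge(-and-dipole) solver, droplet structural analysis
(RDF and running coordination number), spectral assembly, and a
synthetic-data engine that emulates the MD and excited-state steps at
desk scale so every statistical property is checkable against known
generating parameters.

## The model

MM water sites carry electronegativities χ, hardnesses η and (for the
dipole variants) polarizabilities α. Charges q and induced dipoles μ
minimise the quadratic energy

U(q, μ) = ½qᵀT_qq q + qᵀT_qμ μ + ½μᵀT_μμ μ + (χ+V)ᵀq − E·μ

under charge-conservation constraints, giving a symmetric saddle-point
linear system in (q, λ, μ). Variants: **FQ** (charges, per-molecule
neutrality), **FQFμ** (adds induced dipoles), **FQFμCT** (one global
charge constraint — intermolecular charge transfer). The
solute–solvent interaction energy is Σᵢ qᵢVᵢ − Σⱼ μⱼ·Eⱼ. See
`docs/methods.md` for kernels, parameters and numerics.

## Worked example

```python
import numpy as np
from fqspec import *

cfg = PipelineConfig(
    generator=GeneratorConfig(n_snapshots=40, droplet_radius=8.0, seed=1),
    variant=ForceFieldVariant.FQFMU, seed=1)
cfg.excitation.noise_sd = 0.0          # isolate the environment-driven dispersion

report = run_pipeline(cfg, "ws_demo")
print("E_solv = %.3f eV" % report["e_solv_eV"])
print("dE     = %.3f eV" % report["delta_e_eV"])
print("width  = %.3f eV" % report["band_width_eV"])

snaps = generate_snapshots(cfg.generator)
rdf  = radial_distribution(snaps, "O2", "HW", r_max=8.0, bin_width=0.05)
rcn  = running_coordination_number(rdf)
rmin = first_minimum(rdf)
print("RDF peak %.3f A, first min %.2f A, n(first min) = %.2f" % (
    rdf.r_centers[np.argmax(rdf.g)], rmin,
    rcn.n[np.argmin(abs(rcn.r_centers - rmin))]))
```

Output:

```
E_solv = 2.777 eV
dE     = 0.323 eV
width  = 0.210 eV
RDF peak 1.825 A, first min 2.28 A, n(first min) = 2.10
```

Reading: the hydrogen-bonded shell (acceptor–Hw distances peaked near
1.8 Å, ≈ 2 donors inside the first minimum) red-shifts the averaged
first band from the 3.10 eV gas-phase reference to 2.78 eV, a +0.32 eV
solvatochromic shift, with a 0.21 eV inhomogeneous spread of the
per-snapshot transition energies. The run writes every stage's
artifacts (snapshots, cut droplets, solved charges/dipoles, stick
spectra, averaged curve, shift report, manifest with content hashes)
into `ws_demo/`.

The same workflow is available from the shell:

```sh
fqspec run --config config.yaml --seed 1 --out ws
fqspec compare --config config.yaml --variants FQ,FQFmu,FQFmuCT --out cmp
```

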