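# Methods

## Scope and model

`fqspec` implements the classical half of a polarizable QM/MM absorption
workflow for a chromophore in water, together with a synthetic engine
that stands in for the expensive halves (molecular dynamics and
excited-state quantum chemistry) so that every statistical property of
the pipeline can be verified against known generating parameters.

### Polarizable solvent models

Each water carries three interaction sites with electronegativity χ and
chemical hardness η (and, for the dipole-carrying variants, an isotropic
polarizability α), all in atomic units. Charges and induced dipoles are
variational: they minimise

    U(q, μ) = ½ qᵀ T_qq q + qᵀ T_qμ μ + ½ μᵀ T_μμ μ + (χ + V)ᵀ q − E·μ

subject to charge conservation, where V and E are the solute's
electrostatic potential and field at the MM sites. Three constraint
structures are supported:

* **FQ** — charges only; each molecule's net charge is fixed.
* **FQFμ** — charges plus induced dipoles; per-molecule constraints.
* **FQFμCT** — as FQFμ but with a single total-charge constraint, so
  charge may transfer between solvent molecules.

The stationarity conditions form a symmetric saddle-point system in
(q, λ, μ) with Lagrange multipliers λ, solved by direct symmetric
factorisation with an SVD fallback and a residual check (raising a
degenerate-geometry error above 1e-9 relative residual). The FQ system
is the same matrix with the dipole rows and columns removed.

### Interaction kernels

The published parameterisations do not fix a unique closed form for the
kernels, so two are provided, selectable via `kernel_form`:

* `"ohno"` (default): S(r) = 1/√(r² + d_ij²) with the hardness-derived
  damping d_ij = 2/(η_i + η_j), the screening family conventionally used
  with electronegativity-equalisation charges. At r = 0 this reproduces
  the standard combination (η_i + η_j)/2 and at large r the bare 1/r.
* `"coulomb"`: bare 1/r off-diagonals.

Charge–dipole and dipole–dipole blocks are the consistent first and
second derivatives of the same scalar kernel; diagonal blocks are η_i
(charge) and α_i⁻¹·I (dipole), which makes the isolated-site limit
μ = αE exact.

**Intramolecular induction is excluded** (molecules act as polarization
groups, as in AMOEBA-style force fields): point dipoles at bond
distances couple near-catastrophically to their own molecule's charges
(α/r³ ≈ 1 for O–H), and the intramolecular electrostatics is already
encoded in χ/η. Intramolecular charge–charge terms are kept — they *are*
the electronegativity-equalisation mechanism. With intra-group induction
included, the induced dipoles are dominated by their own molecule's
charges and *screen* the solvent field at the solute, inverting the
physical expectation that adding polarizability strengthens
solute–solvent coupling; excluding it restores that behaviour.

### Parameters

The literature water parameterisations are not redistributed; named
templates (`FQa`, `FQb`, `FQc`, `FQFmu`) ship with explicit `None`
placeholders that must be filled from a config file. All defaults and
tests use the documented **toy set** (a.u.):

| site | χ | η | α |
|------|-----|-----|-----|
| O | 0.30 | 0.60 | 5.0 |
| H | 0.10 | 0.90 | 2.5 |

Hardnesses sit in the 0.5–1 a.u. range typical of
electronegativity-equalisation sets; the polarizabilities sum to
≈ 10 bohr³, close to the molecular polarizability of liquid water. With
the Ohno kernel this yields q_O ≈ −0.62 for an isolated water,
comparable to fixed-charge water models.

## Synthetic data

### Droplet generator

`generate_snapshots` emulates snapshot extraction from a solvated-MD
trajectory. Defaults are the reference study conditions: 100 snapshots,
a 17 Å droplet at the liquid-water number density 0.0334 Å⁻³, and a
hydrogen-bond shell on the carbonyl-like acceptor with Poisson(2)
donors at O···H distances Normal(1.8, 0.1) Å. Details that matter:

* Waters are rigid three-site molecules (O–H 0.9572 Å, H–O–H 104.52°);
  bulk waters are uniform in the droplet with uniform random
  orientations, subject to a hard 2.4 Å heavy-atom contact rule
  (bounded retries, then a generation error).
* HB donors approach on the solvent-exposed hemisphere around the bond
  axis through the acceptor, with the donor O–H collinear with the
  hydrogen bond. An isotropic approach distribution would average the
  solvent field at the solute to zero and erase the red-shift
  mechanism; real carbonyl hydrogen bonds are directional.
* Bulk waters are additionally rejected if any hydrogen falls inside
  the acceptor's 2.4 Å HB sphere — such a geometry *is* a hydrogen
  bond, and the HB count is controlled by `hb_count_mean` alone. The
  Poisson draw is capped at 5 (more donors cannot pack on the
  hemisphere; the cap biases the mean by < 0.01).
* Randomness: one top-level seed; snapshot *i* uses the independent
  substream (seed, i), so ensembles are bit-reproducible and
  order-independent.

What the generator does **not** emulate: thermodynamics (no forces,
thermostat or periodic electrostatics), orientational correlations of
the bulk network, snapshot time-correlation (snapshots are independent
by construction), and solute flexibility. Passing tests therefore
validate the *pipeline machinery and its statistics*, not force-field
accuracy against real water structure.

### Mock excited states

`mock_excitations` maps a solved embedding to a stick spectrum via a
linear Stark model: E₁ = e₀ − k·F + noise, with F the solvent electric
field from the solved charges and dipoles at a probe point, projected
on a probe axis. Defaults: e₀ = 3.10 eV (a gas-phase π→π* reference),
probe at the carbonyl oxygen, axis along the solute dipole, slope
k = 15 eV per a.u. of field — chosen so that the typical HB-shell field
(~0.01–0.03 a.u.) maps to a red shift of a few tenths of an eV, the
regime observed for strongly solvatochromic dyes. Higher states sit at
fixed offsets (defaults +1.3, +2.1 eV) with independent noise;
oscillator strengths are |Normal(0.5, 0.1)| draws. The linear form is
an emulation device: it makes slope recovery, band-broadening
monotonicity and shift sign exactly testable.

## Structural analysis

`spherical_cut` keeps whole waters whose **oxygen** lies inside the cut
radius (split molecules would break the per-molecule charge
constraints); the solute is always kept and any periodic cell dropped.

`radial_distribution` uses the standard estimator
g(r) = ⟨counts⟩ / (N_A · 4πr²Δr · ρ_B) with bin width 0.05 Å and
r_max 8 Å by default. ρ_B is, in order of preference: an explicit
argument; N_B/V with minimum-image distances when snapshots carry a
periodic box; otherwise the mean B density within r_max of the A sites
— the natural normalisation for a finite droplet, where no true bulk
exists. Droplet g(r) at radii comparable to the droplet size is
edge-biased; quantitative closed-form checks (the ideal-gas g ≡ 1
limit) are run in the periodic-box mode where the estimator is exact.

`running_coordination_number` integrates n(r) = 4πρ_B ∫₀^r g s² ds by
trapezoid on the stored grid; the coordination read-out takes n at the
first local minimum of the 5-point-smoothed g(r) after its first peak.

## Spectra

Sticks are broadened with Gaussians of fixed FWHM (default 0.3 eV,
σ = FWHM/2√(2 ln 2)) on a uniform grid (default 1.5–8.0 eV, 0.01 eV);
each stick contributes area f_k σ√(2π); sticks clipped by the grid
trigger a warning reporting the clipped strength fraction. Ensemble
averaging is a pointwise mean over identical grids; intensities are
arbitrary units (an optional flag normalises the averaged curve to unit
maximum). The band maximum is the discrete argmax refined by three-point
parabolic interpolation; the solution-phase energy is read from the
*averaged* curve (matching how an experimental λmax is read), not as the
mean of per-snapshot maxima. The solvatochromic shift is
ΔE = E_vac − E_solv, positive for a red shift; wavelength conversion
uses hc = 1239.841984 eV·nm pinned in `units.py`.

## Problem sizes and numerics

Tests and the acceptance script run desk-scale ensembles chosen for
statistical adequacy: 6–8 Å droplets (≈ 30–140 waters) wherever the
embedding is solved per snapshot, 200 snapshots at the full 17 Å
droplet for structure recovery (generation only), 100 snapshots for
slope recovery, and 40 snapshots per variant for the end-to-end shift
comparison. Solver tolerance is a 1e-9 relative residual; site pairs
closer than 0.1 Å and solute–MM contacts closer than 0.5 Å are rejected
as degenerate rather than regularised, so generator faults surface as
errors instead of silently damped numerics.

## Known limitations

* The embedding is one-shot: the source does not respond to the solved
  charges (no self-consistent coupling to a quantum region).
* No forces or analytic gradients; no periodic electrostatics in the
  solver (droplet geometry only).
* The FQFμCT variant changes only the constraint structure; whether a
  charge-transfer parameterisation should also modify the kernels is
  left open, and the kernels are shared across variants.
* Hydrogen bonds are characterised by distance only (no angular
  criterion), matching the RDF/RCN read-out used throughout.
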