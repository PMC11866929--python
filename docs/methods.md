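# Methods

This note documents the model, the estimators, the numerical choices and
the limits of what the bundled experiments demonstrate.

## The kernel RDF estimator

The RDF is represented as a histogram on a uniform grid of `B` bins of
width Δ starting at `r_lo` (default 0).  Each pair distance r_ij is
spread with a rectangular kernel of width Δ and unit area centred at
r_ij, so the estimator is continuous and piecewise linear in every pair
distance — the property that makes it usable as a bias potential with
exact forces.  Accumulation is cloud-in-cell: with t = (r − r_lo)/Δ − ½,
the pair splits between bins ⌊t⌋ and ⌊t⌋+1 with weights 1−frac(t) and
frac(t).  A distance exactly on a bin edge splits 0.5/0.5; a distance at
a bin center lands entirely in that bin.

Every pair whose kernel overlaps the grid contributes its in-grid
overlap, including pairs up to Δ/2 beyond either grid end.  This keeps
the expectation of the *edge* bins at the ideal-gas value; mass spilling
outside the grid is dropped, never renormalised (the estimator is an
expanded-range histogram, not a probability density on the grid).  The
only residual edge bias is the first bin when r_lo = 0 (no pairs exist
at negative r to spill in), of relative size Δ-independent 1.6% there
and far below counting noise at any realistic sample size.

Normalisation uses ordered pair counts N(N−1) rather than the
macroscopic N², so a system of uncorrelated uniform particles has
expectation exactly 1 in every interior bin at any N.  For species pair
(α, β) the per-pair weight is w^{αβ}·2V/(N_α N'_β V_b) with
N'_β = N_β for unlike and N_α−1 for like pairs.

Pair weights w^{αβ} sum to 1 in all three modes: `identical` (one
implicit species), `frequency` (w^{αβ} = m c_α c_β, m = 2 for unlike
pairs), and `xray` — the Warren–Krutter–Morningstar form
w^{αβ} = m c_α c_β f_α f_β / (Σ_γ c_γ f_γ)².  The scattering factors f
are constant per species (defaults: atomic numbers for H, O, Ti, and
arbitrary user values), consistent with the q-independence that the
Warren–Krutter–Morningstar approximation assumes; q-dependent analytic
form-factor parametrisations are deliberately out of scope.  The exact
placement of the form factors (f_α f_β / ⟨f⟩²) is a convention choice —
the normalisation Σw = 1 is the invariant the rest of the package
relies on — and the weighting object accepts arbitrary explicit pair
weights for users who need another convention.

## The linear bias

The maximum-relative-entropy ensemble that reproduces a target RDF while
minimally perturbing the unbiased ensemble has a bias linear in the
constrained observables: E_bias = Σ_b λ̂_b g_b with λ̂ in energy units
(λ̂_b = k_BT·λ_b in terms of the dimensionless multipliers).  Since each
pair touches at most two bins, the exact force on a pair is

    dE/dr_ij = (W_ij/Δ)(λ̂_{k+1}/V_{k+1} − λ̂_k/V_k)

with k, k+1 the two touched bins and off-grid multipliers treated as
zero (mirroring the kernel truncation).  Forces are pairwise and
central; Newton's third law and momentum conservation hold by
construction, and the force/energy pair is verified against central
finite differences in the test suite (to ~1e−8 relative in practice).

The bias virial is the pairwise sum T_ME = (1/3) Σ r_ij·F_ij, reported
both in total and decomposed by the bin whose multiplier generated each
force term (Σ_b T_ME^b = T_ME to machine precision).  Note the kernel
RDF normalisation carries an explicit factor of the ensemble volume V;
the virial differentiates only through the pair distances, so the
energy–virial consistency oracle scales positions and box while holding
the normalisation volume fixed (`norm_volume=` in the bias API exists
for exactly this).  A hard minimum-distance guard (10⁻⁶ Δ) excludes
r_ij → 0 from the force, where the direction vector is undefined.

## The controller

Multipliers are fitted by gradient descent on the Legendre-transform
objective Γ(λ).  Γ itself contains an intractable partition-function
term and is never evaluated; its gradient is just
g̃_b^target − ⟨g_b⟩.  One update cycle: sample the instantaneous RDF
every `sample_every` steps, average `window/sample_every` samples, apply

    λ̂_b ← λ̂_b − γ·k_BT·κ_b·(g̃_b^target − ⟨g_b⟩)/Σ_b'|g̃_b'^target − ⟨g_b'⟩|

reset the averages, and optionally skip `equilibrate` steps before
sampling resumes.  Design points:

* **Sign.** Under-represented bins (target > measured) get lower λ̂,
  lowering the bias energy of configurations that fill them.  This is
  validated end-to-end by the MAE-decrease property and by the sign of
  the recovered pair potential (below).
* **ℓ1 normalisation.** The per-update change has ℓ1 norm exactly
  γ·k_BT when κ≡1 (unit-tested to machine precision), so updates do not
  stall as the match improves and γ can stay constant.  Typical γ: 10–5
  for liquid-to-liquid matching, 5–1 for inducing liquid-to-solid
  transitions, where gentler tilting keeps nucleation stochastic rather
  than violent.
* **κ damping.** `anti_contraction` multiplies the update by
  `kappa_factor` in bins whose average per-bin virial ⟨T_ME^b⟩ < 0
  (`anti_expansion`: > 0).  Only relevant under a barostat, where the
  bias virial otherwise drives large volume drifts.
* **Running averages reset after each update** (continuing them would
  mix ensembles sampled under different multipliers); the choice is a
  convention and is stated here because the alternative is defensible.
* **Non-convexity.** RDF bins are correlated observables, so Γ is not
  convex and gradient descent may settle in a local minimum.  The
  controller records the windowed MAE history so stalls are visible; no
  restart heuristics are applied.
* **Statistics guard.** At startup the controller warns when bins are
  expected to collect fewer than 10 pair counts per update window
  (thin bins make updates noisy and the resulting forces spiky).
* At convergence the ℓ1-normalised updates keep full size, so λ̂
  random-walks around the optimum.  The converged bias profile is
  therefore read out by averaging the multiplier trace (default: the
  last half of the updates) and smoothing over 3 bins
  (`recovered_pair_potential`).

## The MD engine

Reduced Lennard-Jones units throughout (σ = ε = m = k_B = 1; time in
σ√(m/ε)).  Velocity-Verlet; the Langevin thermostat uses BAOAB
splitting with exact Ornstein–Uhlenbeck velocity updates, so NVE is
recovered by switching the thermostat off.  Thermostat damping is a
first-class knob because strongly biased runs (sharp crystalline
targets ⇒ large adjacent-bin λ̂ differences ⇒ strong forces) heat up;
increasing the friction or shortening dt contains this.  The isotropic
Berendsen barostat rescales volume toward the set pressure using the
total virial T_0 + T_ME — the bias contributes to the pressure exactly
as an extra pair potential would.  Per-step volume rescaling is clipped
to ±10% as a stability guard.

Pair geometry is computed once per step with vectorised O(N²)
minimum-image arithmetic (a numba fast path when available; the numpy
path is the reference and is cross-checked to machine precision) and
shared by all force providers through one contract:
`provider(frame, pairs) → (energy, forces, virial)`.  At the N ≤ 500
used here an O(N²) pass beats a Verlet list in numpy; the provider
contract is the extension point for anything larger.  Forces are
truncated at the cutoff (default 2.5σ, potential shifted to zero
there); energy conservation in NVE is ~1e−5 relative over 10⁴ steps at
dt = 0.002.

## Targets

Two self-contained target sources:

* **Reference runs** — time-averaged kernel RDF of an unbiased
  simulation with the reference interaction; block-average drift of the
  potential energy triggers an unequilibrated-input warning.
* **Broadened lattices** — analytic crystalline targets
  g(r) = Σ_k z_k/(4π r² ρ)·N(r; r_k, σ) built from the coordination
  shells (radius r_k, count z_k) of fcc/bcc/sc/hcp lattices, computed
  by tiling the lattice rather than from tables.  Binning uses exact
  Gaussian mass per bin (erf), so integrating g·4πr²ρ over a peak
  recovers z_k independent of σ.  This is the same mathematical object
  as the RDF of a cold crystal, without running cold-crystal MD; a σ
  below Δ/3 warns, since peaks thinner than bins reproduce the
  noisy-update instability described above.

## Diagnostics

* **MAE** — mean absolute error per bin between two RDFs or two ADFs; a
  metric (symmetric, zero iff equal, triangle inequality).
* **ADF** — distribution of neighbour–central–neighbour angles within a
  cutoff, normalised to unit integral over θ in degrees (the
  normalisation is a package convention; MAEs between ADFs are computed
  on these densities).
* **Diffusion** — Einstein relation D = slope/6 of the FFT-based MSD
  (all time origins), fitted by least squares over the second half of
  the lag range by default; flagged when R² < 0.9 or the log–log
  exponent strays from 1 by more than 0.3 (ballistic or caged motion).
  Requires unwrapped coordinates.
* **Bond order** — Lechner–Dellago averaged local Steinhardt
  parameters: q_lm(i) averaged over {i} ∪ neighbours(i) before the
  rotational invariant is formed.  Neighbour rule per call: cutoff or
  k-nearest (knn = 12 default).  Perfect-FCC q̄6 = 0.574524 over 12
  neighbours; classification labels an atom solid when q̄_l exceeds a
  threshold.  Packaged presets: q̄6 > 0.07 (water-like, cutoff rule),
  q̄8 > 0.073 and q̄10 > 0.085 (12-nearest rule); the LJ experiments
  use 0.35, which separates hot gas (max ≈ 0.15) from crystal (0.57)
  with a wide margin.

## Study conditions of the bundled experiments

The RDF-matching experiment uses N = 500 at ρ* = 0.8, T* = 1.0, grid
Δ = 0.05σ over 0–4σ (80 bins), γ = 5, sampling every 10 steps with
100-step windows, 300 update cycles, target from a 100-frame reference
run at ε = 1.3; these are the package's standard desk-scale conditions
and run in a few minutes on one CPU.  The recovered −Δu correlation is
evaluated over the first coordination shell, defined data-driven as the
bins from the inner rise of the target (g ≥ 0.5 — below that the pair
density is too thin to constrain a multiplier) to the first local
minimum after the main peak.

The nucleation demonstration (broadened-FCC target, T* = 0.4, γ = 2)
is a long run (tens of minutes per seed) and lives in
`scripts/nucleation_demo.py` rather than the test suite.

## What the synthetic systems do and do not show

All bundled experiments are monatomic Lennard-Jones systems.  They
exercise every code path the method needs — kernel estimation,
weighting, exact forces and virial, the controller, nucleation — but
they do not probe molecular connectivity (rigid molecules,
electrostatics), realistic X-ray form-factor physics (constant f per
species only), long-range dispersion corrections, or system sizes where
O(N²) pair handling matters.  Passing tests show the estimator and
controller mathematics is right and that the method behaves as designed
at desk scale, not that any particular real material will crystallise.

Known limitations, stated rather than hidden: orthorhombic periodic
boxes only; minimum-image convention restricts the grid to half the
smallest box length; biased dynamics suppress diffusivity (the bias
constrains structure, so dynamical properties of biased runs should not
be trusted); the ice-like multi-domain crystallisation behaviour of the
full-scale method is outside what the desk-scale LJ analogue can
reproduce.
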