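# rdfbias

Maximum relative entropy biasing of molecular dynamics simulations with
target radial distribution functions.

## The problem

A radial distribution function g(r) — from a reference simulation, from
an analytic crystal model, or from wide-angle X-ray scattering — pins
down the *average* pair structure of a system, but not the ensemble that
produced it.  Infinitely many biased ensembles reproduce a given g(r);
almost all of them distort the underlying interaction model far more
than the data warrants.  The principle of maximum relative entropy picks
the unique ensemble that matches the target RDF while staying closest
(minimal Kullback–Leibler divergence) to the unbiased ensemble of the
original force field.  The result is a bias that is **linear** in the
RDF histogram:

```
E_bias(r^N) = Σ_b λ̂_b g_b(r^N)
```

where `g_b` is a differentiable kernel estimate of the RDF in bin `b`
(each pair distance spread over two adjacent bins by a rectangular
kernel of one bin width) and `λ̂_b` are Lagrange multipliers in energy
units.  Because `g_b` is piecewise linear in every pair distance, the
bias has exact pairwise central forces and an exact virial
`T_ME = (1/3) Σ_pairs r_ij · F_ij`, decomposable bin by bin.

The multipliers are fitted *on the fly* by normalised gradient descent:
the gradient of the governing objective Γ(λ) is simply
`g̃_b^target − ⟨g_b⟩`, the per-bin difference between target and the
windowed mean measured in the biased run, so each update is

```
λ̂_b ← λ̂_b − γ·k_BT·κ_b·(g̃_b^target − ⟨g_b⟩) / Σ_b' |g̃_b'^target − ⟨g_b'⟩|
```

The ℓ1 normalisation keeps every update the same total size (γ·k_BT),
so one step size γ works from the first update to convergence.  The
optional per-bin damping κ_b throttles updates in bins whose bias
virial would contract or expand the box under a barostat.  Multi-species
systems are supported through pair-frequency or X-ray
(Warren–Krutter–Morningstar) weighting of the partial RDFs, with the
weights entering the forces exactly as they enter the total RDF.

Biasing toward a sharply peaked crystalline target tilts the free-energy
surface along every RDF bin at once, which can drive a liquid through
nucleation into the crystal the target describes — including metastable
polymorphs that annealing-style methods cannot reach.

The package bundles a small periodic Lennard-Jones MD engine (reduced
units, velocity-Verlet, Langevin thermostat, isotropic Berendsen
barostat) so the whole method runs at desk scale, plus the diagnostics
used to judge it: RDF/ADF mean absolute error, mean-squared-displacement
diffusion coefficients, and Lechner–Dellago averaged bond-order
parameters q̄_l with solid/liquid classification.

## Worked example

Bias a Lennard-Jones liquid (ε = 1.0) to reproduce the RDF of a
*different* liquid (ε = 1.3) that the controller only knows through its
RDF:

```python
import rdfbias as rb
from rdfbias.engine import EngineConfig, LJParams
from rdfbias.targets import reference_run_target

grid = rb.RDFGrid(n_bins=80, delta=0.05)          # 0..4 sigma
ref = EngineConfig(lj_params={("X", "X"): LJParams(epsilon=1.3)},
                   temperature=1.0, seed=1001)
target = reference_run_target(ref, grid, n_frames=100, n=500, density=0.8)

sim = EngineConfig(lj_params={("X", "X"): LJParams(epsilon=1.0)},
                   temperature=1.0, seed=1)
schedule = rb.BiasSchedule(sample_every=10, window=100, gamma=5.0)
model = rb.RDFBiasModel(target, sim, schedule, n_particles=500, density=0.8)
res = model.fit(n_updates=100, seed=1)
print(res.summary())
```

```
        Maximum-entropy RDF bias fit
================================================
bins                 80 x 0.05 (range 0..4)
particles            500
temperature          1.0
step size gamma      5
kappa mode           none (factor 1)
cadence              sample 10 / window 100 / equil 0
updates applied      100
windowed MAE         0.0298 -> 0.0130
frozen-bias MAE      0.0073
lambda l1 norm       253.5262
lambda range         [-15.4942, 34.6726]
bias virial T_ME     409.5033
```

The windowed mean absolute error between the measured and target RDFs
falls from 0.030 (the structural difference between the two liquids) to
0.013 within 100 update cycles; averaging with the bias frozen
afterwards gives MAE 0.007, i.e. the biased ε = 1.0 liquid reproduces
the ε = 1.3 structure to well within its own sampling noise.  The
negative λ̂ values sit where the target has more structure than the
unbiased liquid (an energetic reward for filling those bins).  The
learned bias is itself physically meaningful: expressed as a pair
potential via `rdfbias.recovered_pair_potential(res)`, it correlates
with the true pair-potential difference Δu(r) = u_{1.3} − u_{1.0} over
the first coordination shell with Pearson r ≈ 0.93
(`rdfbias.experiments.LJMatchingResult.recovery_correlation`).

The same machinery runs from the shell:

```
rdfbias make-target lattice --lattice fcc --spacing 1.1 --sigma 0.08 --out fcc.rdf
rdfbias bias --config run.yaml            # controller run with traces
rdfbias compare --rdf a.rdf b.rdf         # MAE between two RDF files
rdfbias boop traj.xyz --l 6 --knn 12 --threshold 0.35
```

`scripts/nucleation_demo.py` runs the long crystallisation
demonstration (a cold LJ liquid biased with a broadened-FCC target until
a solid cluster nucleates, tracked by the q̄6 solid fraction).

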