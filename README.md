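# synspread

An agent-based Susceptible–Infected–Removed (S-I-R) simulator of misfolded
α-synuclein propagation on a structural brain connectome, for researchers
studying connectome-based models of neurodegenerative disease (Parkinson
disease in particular).

Misfolded α-synuclein is thought to spread prion-like along axonal
projections, converting normal α-synuclein as it goes, while regional gene
expression sets local vulnerability.  `synspread` implements that hypothesis
as a mean-field agent-based epidemic on a weighted network: agents are
individual proteins, regions are network nodes, and white-matter tracts are
the routes of spread.  The package covers the full analysis cycle —
simulation, epicenter identification, null-model controls, and model-fit
evaluation against a regional atrophy map — plus a synthetic-data generator
so every stage runs without restricted imaging or transcriptomic data.

## Model

Per region *i* with size *S_i* (voxels), synthesis rate *α_i* and clearance
rate *β_i* (both mapped from SNCA / GBA expression z-scores into (0, 1) by the
standard normal CDF), normal (*N_i*) and misfolded (*M_i*) agents update per
time step Δt:

```
ΔN_i = α_i S_i Δt − (1 − e^{−β_i Δt}) N_i − e^{−β_i Δt} (1 − e^{−γ_i⁰ M_i Δt}) N_i
ΔM_i = e^{−β_i Δt} (1 − e^{−γ_i⁰ M_i Δt}) N_i − (1 − e^{−β_i Δt}) M_i
```

with baseline transmission rate γ_i⁰ = 1 / S_i.  Both species walk the
network: an agent stays in region *i* with probability ρ_i or enters edge
(*i*, *j*) with probability (1 − ρ_i) w_ij / Σ_j w_ij (optionally rescaled by
e^{k·fc(i,j)} to bias motion toward functionally coupled regions), and exits
an edge of length l_ij with probability v / l_ij.  Atrophy accrues from
direct toxicity plus deafferentation:

```
ΔL_i = k₁ (1 − e^{−r_i(t) Δt}) + k₂ Σ_j [w_ji / Σ_j w_ji] (1 − e^{−r_j(t−1) Δt})
```

where r_i = M_i / (N_i + M_i).  Disease-free growth converges to a unique
equilibrium; seeding misfolded agents then either extinguishes or ignites an
outbreak that settles at a seed-independent endemic state.  The minimal seed
that ignites a region — its *spread threshold* — ranks regions as candidate
disease epicenters.  A single-region two-compartment reduction
(`synspread.reduced`) makes the two-fixed-point structure explicit and
analytically checkable.

## Worked example

```python
import numpy as np
import synspread as ss

spec = ss.SyntheticSpec(n_regions=12, rng_seed=7)
bundle = ss.generate_bundle(spec)
c, prof = bundle["connectome"], bundle["profiles"]

params = ss.SimulationParams(seed_region="region_03", seed_amount=1.0, max_steps=4000)
eq, density = ss.growth_to_equilibrium(c, prof, params)
print("top equilibrium density:", c.region_names[int(np.argmax(density))],
      round(float(density.max()), 3))

amap, traj = ss.generate_atrophy(c, prof, "region_03", t_obs=4000, noise_sd=0.3,
                                 rng=0, params=params, return_trajectory=True)
t_peak, r_peak = ss.peak_fit(ss.fit_curve(traj, amap))
print(f"peak Spearman fit r = {r_peak:.3f} at step {int(t_peak)}")

static = ss.static_predictor_fits(c, prof, amap, exclude_seed_region="region_03")
print("best static predictor:", static["spearman"].abs().idxmax(),
      round(float(static["spearman"].abs().max()), 3))
```

prints

```
top equilibrium density: region_03 2.979
peak Spearman fit r = 0.882 at step 3710
best static predictor: eigenvector 0.518
```

Here the ground-truth atrophy map was forward-simulated from a seed in
`region_03` with noise of 0.3 SD: the dynamic model recovers it with peak
rank correlation 0.88, well above the best static network predictor (0.52),
and the seed region also carries the highest equilibrium density of normal
protein — the signature the epicenter analysis exploits.

The same pipeline is scriptable from the shell:

```
synspread synth --n-regions 42 --seed 1 --out inputs/
synspread simulate --inputs inputs/ --steps 10000 --out run/
synspread evaluate --inputs inputs/ --trajectory run/ --out eval/
synspread thresholds --inputs inputs/ --out thresholds/
synspread reduced        # fixed points of the two-compartment reduction
```

Every command writes a JSON manifest (parameters, input SHA-256 hashes,
seeds) so runs can be reproduced bit for bit.

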