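# Methods

## The model

`synspread` treats α-synuclein molecules as independent agents on a weighted,
undirected structural connectome.  The population in each region *i* splits
into susceptible normal agents *N_i*, infectious misfolded agents *M_i*, and
removed (cleared) agents; directed edge compartments *N_(i,j)*, *M_(i,j)*
hold agents in transit along fiber tracts.

Per unit time, in region *i*:

* **Synthesis** — a normal agent appears per voxel with probability
  α_i = Φ(z_SNCA,i), so the regional increment over Δt is α_i S_i Δt
  (S_i the voxel count).
* **Clearance** — any regional agent survives Δt with probability
  e^{−β_i Δt}, β_i = Φ(z_GBA,i); the cleared fraction is 1 − e^{−β_i Δt}.
  Agents in edges are in transit and are not cleared.
* **Infection** — a surviving normal agent misfolds with probability
  1 − e^{−γ_i⁰ M_i Δt}, the chance of meeting at least one of the M_i
  misfolded agents, with baseline transmission rate γ_i⁰ = 1/S_i.
* **Mobility** — an agent stays with probability ρ_i or enters edge (i, j)
  with probability (1 − ρ_i) w_ij / Σ_j w_ij; an agent in edge (i, j) exits
  into region j with probability v / l_ij.  Both species move identically.
  With a functional-connectivity matrix, edge attractiveness is rescaled by
  e^{k·fc(i,j)} and renormalized, so k = 0 is exactly neutral.

One integration step applies mobility first (an exactly conservative
exchange), then synthesis/clearance/infection ("asynchronous" mode, the
default); "synchronous" mode computes both sets of increments from the
pre-step state.  Final states of the two orderings agree to well under 1%
relative, which the suite checks.

Atrophy accrues as
ΔL_i = k₁ (1 − e^{−r_i(t)Δt}) + k₂ Σ_j [w_ji/Σ_j w_ji] (1 − e^{−r_j(t−1)Δt}),
r_i = M_i/(N_i+M_i) (defined 0 at 0/0): a direct-toxicity term plus
deafferentation weighted by normalized in-strengths, lagged one step.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| Δt | time step (unit time 1) | 0.01 | increments O(Δt); halving it halves per-step fractions |
| ρ_i | stay probability | 0.5 | fit known to be robust over 0.1–0.9 |
| k₁, k₂ | atrophy weights | 0.5 / 0.5 | constrained k₁+k₂ = 1 |
| k (fc_k) | FC influence | 0 | typical useful range 0–5 |
| v | edge-traversal speed | 1 | exit probability v/l_ij must stay ≤ 1 |
| ε (tol) | equilibrium tolerance | 1e-7 | on the max per-step state change |
| seed_amount | injected misfolded agents | 1 | added, not converted |

Rate transforms are pluggable (`normal_cdf` default, `logistic`,
`arctan`); all are strictly increasing onto (0, 1), so they preserve the
rank order of regional rates, which is what the dynamics respond to.

## The reduced two-compartment system

Collapsing to one well-mixed region with probabilities read as rates gives

    dN/dt = α − β₁N − (1 − β₁) g(M) N
    dM/dt = (1 − β₁) g(M) N − β₂M,      g(M) = 1 − (1 − γ)^M.

The (1 − β₁) factor carries the discrete update's "survive clearance, then
misfold" ordering into the flow.  On the M = 0 axis the balance point is
N = α/β₁; with β₁ = β₂ = β, summing the equations forces N + M = α/β at any
fixed point, and the second intersection solves g(M)·N = (β₂/(1−β₁))·M.  At
α = 5000, β₁ = β₂ = 0.5, γ = 0.001 the fixed points are (10000, 0) — a
saddle in the outbreak regime — and a stable endemic point at
(5017.15, 4982.85).  Fixed points are located by bracketing sign changes of
dM/dt along the N-nullcline on a log-spaced M grid (10⁴ points over
[1e-6, 10α/β₂]) with Brent refinement, and classified by the eigenvalues of
a central-finite-difference Jacobian (step 1e-6 × state scale; eigenvalues
within 1e-8 of the imaginary axis raise a "marginal" error rather than
silently classifying).  A discrete single-region map mirroring the per-step
update is provided for comparison (`reduced_map_step`).

## Spread thresholds and the role of floating point

The disease-free equilibrium of the networked system is, for typical rate
profiles, *linearly* unstable: in exact arithmetic any positive seed would
eventually ignite, and near M = 0 the dynamics are linear in M, so an
endpoint outbreak test would not depend on the amount at all.  The finite,
region-dependent spread threshold arises because the infection fraction
1 − e^{−γ⁰MΔt} is evaluated literally: once γ⁰M_iΔt falls below roughly
1e-16, e^{−x} rounds to 1.0 and the fraction is exactly zero, so
sub-viability misfolded populations cannot transmit and decay away.  The
implementation intentionally uses `exp`, not `expm1`; the threshold scan
(start and step 1e-13 agents by default) probes exactly this viability
boundary.  Consequences worth knowing:

* thresholds scale roughly with S_i (the viability level is
  M ≈ S_i · 5e-15 at Δt = 0.01), modulated by whether local net growth at
  viability is positive — which is where gene expression enters;
* on networks with uniform region sizes, many viable regions tie at the
  same grid-quantized threshold; a region "attains the minimum" if its
  threshold equals the smallest one (any member of the tie set is an
  argmin at scan granularity);
* the outbreak test is windowed: outbreak means total misfolded mass at the
  horizon (default 2×10⁴ steps) exceeds both its half-horizon value and the
  seeded amount, because near-threshold dynamics are slow and a pure
  endpoint test misclassifies.

The linear scan is the reference algorithm; a doubling-bracket bisection
over the same amount grid returns the identical value (outbreak is monotone
in amount) at logarithmic cost, and the batched per-region search advances
all regions through one shared simulation per round.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) a geometric random connectome — coordinates
uniform in a box (60 mm default, a single-hemisphere scale), edge scores
decaying with distance (decay 20 mm), the distance minimum-spanning tree
always kept so the network is connected at the target density (35%);
weights distance-decayed log-normal; lengths euclidean distance × U(1, 1.3),
clamped ≥ 1 mm — (ii) independent standard-normal gene z-scores with an
optional re-standardized expression hotspot, (iii) structure-coupled FC and
AR(1) time series, and (iv) ground-truth atrophy maps forward-simulated
from a known seed with Gaussian noise in z units.

Region sizes default to a uniform 200 voxels.  Because the spread-threshold
floor is proportional to S_i, size heterogeneity acts as a multiplicative
confound on epicenter ranking; holding sizes fixed makes the
hotspot-recovery experiment identify the gene-expression effect itself
(`size_sigma` re-enables heterogeneity when wanted).

What passing tests on these data do **not** show: real tractography
consensus networks have reciprocity/communities beyond distance decay; real
expression maps are spatially autocorrelated, not i.i.d.; real atrophy
t-maps carry structured, not i.i.d. Gaussian, noise.  Tests on synthetic
data validate the machinery and its internal consistency, not empirical
claims about patient data.

## Numerical choices

* Growth to equilibrium iterates until the largest absolute per-step change
  over regional *and* edge populations is below ε; the isolated-region fixed
  point αSΔt/(1 − e^{−βΔt}) is met to 1e-7 when ε is tightened to 1e-12
  (distance to the fixed point is about residual/(βΔt)).
* The mobility exchange is written as paired gain/loss terms, so species
  totals are conserved to machine precision by construction.
* The stochastic variant draws synthesis as Poisson(α_iS_iΔt), clearance
  and infection as binomial thinnings, and mobility as binomial leave +
  multinomial split, matching the deterministic expected increments; runs
  are vectorized across replicates.
* Consensus construction ranks edges by occurrence count, breaking ties by
  mean weight then lexicographic index (deterministic); kept weights average
  over all subjects (zeros included), kept lengths over possessing subjects
  only — zero is a missing length, not a short one — with a switch for the
  other convention; lengths are clamped ≥ 1 mm.
* Expression aggregation standardizes with the sample SD (ddof = 1) at both
  the per-probe and per-gene stage.
* Fit curves mask frames whose misfolded density still changes by > 1%
  between recordings, plus frames with undefined (constant-vector)
  correlations; the peak takes the earliest maximizer on ties.  Permutation
  p-values use the add-one convention (1 + #{null ≥ real})/(n + 1).
* The spatial null recomputes edge lengths from the permuted geometry via
  the distance–length regression fitted on the original network (mode
  `regress`); mode `carry` instead leaves lengths attached to node pairs,
  under which an identity permutation returns the network unchanged.

## Problem sizes used by the test suite

The suite runs end to end on generated networks of 6–42 regions: the
conservation check uses the full 42-region default; dichotomy and
seed-independence use 20 regions with a 4000-step outbreak window, a
300 000-step extinction run and 50 000-step endemic runs; stochastic
validation uses 10 regions × 200 replicates × 40 000 steps; hotspot
recovery uses 20 instances of 12 regions.  These sizes were chosen so each
experiment's quantity of interest is converged at its stated tolerance.

## Known limitations

* Cell death does not feed back on propagation, and spread is bidirectional
  along tracts; tract- or cell-type-specific directionality is not modeled.
* Atrophy is a fixed linear blend of toxicity and deafferentation.
* The spread-threshold mechanism is tied to double precision (see above);
  thresholds are meaningful relative to the scan grid, not as physical
  protein counts.
* Only two genes modulate rates; other vulnerability factors enter only
  through what the caller encodes in the z-score vectors.
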