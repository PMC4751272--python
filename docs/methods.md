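# Methods

## Model

`cablenet` solves the cable equation on branched neuron morphologies by a
vertex-centered finite-volume discretization.  A morphology is a rooted
tree of 3-D vertices with radii; around every vertex sits a tubular
compartment whose axial extent is the sum of the half-lengths of its
incident edges.  Charge conservation on compartment *i* reads

    C_i dV_i/dt = Σ_j G_ij (V_j − V_i) + I_m,i

with membrane capacitance `C_i = c_m · 2π a_i l_i` and axial conductance

    G_ij = 2π / (r_c (a_i⁻² + a_j⁻²) ‖e_ij‖)

— the closed form of the trapezoidal integral of the axial resistance of
two tubular half-compartments.  Branch vertices sum the same two-point
flux over all incident edges; conservation is local and exact by
construction.  Ion species (cytosolic Ca²⁺) obey an axial
diffusion equation discretized with the same geometry; a convection term
is supported in principle but defaults to zero velocity.

The membrane current `I_m` collects plug-in transport mechanisms, all of
which follow one explicit contract: internal states are advanced *before*
the step using only the previous step's solution, and the mechanism then
reports an outward-positive current (or flux) density at the previous
potential.  The solver negates the total once when it assembles the
inward membrane term, so AMPA-type synapses with a 0 mV reversal
depolarise a resting cell.

### Membrane mechanisms

* **Hodgkin–Huxley channels** — `i_hh = c(T)(g_K n⁴(V−E_K) + g_Na
  m³h(V−E_Na))` with the classical squid-axon rate functions shifted so
  that rest sits at V_r = −65 mV, and a temperature factor c(T) = 3.21
  multiplying both the flux and the gate kinetics.  Conductances are
  region-specific (axon / soma / dendrite); the defaults are the cortical
  network parameter set (`TABLE_NETWORK_SPEC`: g_K = 400/200/30 S m⁻²,
  g_Na = 30000/1500/40 S m⁻², g_l = 200/1/1 S m⁻²).  Removable
  singularities of the rate functions are filled with their analytic
  limits; gates are clamped to [0, 1] after every explicit update.
* **Calibrated leak** — `i_l = c(T) g_l (V − E_l)` with E_l solved per
  region from zero net membrane current at rest.  c(T) multiplies channel
  and leak identically and cancels, so the calibration is evaluated with
  c(T) = 1.  With the default conductances this yields E_l =
  −0.066148458 V (axon), −0.030654022 V (soma), −0.057803624 V
  (dendrite), and a synapse-free cell initialised at −65 mV is an exact
  fixed point of the discrete scheme.
* **Calcium machinery** (soma + dendrites) — an N-type voltage-dependent
  calcium channel in the Borg-Graham exponential-rate form (gates m²h,
  GHK flux by default, ohmic selectable), NCX (first-order
  Michaelis–Menten) and PMCA (second-order Hill) extrusion pumps, and a
  constant leak influx calibrated so the total membrane calcium flux
  vanishes at the resting state.  The VDCC/pump numeric parameters are
  package defaults chosen to give spike-locked somatic calcium steps of
  order 10⁻⁴ mM on a ~100 nM resting level decaying over hundreds of
  milliseconds; they are configuration values, not reproductions of any
  published set.  A fraction (default 0.1 %) of every inward AMPA current
  is converted to calcium influx through Faraday's constant with z = 2,
  standing in for the calcium permeability of the receptors under heavy
  endogenous buffering (no explicit buffers are modelled).

### Synapses

*Primary* synapses (external drive) follow the alpha conductance
`g(t) = g_max ((t−t_onset)/τ) exp(−(t−t_onset−τ)/τ)`, truncated outside
`[t_onset, t_onset+6τ]`, with `t_onset ~ N(μ_onset, σ²_onset)` and
`τ ~ N(μ_τ, σ²_τ)` per synapse (non-positive τ draws are rejected).
Placement over the dendritic edges is length-weighted —
`P(edge j) = ‖e_j‖ / Σ_k ‖e_k‖` — with the position on the edge uniform
in (0, 1); the synapse attaches to the nearer edge endpoint, consistent
with the vertex-centered discretization.

*Interconnecting* synapses couple an axon to a dendrite of another cell.
An upward crossing of the presynaptic potential above V_th = −10 mV
(evaluated on the *previous* step's solution — a structural one-step lag
that keeps cells decoupled within a step) appends an activation time;
each activation contributes an independent bi-exponential conductance
normalised to peak at g_max a time
`t_max = τ₁τ₂/(τ₂−τ₁)·ln(τ₂/τ₁)` after onset (τ₁ = 0.2 ms, τ₂ = 1.7 ms).
Re-activation requires the presynaptic potential to fall below threshold
first.  Per synapse the most recent eight activations are retained;
older ones are dropped (at these kinetics an activation's conductance is
negligible long before eight further threshold crossings can occur).
No transmitter delay is modelled beyond the structural lag.

### Network generation

Layered networks place somata uniformly inside per-type depth slabs with
a minimum-separation constraint (dart throwing; over-full boxes are
rejected).  Cells are stylized parametric morphologies grown as biased
random walks: basal dendrites radiate from the soma, apical trunks climb
toward their target lamina, axons are steered toward their laminar
target or meander locally.  The walk's direction noise scales with the
square root of the step and the homing bias linearly with the step, so
shape statistics are invariant under re-sectioning.  These are deliberate
stand-ins for anatomically fingerprinted morphologies: their branch
counts and lengths are template parameters, not fits to data, so
absolute synapse counts of any particular cortical reconstruction are
out of scope — only structural laws (e.g. the cubic growth below) are.

Synaptogenesis follows the distance rule: for every pair of an axonal
edge and a dendritic edge of *different* cells whose cell types the
connectivity table allows, one synapse is created at the closest points
whenever the minimum segment-to-segment distance falls below
`dist_synapse`.  "Section distance" is segment-to-segment (robust to
discretization), not vertex-to-vertex.  The postsynaptic peak
conductance is `(1 + 0.001·d_soma[µm]) · g_base(T1, T2)` with the
base-conductance table (L2/3→L2/3 1.0 nS, L4→L4 1.6, L5A→L5A 2.0 nS, …);
a forbidden pair raises, it is never reported as 0 nS.  Thalamic inputs
are primary synapses on L4 spiny-stellate (mean 30/cell) and L5B
pyramidal (mean 25/cell) dendrites with per-cell Poisson counts — the
protocol prescribes averages, not exact counts.

In homogeneous neuropil the expected number of section pairs within
distance d grows like the search-sphere volume, i.e. ∝ d³.  Binary
pair counting carries a finite-section-length correction of relative
size O(ℓ/d) (the Minkowski d² and d¹ terms), so the scaling experiment
regrids the geometry to 0.25 µm sections before evaluating the rule;
with d ∈ {1..5} µm the measured log-log slope is then ≈ 2.9–3.1.

### Discretization and solution

Time stepping is a mixed Euler scheme: *backward* in the axial fluxes,
*forward* in the membrane/radial fluxes.  Every step solves
`(C/dt + L) V⁺ = (C/dt) V − I_m(V)` with L the axial operator — a
symmetric, tree-structured sparse system.  Vertices are permuted by a
reverse Cuthill-McKee order (breadth-first per component, reversed), so
each matrix row has at most one non-zero strictly right of the diagonal
and the sparse LU factorization and solves are linear in the number of
unknowns; non-tree components fall back to the same ordering with a
warning.

The explicit membrane part imposes a CFL-type bound.  The estimate is
`dt = min(dt_max, safety · min_i C_i/G_mem,i)` where `G_mem,i` is the
present total membrane conductance at vertex *i* — channels at their
current gate states plus the synapses active there.  Current gate states
(not worst-case conductances) are used, with safety = 0.5; the true
stability limit of the explicit part is 2C/G, so the default keeps a
factor-4 margin.  dt is quantized to dyadic fractions of dt_max so the
LU factorizations can be cached per level; the factorization is redone
whenever dt changes level, while the sparsity pattern and ordering are
computed once.  One global dt serves all cells in a step — required for
the one-step synaptic lag to be well defined.  A solution leaving
[−1, 1] V (or going non-finite) aborts with a divergence error naming
the CFL bound; deliberately violating the bound is detected, not
silently wrong.

### Partitioned (cut-cell) solve

`partitioned_solve` emulates, serially, the distributed solve used when
cells are cut across processors.  Axial couplings are stored additively:
each edge belongs to the block owning its lower-indexed endpoint, so the
global matrix is the sum of the block couplings, and a vertex referenced
by another block's edge appears there as a cut point.  Before
factorization each block's diagonal is made consistent (the fully summed
global diagonal — the serial analogue of the diagonal communication a
distributed code performs).  Each iteration computes the consistent
defect (block-local additive defects summed at cut points), solves every
block exactly by LU, and combines the corrections at cut points with
partition-of-unity weights (1/number of sharing blocks).  A plain
unweighted sum over-corrects the shared unknowns and oscillates with an
interface eigenvalue near −1 instead of contracting; the weighted
combination contracts, reduces the defect by roughly half an order of
magnitude per sweep at simulation-typical dt, and leaves the uncut case
exact after a single iteration.  The iteration stops when every block's
owned-defect norm has dropped by `reductionFactor`; with
`reductionFactor = 1` it returns the initial iterate untouched.

### Fused ensemble backend

The loss study runs hundreds of simulations differing only in their
synapse sets.  `cablenet.fastpath.run_alpha_ensemble` executes such an
ensemble in one JIT-compiled loop — same scheme, same CFL estimate, same
mechanism updates, with the tree factorization shared across the batch
and cached per dyadic dt level.  It is an execution backend restricted
to primary synapses, not a second model; a test pins its spike times and
calcium traces to the reference solver.  Note that a batch shares the
global dt, so any spiking member drives the whole batch to the small
step sizes of an action-potential upstroke.

## Study protocols

**Synapse loss vs. synchrony** (`run_loss_study`).  Default scaled-down
conditions: a soma-stick-axon cell (350 µm dendrite of 0.7 µm radius at
40 segments, 150 µm axon of 0.4 µm radius, 8 µm soma), n_syn = 200
synapses (g_max = 1.2 nS, τ = 0.4 ms), N = 20 sample configurations,
synchrony levels σ_onset ∈ {0, 5, 10} ms with μ_onset = 3σ_onset, and a
loss grid {0, 0.2, 0.4, 0.6, 0.75, 0.9, 0.95, 0.977} bracketing the
interesting breakdown region.  Per sample, the distribution and its
activation times are drawn once; loss levels remove nested subsets
(survivors are prefixes of one random permutation), so a sample's
survivors are consistent across the grid.  Simulated time per level is
μ_onset + 2.5σ_onset + 25 ms.  Spikes are counted at the soma as upward
0 mV crossings separated by ≥ 3 ms (the axon-end probe is also
recorded); somatic calcium steps are measured per spike and the tail
decay constant by log-linear regression.  At this scale the study shows
the same structure as at full scale: synchronous volleys elicit exactly
one spike and sustain it to ≈ 97 % loss, jittered inputs fire 2–6 times
intact but break down around 75 % loss, and every calcium step
corresponds to one action potential.  The original-scale protocol
(n_syn = 1000, N = 100) is available through
`LossStudyConfig.full_protocol(swc_path)` for a reconstructed
morphology; the repository ships no third-party reconstructions.

**Network connectivity** (`run_network_study`).  A layered network is
driven by thalamic inputs sampled with (μ_onset, σ_onset) =
(5, 2.5) ms, (μ_τ, σ_τ) = (2.5, 0.1) ms, g_max = 1.2 nS over 20 ms; the
study reports, per layer and time, the fraction of somata at or above
−45 mV, the count of recently activated synapses per projection (a
synapse counts as active for 5τ₂ ≈ 8.5 ms after an activation), and each
layer's peak fraction and peak time.  Default desk-scale size is 20
cells (7/7/3/3 per type); the qualitative connectivity ordering — higher
and earlier L2/3 peaks with larger dist_synapse on matched seeds — is
the reproducible claim at this size, not absolute peak values of any
10,000-cell column.

## What the synthetic conditions do and do not show

The generator's stylized cells have realistic calibers, laminar targets
and tortuosity but no fingerprint-matched branching statistics; the
stick-cell study geometry is a minimal integrate-and-fire-capable
morphology, not a reconstruction.  Passing tests therefore demonstrate
the *mechanisms* — calibration, stability, convergence to analytic and
ODE references, distribution laws, monotonicity and ordering of the
loss/synchrony interaction, cubic synaptogenesis scaling — on controlled
geometry.  They do not certify absolute spike counts, synapse counts or
activity fractions for any real cortical tissue.

## Numerical choices and degenerate inputs

* Multi-point SWC somata are collapsed to one root vertex at the soma
  centroid with sphere-area-equivalent radius (the model is
  vertex-centered; a soma polyline has no distinguished vertex).
* SWC files store radii; files declaring diameters are out of scope and
  are not auto-detected.
* Unknown SWC type codes map to basal dendrite with a warning; cycles,
  multiple roots and non-positive radii are errors.
* Synapse-loss survivor counts use round-half-even.
* Edge resampling subdivides but never merges, preserving branch length
  exactly.
* Empty networks are legal (zero cells, zero synapses); meshing one is
  an error.
* τ₁ = τ₂ in the bi-exponential normalizer is rejected (undefined peak).
* The GHK flux fills its removable singularity at V = 0 with the
  analytic limit.

## Known limitations

Electro-diffusion, truncated-cone compartments, inhibitory synapses,
NMDA voltage dependence, calcium buffers and ER stores are not modelled.
The partitioned solve is a serial emulation — it reproduces the
algebra of the distributed iteration, not its wall-clock behaviour.
Batched ensembles share one global dt, which is conservative for
non-spiking members.
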