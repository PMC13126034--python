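# Methods

This note documents the models, conventions, parameters, and design choices
behind the `axoaxonic` package: what each stage assumes, which knobs matter,
and what the synthetic benchmark does and does not establish about real data.

## Connectome scrubbing

Input tables follow the neuPrint CSV export style: a neuron metadata table
(`neuron_id,class,type,transmitter,side`) and a directed connection table
(`pre_id,post_id,weight`) whose weight is a synapse count.  Duplicate
`(pre, post)` rows are summed **before** filtering, so the strength filter
always applies to the total strength of a neuron pair.  Scrubbing then

1. drops connections with total strength below `min_strength` (default 6,
   boundary kept: weight 6 survives);
2. drops connections touching a neuron whose transmitter is unknown or whose
   type label is blank.

Drop reasons are tallied in that precedence order, so each dropped
connection is counted once.  Neurons left without connections remain in the
neuron table — graph builders exclude isolated nodes themselves, which is
why the neuron count and motif-graph node count differ.  Scrubbing is
idempotent and conserves counts (kept + Σ dropped = input).

Polarity follows fly receptor pharmacology: nicotinic acetylcholine
receptors are excitatory; GABA_A and GluCl are chloride channels, so
GABAergic and glutamatergic connections are inhibitory.

## Motif graphs and metrics

A motif graph keeps edges whose presynaptic neuron is in a chosen class set
and whose postsynaptic neuron is a DN.  Conventions, chosen once and
recorded in every metric bundle:

- **Density** is reported under both conventions: ordered pairs
  m/(n(n−1)) and unordered pairs m/(n(n−1)/2).  The headline density quoted
  for the DN→DN graph uses the unordered-pair formula (2757/(884·883/2) ≈
  0.007).
- **Average shortest path** is unweighted hops on the undirected projection,
  averaged over the largest connected component.  A sparse directed graph of
  this kind is generally not strongly connected, so a single finite value
  requires this (or an equivalent) convention.
- **Clustering** is the mean local clustering coefficient of the undirected
  projection, unweighted.
- **Communities** come from Louvain on the weighted undirected projection at
  resolution 1.0 with a fixed seed (default 0); modularity is reported for
  that partition.  Community counts are reproducible only jointly with the
  seed.
- **Betweenness** is directed and weighted, treating distance as 1/weight
  (stronger connections are shorter), normalized by (n−1)(n−2).
- **Assortativity** is total-degree assortativity on the undirected
  projection.
- **Rich club** Φ(k) is the *unnormalized* directed density of the subgraph
  induced by nodes with total degree (in + out) ≥ k, defined while at least
  two nodes qualify.  Φ(k) = 1 therefore means "fully connected", which is
  the reading used when quoting a peak; no degree-preserving null model is
  applied.
- The **random-graph baseline** ⟨L⟩ = ln(n)/ln(m/n) is the standard
  Erdős–Rényi approximation of the mean shortest path, defined only for mean
  degree m/n > 1.

Unweighted conventions for path/clustering against weighted conventions for
betweenness/modularity reflect the mixed usage common in connectomics
reports (hop-like path lengths alongside strength-aware centralities).

## Output specialization

Outputs are pooled by postsynaptic **DN type label**, so left/right copies
of a type count as one target.  Per presynaptic neuron: dominant fraction
(share of total DN-directed strength onto the strongest type; ties break
lexicographically and are flagged), Shannon entropy in bits of the
type-level strength proportions, and the strongest off-target type's summed
strength.  Only DN-directed outputs enter the denominator.

The cutoff separating multi-target from single-type biased neurons is found
by scanning candidate cutoffs (midpoints of consecutive distinct observed
fractions) and minimising Otsu's within-class variance w₀σ₀² + w₁σ₁².  Otsu
was chosen as the canonical, fully reproducible two-population separator;
any error functional with a unique interior minimum would serve.  The split
is additionally characterised by a two-sample Kolmogorov–Smirnov test
between the groups.  Classification applies the cutoff (≥ keeps) plus an
off-target cap: a strongest off-target type of **15 or more** synapses
disqualifies, since an off-target pathway that strong implies real influence
elsewhere.  Classification is monotone in the cutoff by construction.

## Morphology

Cable length is the sum of parent–child Euclidean segment lengths of a
single-rooted SWC tree, ignoring radii; it is invariant to node reindexing
and rigid motion.  Strength-vs-length fits are ordinary least squares with
intercept (linear and quadratic; the quadratic can never have lower R²).
The 2-D KDE uses a Gaussian kernel with Scott's-rule bandwidth by default.

## LIF network model

Units are mV / ms / nS / pF (dimensionally consistent: nS·mV/pF = mV/ms).

| parameter | value | notes |
|---|---|---|
| C_m | 72 pF | all neurons |
| R_m | 25 MΩ (GF), 300 MΩ (others) | τ_m = 1.8 ms / 21.6 ms |
| V_rest = V_reset | −55 mV | |
| V_th | −40 mV | |
| τ_ref | 2 ms | absolute, voltage clamped at reset |
| J_ach, τ_ach, E_ach | 0.27 nS, 1.1 ms, 0 mV | nicotinic |
| J_gaba, τ_gaba, E_gaba | 0.8 nS, 5.4 ms, −60 mV | GABA_A (chloride) |
| J_glut, τ_glut, E_glut | 0.8 nS, 5 ms, −60 mV | GluCl (chloride) |
| background | Poisson 30 Hz, 5 nS, ach kinetics | independent per neuron |
| probe drive | Poisson 10 Hz, 40 nS | GF-analog stimulation |
| dt, duration | 0.1 ms, 2000 ms | defaults |

Choices the equations leave open:

- **Synaptic increment scales with synapse count**: Δg_x = J_x × weight, with
  no per-synapse saturation.
- **Channel = presynaptic transmitter**, consistent with the polarity map.
- **Delay** is one time step (0.1 ms) for all connections; zero-delay
  same-step delivery would make the update order inside a step significant.
- **Background drive** uses ach kinetics with a 5 nS increment; the drive is
  described only by rate and conductance, so the fast excitatory channel is
  the natural carrier.
- **"Electrical" stimulation** in the 24 Hz protocol is a conductance pulse
  through the ach channel; periodic (not jittered) pulses keep the per-pulse
  response bookkeeping well defined and time-locked.

**Integrator.**  Exponential Euler: conductance decay is integrated exactly
each step; the membrane equation is advanced with the exact
constant-coefficient solution using each channel conductance evaluated at
the midpoint of its analytic decay over the step.  The midpoint evaluation
matters at the GF's 1.8 ms time constant with τ_ach = 1.1 ms: it keeps a
single weighted EPSP within 0.01 mV of a dense adaptive reference
integration at dt = 0.1 ms (the test suite verifies ~6 × 10⁻⁴ mV), where a
start-of-step evaluation would not.  Spikes are detected after the membrane
update (v ≥ V_th), reset to V_reset, and clamped for τ_ref; between resets
the voltage is confined to [min(E_gaba, V_reset), E_ach] because every term
drives v toward a reversal potential inside that interval.

**Calibration.**  The just-subthreshold pulse amplitude is found by
bisection on an isolated copy of the probe — exact, because in a quiescent
network no other neuron can ever spike — and the bracket is tightened until
lower/upper > safety (0.95); the returned amplitude (safety × upper) alone
never fires the probe while upper does.

**Protocols.**  Scenario experiments pair trials by seed across conditions:
A (probe drive only), B (probe + octet), C (probe + non-octet presynaptic
partners, octet deleted), D (probe + octet, non-octet partners deleted),
E (probe only, octet deleted).  Deletion removes a neuron's spikes and all
its synapses; silencing removes only a specified directed synapse set.
Spike-count distributions are compared with two-sided Mann–Whitney U tests;
subthreshold histograms exclude samples within τ_ref of a spike.  In the
24 Hz protocol the octet is driven at 40 Hz / 40 nS during the middle third
of the run — a deliberately strong drive emulating sustained optogenetic
depolarization of the octet — and a pulse counts as a response if the probe
spikes within 5 ms.

## Synthetic benchmark

The generator reproduces the statistical features the analyses depend on, at
a scale (300 DN + 120 AN + 80 IN = 500 neurons) that keeps every test fast:

- **Sparsity**: per-motif ordered-pair densities 0.010 (DN→DN), 0.012
  (AN→DN), 0.007 (IN→DN).  Each motif's edge count is drawn binomially at
  its density and the planted structure is carved out of that budget, so
  realized densities stay within binomial sampling error of the targets.
- **Weights**: shifted geometric on {6, 7, …} with median ≈ 10 — skewed,
  and every edge survives the strength scrub by construction.
- **Transmitters**: mirror DN pairs share a transmitter drawn cholinergic
  with probability 0.9, so homotypic (same-type) edges are ~90% cholinergic;
  heterotypic DN→DN edges pick a cholinergic presynaptic neuron with
  probability 0.6; AN and IN populations are half cholinergic, half
  inhibitory (GABA/glutamate split evenly).
- **Mirror pairing**: 90% of each class is laid out as L/R type twins;
  mirror DN pairs connect at elevated probability (0.35 per direction),
  producing the contralateral same-type diagonal.
- **Planted hub**: one mirror DN pair of type `DNp01`; each hub's
  presynaptic pool is sampled so its distinct-partner count lands near 97
  (binomial, so within a few √97 of target).
- **Planted octet**: 8 ascending neurons of one type, cholinergic, each with
  a strong edge (80–120 synapses) to its primary hub, a weaker edge (20–40)
  to the mirror hub, and at most two off-target edges capped at 14 synapses
  — below the 15-synapse exclusion rule by construction, with dominant
  fractions ≥ 0.75.
- **Skeletons**: random branching trees whose total cable length is drawn
  with a configurable population correlation (default 0.95) to total input
  strength.

What passing on this benchmark shows: the pipeline's statistics are computed
correctly (they match brute-force oracles and recover planted structure),
and the circuit-level directional effects — octet drive raises probe
excitability, silencing the monosynaptic pathway removes the gain,
just-subthreshold pulses become suprathreshold during octet drive — follow
from the wiring plus the stated biophysics.  What it does not show: the
generator does not reproduce the real dataset's absolute scale (23k neurons,
1.15M connections), its type taxonomy, spatial synapse placement, or any
quantity that depends on them (absolute spike counts, exact cutoff values,
raster structure).  Real-data checks (scrub totals, the 884-node/2757-edge
motif, the GF's 97 partners, the rich-club peak 0.076 at k ≥ 18) are
implemented and run whenever a local MANC v1.2.1 CSV export is present
under `data/manc/`.

## Problem sizes and numerics

Default analysis scale is the 500-neuron synthetic network; simulations use
dt = 0.1 ms over 2 s (3 s for the windowed 24 Hz protocol), 5–10 trials per
condition with seed-paired comparisons.  Degenerate inputs are handled
explicitly: single-node graphs report NaN sentinels rather than zeros; a
dominant-fraction distribution with a single distinct value raises rather
than fabricating a cutoff; correlation on fewer than three DNs reports NaN;
mean-degree ≤ 1 makes the random-graph baseline undefined and raises.
Louvain community counts, Poisson drives, and the generator are all
deterministic given their seeds.

## Known limitations

- Single-compartment neurons: no spike-initiation-zone geometry, no
  dendritic filtering; in-vivo phenomena tied to those (e.g. a second spike
  initiation zone) are outside the model class.
- No gap junctions, neuromodulation, conductance saturation, or short-term
  plasticity.
- The Otsu error functional is one defensible reading of "threshold by error
  minimisation"; cutoffs from other functionals can differ on real data.
- Rich-club values are unnormalized; comparisons against degree-preserving
  nulls require an extra step.
- The symbolic-regression variant of the morphology fit is intentionally not
  implemented.
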