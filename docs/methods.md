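# Methods

## The model

A neuron is a single-compartment conductance-based membrane coupled to the
slow chemistry of its extracellular micro-domain.

**Membrane and gating.** The membrane potential obeys

    C_m dV/dt = -(I_Na + I_K + I_AHP + I_L) + I_stim,

with a transient sodium current `I_Na = g_Na m^3 h (V - E_Na)`, a delayed
rectifier `I_K = g_K n^4 (V - E_K)`, a calcium-gated afterhyperpolarization
current `I_AHP = g_AHP [Ca]_i/(1+[Ca]_i) (V - E_K)` (pyramidal cells only —
it produces their spike-frequency adaptation), and a three-component leak
(K+, Na+, Cl-).  Gates follow first-order kinetics
`dx/dt = phi [alpha_x(V)(1-x) - beta_x(V) x]` with the rate functions of
this model family; the two ratio-form rates (`alpha_m`, `alpha_n`) have
removable singularities that are evaluated by their analytic limits.  The
full activation gate `m` is dynamic, not an instantaneous `m_inf`
approximation, because the filter tracks it as a state variable.

**Ion microenvironment.** Extracellular potassium `[K]_o` and intracellular
sodium `[Na]_i` are dynamic (per-second time base, rescaled inside the
millisecond RHS):

    d[K]_o/dt  = gamma*beta*I_K,flux - 2*beta*I_pump - I_glia - I_diff (+ lateral)
    d[Na]_i/dt = -gamma*I_Na,flux - 3*I_pump

`I_pump` is a product of sigmoids saturating in `[Na]_i` and `[K]_o`
(electrogenic 3 Na+ : 2 K+ stoichiometry — the factor `beta` = 7 converts
intracellular-equivalent fluxes into the seven-fold smaller extracellular
volume); `I_glia = G_glia/(1+exp((18-[K]_o)/2.5))` is a saturating glial
uptake; `I_diff = epsilon([K]_o - K_bath)` is Fickian exchange with a
distant reservoir (bath in vitro, vasculature in vivo).  Intracellular K+
and extracellular Na+ are slaved to `[Na]_i` by electroneutrality
(`K_i = 140 + (18 - Na_i)`, `Na_o = 144 - beta (Na_i - 18)`; identities
hold to machine precision by construction), and the Nernst equation feeds
the concentrations back into `E_K`, `E_Na` — the loop that makes rising
`[K]_o` epileptogenic.  `[Ca]_i` (arbitrary units) drives only the AHP
current and is integrated on the millisecond base with an 80 ms decay; a
per-second base would abolish spike-frequency adaptation.

**Geometry constants.** `gamma = A/(F Vol) = 3/(r F)` for a spherical
micro-domain of radius 7 um gives 0.0445 mM cm^2/uC; multiplied by `beta`
it yields the ~0.31 factor scaling the K+ current in the `[K]_o` equation.
`epsilon = 2D/dx^2` with `D = 2.5e-6 cm^2/s` and 20 um capillary spacing
gives 1.25 /s.  A separate, larger effective radius (20 um) converts
pipette currents to densities: a patch current spreads over the whole
somatodendritic membrane, while `gamma` is set by the somatic
surface-to-volume ratio.  With that conversion, 100 pA ~ 2 uA/cm^2, which
drives ~63 Hz repetitive spiking and a clean return to rest; using the 7 um
area instead (16 uA/cm^2) produces potassium runaway and afterdischarges,
inconsistent with a cell that stops firing when the pulse ends.

**Coupling.** The PC and OLM interneuron exchange AMPA (PC->IN, 0.17
mS/cm^2) and GABA_A (IN->PC, 0.84 mS/cm^2) conductances gated by first-order
synaptic variables `s` (sigmoidal steady state in the presynaptic voltage),
and extracellular K+ diffuses laterally with pairwise-conservative exchange
`delta([K]_o^other - [K]_o^self)`.  Each synapse is multiplied by a
depolarization-block gate `chi(eta)`: `eta` low-passes (tau = 800 ms) a
sigmoidal indicator of sustained presynaptic depolarization (threshold -40
mV, so brief spikes barely move it while a depolarized plateau drives it to
1), and `chi` is a descending sigmoid in `eta` (half point 0.6, slope 0.06).
The functional form and constants are this package's own documented choice;
only the gate's role (synaptic input drops to zero in depolarization block)
and the synaptic strengths are inherited from the source model family.

## Numerics

Fixed-step classical RK4 at dt = 0.01 ms, for both truth generation and the
filter's substeps (10 substeps per 0.1 ms observation interval).  Truth
integration aborts with a diagnostic if |V| > 150 mV or any state becomes
non-finite.  Order-4 convergence is verified on subthreshold segments; on
spiking trajectories pointwise comparisons are phase-limited (a ~1 us spike
shift on a 500 mV/ms upstroke looks like ~0.5 mV), so convergence is
asserted on the subthreshold prefix and on spike times.

Sigma-point propagation additionally projects each point onto the model's
valid operating box ([K]_o in [0.3, 80] mM, gates in [0, 1], ...) after
every substep: far outside the data-constrained region the gate kinetics
become stiff for RK4 (beta_m ~ 230/ms below -120 mV), and an ensemble
member there carries no useful information anyway.  The posterior mean is
projected onto the same box after each update (standard constrained-filter
projection).  Tracked parameters are never clamped; log-transformed
parameters are exponentiated with a +/-14 cap on the exponent.

## The filter

Equal-weight unscented Kalman filter: 2D sigma points at
`x_bar +/- rows of sqrt(D P)` (Cholesky of `D*P`, symmetric-eigendecomposition
fallback), plain averages for all means, prior covariance = propagated
scatter + Q, and a measurement update that by default redraws sigma points
from the conditioned prior.  On linear-Gaussian systems this is
algebraically identical to the closed-form Kalman recursion, which the test
suite asserts to 1e-8 over 100 steps (scalar and 2-D).  Covariances are
conditioned by symmetrization plus an eigenvalue floor at
`1e-10 * trace(P)/D`.

Joint state-and-parameter estimation appends tracked parameters to the
state with trivial dynamics; positivity-constrained parameters are carried
in log space.  Q and R are config: R defaults to the observation-noise
variance; Q defaults per component class (1e-2 for voltages, 1e-6 for
gates/synapses, 1e-7 for concentrations, per 0.1 ms step) with a
random-walk variance of 1e-7 for slowly varying tracked parameters and
3e-3 for the deliberately time-varying `alpha_m`.

## Synthetic recordings (twin experiments)

All validation uses twin experiments: the model generates truth, V is
subsampled every 0.1 ms and corrupted with i.i.d. Gaussian noise
(SD 0.5 mV — the recordings being emulated are "noisy" without a stated
magnitude; the value is config), and the filter sees only the noisy V.
What passing twins shows: the estimator recovers the hidden states and
parameters *of this model* from partial data.  What it cannot show:
robustness to real-electrode artifacts, to cell-to-cell variability, or to
structural model error beyond the deliberately crippled/fixed-ion variants.

**Spiking PC.** 100 pA for 1 s after 200 ms of rest; 63 spikes confined to
the pulse.  The initial state is the quasi-steady rest reached after a 20 s
settle (Na_i ~ 19 mM); the exact mathematical equilibrium (Na_i ~ 23 mM,
located by root solving) is less excitable and is not what a briefly
patched cell sits at.

**Seizure preset.** Spontaneous recurrent seizure-like events require a
regime where quiet-state K+ clearance barely balances release.  With the
physiological bath (3 mM) the pump alone clamps `[K]_o` below ~5 mM for any
(G_glia, epsilon) combination (verified by scan), while spontaneous firing
needs `[K]_o` ~ 8 mM, so the preset combines limited bath exchange
(epsilon = 1.3 /s), near-physiological glia (G_glia = 60 mM/s — chosen so
glial uptake carries a non-negligible ~12% of clearance at the episode
peak), stronger adaptation (g_AHP = 0.05, letting the Na_i/pump feedback
terminate episodes before depolarization block), and a just-suprarheobase
DC bias (2.3 uA/cm^2) standing in for the raised excitability of a seizing
preparation.  The slow subsystem carries a `time_scale` factor of 12 for
desk-scale runs: it uniformly speeds the concentration equations, which
compresses the episode period (~12.4 s) while preserving the slow
(K_o, Na_i) orbit by time-scale averaging — interictal baseline 3.2 mM,
episode peak 6.7 mM, matching the 3 -> ~7 mM excursion being emulated.  A
20 s burn-in aligns the shipped 12 s recording on one complete episode.

**PC-IN pair.** The interneuron's micro-domain is buffered much more weakly
(G_glia = 2, epsilon = 0.2) and driven harder (3.1 uA/cm^2): after ~1 s of
intense firing it locks into a depolarized non-spiking state, `eta_i`
saturates, `chi(eta_i)` collapses below 0.05, and the disinhibited PC
roughly quadruples its firing rate — the interplay pattern in which the
collapse of inhibition releases seizure-like excitation.  Lateral K+
diffusion (delta = 0.05 /s) lets the IN's potassium flood bias the PC.

## Experiment design notes

* **Crippled-model tracking** starts assimilation 10 ms before the pulse:
  at rest the Na+ current is invisible in V, so the tracked parameter's
  random walk is unconstrained and can drift into a basin from which the
  filter cannot recover once spiking starts.  The spiking epoch itself
  keeps the parameter observable.  The "cannot spike by itself" check
  freezes the crippled model at the *median* tracked value (the arithmetic
  mean is inflated by the brief spike-phase excursions of a quantity that
  spans two orders of magnitude).
* **Tracking accuracy limit.** The tracked `alpha_m` follows its true
  voltage-dependent value with a ~2 ms lag set by the information rate
  (sensitivity of V to `alpha_m` over one interval vs. measurement noise);
  during the afterhyperpolarization the parameter is strictly unobservable
  (m ~ 0 regardless).  At the 63 Hz firing rate of the fixture this lag is
  a substantial fraction of the inter-spike interval, and the median
  pointwise relative deviation settles near 45% even though every spike is
  reconstructed and the gate trajectories track closely.  Raising the
  parameter's process noise below the lag floor destabilizes the joint
  estimate (the parameter walks off during information-free phases).
* **Parameter identifiability.** In the seizure twin, epsilon and K_bath
  recover to within a few percent from 30% initial errors.  G_glia does
  not: below ~10 mM the glial sigmoid (midpoint 18 mM) is exponentially
  suppressed, and its effect on the K_o path is nearly collinear with
  small (epsilon, K_bath) adjustments, so the filter's G_glia posterior SD
  never contracts and the estimate stays near its prior.  This is a
  physical identifiability limit of V-only assimilation in the 3-7 mM
  regime, not a filter defect; the driver reports it like the others.
* **Cross-cell reconstruction** is scored at two timescales.  The 100 ms
  envelope correlation (0.97-0.99 in both directions) captures the slow
  reciprocal interplay the experiment is about; the raw 0.1 ms correlation
  additionally requires spike-by-spike synchronization of the unobserved
  cell, which the weak AMPA coupling (sub-noise single-spike signatures)
  cannot support.  The decoupled control is asserted on the raw
  correlation (~0.0), because with coupling removed the envelope still
  follows the shared deterministic model — the reconstruction "reverts to
  the prior dynamics".
* **AIC comparison** uses the residual sum of squares of the a-priori
  predicted observation, `AIC = N ln(RSS/N) + 2k`, with k = 4 extra
  microenvironment parameters for the full model and k = 0 for the
  fixed-ion variant (concentrations pinned at 4 mM / 18 mM).  On the
  seizure twin the full model wins by a wide margin across noise seeds.

## Problem sizes

Shipped runs are sized for a single CPU: 12 s seizure records (one full
episode; 120k observations), 8 s pair records, 1.5 s spiking records, and
three noise seeds for the AIC comparison.  Longer records (tested to 36 s)
change none of the conclusions.

## Known limitations

* Two cells at most; no spatial networks, no multi-compartment dendrites.
* The pump is a sigmoid product, not a kinetic cycle model; the source
  model family reports more realistic pumps behave substantially alike.
* The depolarization-block gate constants are plausible but not fitted to
  data; they are config, and the pair preset depends on them.
* No smoothers and no adaptive noise estimation: the filter is strictly
  causal with fixed Q, R.
* The `time_scale` compression is exact only in the averaging limit; at
  factor 12 the episode peak shifts by a few percent relative to the
  unscaled model.
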