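# Methods

This note records the model definition, parameter provenance, numerical methods and
the main design decisions behind the package, at the level of detail needed to
interpret or modify results.

## 1. Network model

### Populations

Two mirror-symmetric action channels (A and B), each containing cortex (Cx),
direct- and indirect-pathway striatal projection neurons (dSPN, iSPN), external and
internal pallidum (GPe, GPi), subthalamic nucleus (STN) and thalamus (Th), plus
shared (channel-unspecific) cortical (CxI) and striatal (FSI) interneuron pools.
Default sizes: Cx 204, CxI 186, dSPN/iSPN/FSI/GPi/Th 75, GPe/STN 750 per channel
where channel-specific (4269 neurons total).

### Neurons

Integrate-and-fire-or-burst dynamics:

    C dV/dt = -g_L (V - V_L) - g_T h H(V - V_h)(V - V_T) - I_syn - I_ext

with hard threshold V_th = -50 mV, reset V_reset = -55 mV, refractory period 1-2 ms.
The T-current gate `h` decays toward 0 above V_h = -65 mV with τ_h⁻ = 20 ms and
recovers toward 1 below with τ_h⁺ = 100 ms. The T-current is active in STN and Th
(g_T = 15 nS) and absent elsewhere. Principal cells use C = 500 pF, g_L = 25 nS;
interneuron pools C = 200 pF, g_L = 20 nS; thalamus g_L = 18 nS; V_L = -70 mV
everywhere. **Choice of g_T:** at g_T = 60 nS the STN and thalamic populations
become relaxation oscillators with a bistable baseline; 15 nS keeps the baseline
stationary while preserving rebound excitability. The value is configurable.

### Synapses

Conductance-based, with reversal potentials 0 mV (AMPA/NMDA) and -80 mV (GABA) and
exponential gate decay τ_AMPA = 2 ms, τ_GABA = 5 ms, τ_NMDA = 100 ms. NMDA carries
the voltage-dependent magnesium-block factor 1/(1 + e^(-0.062 V)/3.57) and saturates
with rate α = 0.63 per presynaptic spike.

**NMDA gating semantics.** Each (postsynaptic neuron, projection) pair keeps one
accumulator storing the *afferent-averaged* NMDA gate: a presynaptic spike adds
α(1 - s)/K, where K is that neuron's realized in-degree on the projection, and the
synaptic current uses conductance g·K·s. This is the standard per-afferent
saturation (each of K synapses saturates independently at gate 1), expressed with a
single state variable per pair. The alternative — a single accumulator with jumps
α(1 - s), capping the whole projection at one synapse's conductance — makes every
NMDA pathway dynamically irrelevant at the tabulated conductances (0.027-1.5 nS)
and supports no decision cascade, so it was rejected. AMPA/GABA gates sum unit
per-spike jumps and decay exponentially, as usual.

### Connectivity

Connection probabilities and conductances follow the connectivity table in
`cbgt.network.connection_table()`. Within-channel projections connect like-labeled
subpopulations; three projections are diffuse across channels (GPe→GPe collaterals,
STN→GPi, Th→Cx). Shared pools (CxI, FSI) project to and receive from both channels.

**Channel-mirrored anatomy (design decision).** Drawing every Bernoulli adjacency
pattern independently leaves quenched anatomical asymmetry between channels; across
anatomical seeds this biased the choice split by up to ±0.15 even though the model
is symmetric in expectation. The default (`channel_symmetric=True`) draws one
pattern per projection and reuses it for the mirrored branch, making the realized
network exactly isomorphic under A↔B relabeling, so only dynamical noise breaks the
tie. Independent draws remain available (`channel_symmetric=False`).

**Free weights.** Fourteen weight groups are treated as free parameters of the
sweep; where a projection has both AMPA and NMDA components the two conductances
are yoked and scaled proportionally by one group. `WeightConfig` maps a 14-vector
to the conductance table; bounds for the sweep are per-group and enforced at
construction.

### Background drive

Every population receives an independent Ornstein–Uhlenbeck conductance per neuron
(AMPA, and for cortex also GABA), parameterized by (rate Hz, efficacy nS,
connection count n): stationary mean = rate·efficacy·n·τ, noise scale =
efficacy·√(rate·n/1000), clipped at zero. The drive parameters in
`cbgt.config.default_external_drives()` were calibrated against the target baseline
and task firing-rate ranges for each population (see `DEFAULT_RATE_RANGES`) and the
control network's behavior, by sequential damped per-population tuning; they are
frozen as package defaults. Cortex uses a large, nearly balanced AMPA+GABA pair so
that the small stimulus rate step (2.2 → 2.5 Hz) produces a ~35-40 Hz cortical
surge — the high-noise, mean-balanced regime that makes a steep cortical f-I curve
compatible with a low-rate baseline.

With the tabulated conductances, feedforward FSI inhibition largely cancels direct
cortical drive to the SPNs during the stimulus: decisions are carried mostly by the
direct cortico-thalamic route with modest pallidal modulation, and SPN rates stay
low, within their physiological ranges, throughout.

### Trial protocol

200 ms settling at the 2.2 Hz cortical background rate, then a step to 2.5 Hz. A
choice occurs when either thalamic channel's trailing 20-ms window rate crosses
30 Hz; RT is the time from stimulus onset to crossing; trials time out at 800 ms.
Trials are stateless: each starts from a fresh random initial condition, and the
post-decision hold is not simulated.

## 2. Numerics of the simulator

Forward Euler at dt = 0.1 ms. The inner loop is a numba-compiled kernel processing
500-step chunks; OU noise increments are pre-generated per chunk with numpy's PCG64
generator, and the threshold detector keeps a persistent ring buffer across chunks
so detection is independent of chunking. Gate decays use exact exponential factors.
Seeds are derived hierarchically with `numpy.random.SeedSequence.spawn`, so per-trial
streams are independent and reproducible; all derived seeds are masked to 31 bits.

## 3. Drift-diffusion model

Four-parameter Wiener first-passage model: boundary separation `a`, drift `nu`,
non-decision time `t`, relative starting point `z` (diffusion coefficient fixed at
1). The likelihood uses the Navarro–Fuss large-/small-time series for the
first-passage density with automatic series selection; upper-boundary densities use
the (ν, z) → (-ν, 1-z) reflection. Fitting is multi-start L-BFGS-B maximum
likelihood (bounds a∈[0.1,8], ν∈[-10,10], z∈[0.02,0.98], t below the minimum
observed RT); samples with single-boundary behavior are flagged. A short Metropolis
chain around the optimum provides a DIC estimate. Simulation uses vectorized
Euler-Maruyama with a Brownian-bridge crossing correction
(p_cross = exp(-2 d₀ d₁ / dt)), which removes the O(√dt) first-passage bias; the
driftless mean exit time z·a·(a - z·a) + t and the closed-form absorption
probability serve as oracles in the tests.

## 4. Weight sweep and bound calibration

Classic Latin hypercube sampling (independent per-dimension bin permutations) over
the 14 weight groups. `calibrate_bounds` geometrically shrinks any group's bounds
toward the control value (factor 0.8 per iteration, at most 20) while sampled
networks violate the physiological firing-rate ranges, guided by regression slopes
of rate violations on weights.

## 5. Control-ensemble analysis

Rate features per network: 7 channel-summed and 7 channel-difference (A-B)
population rates plus CxI and FSI (16 columns), averaged over decided trials.

* **CCA** (scikit-learn's NIPALS implementation) links W→R and R→P. Predictive
  quality is the pooled-entry R², `1 - Σ(y-ŷ)²/Σ(y-ȳ)²` over all matrix entries.
* **Component count** is selected by 4-fold cross-validation on *contiguous* row
  blocks, taking the count with the best mean held-out score. Row counts must be a
  multiple of the fold count (callers trim).
* **Canonical loadings** are Pearson correlations between original variables and
  canonical variates.
* **Sensitivity normalization** of DDM parameters: each column is centered and
  multiplied by Δx, the centered difference of the DDM's Monte-Carlo mean RT with
  respect to that parameter (h = 0.1, 10⁵ runs, dt = 10⁻³, common random numbers),
  so that distances in parameter space are commensurate in milliseconds of RT.
* **Clustering**: K-means (10 restarts) on the sensitivity-normalized loadings over
  a K grid, selecting K by mean silhouette; a brute-force silhouette implementation
  cross-checks the library one in the tests.

## 6. Surrogate data

`generate_wrp` plants `r` shared latent directions between W (14 cols), R (16 cols)
and P (4 cols): for target canonical correlation ρ the linked block loads on the
latent with coefficient ρ/√(1-ρ²) against unit noise, giving *population* canonical
correlation exactly ρ along orthonormal directions. The surrogate emulates only the
low-rank linear cross-covariance structure the analysis is designed to detect — not
RT distributions, censoring patterns, nonlinearities, or any simulator physics —
and is used to verify component-count selection, planted-correlation recovery and
the analysis front end with known ground truth. `generate_behavior` draws DDM
choice/RT samples with optional uniform censoring for testing the fitting code.

## 7. Reference statistics and tolerances

The control network's reference behavior is a 45.3 % A-choice fraction and an
86.45 ms mean RT over 300-trial sessions. Both are stochastic: at n = 300 the
choice fraction has binomial SE ≈ 2.9 points, and the session mean RT varies by a
few ms across seeds; the acceptance tests use ±3 SE and ±15 ms windows. Reduced
problem sizes used in the test suite (e.g. 8-network sweeps, 30-trial sessions,
surrogate n = 200-300) were chosen to exercise every code path within a small
compute budget while keeping the statistical oracles sharp.

## 8. Known limitations

* External-drive parameters are calibrated, not literature-derived; other drive
  settings satisfying the same rate ranges may behave differently.
* The DDM ignores the ~60 ms of RT below `t` structure (no variability in
  non-decision time, drift or starting point across trials).
* CCA is linear; nonlinear weight-behavior couplings would load diffusely.
* Sensitivity normalization uses mean RT only; boundary effects on accuracy are
  not part of the metric.
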