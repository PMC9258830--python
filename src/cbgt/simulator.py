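"""Integrate-and-fire-or-burst network integration with conductance synapses.

Membrane dynamics (per neuron)::

    C dV/dt = -gL (V - VL) - gT h H(V - Vh)(V - VT) - Isyn - Iext
    dh/dt   = -h / tau_h_minus            if V >= Vh
            = (1 - h) / tau_h_plus        if V <  Vh

with a hard spike at ``V >= V_spike`` (reset to ``V_reset``, refractory
clamp for ``t_ref``).  The synaptic current sums AMPA, NMDA and GABA
conductances; the NMDA term carries the voltage-dependent magnesium-block
factor ``1 / (1 + exp(-0.062 V) / 3.57)``.  Synaptic gating keeps one
accumulator per (postsynaptic neuron, afferent projection): AMPA/GABA
accumulators jump by one per afferent spike and decay exponentially, the
NMDA accumulator jumps by ``alpha (1 - s)`` so it saturates below one.

External input to every neuron is a mean-reverting (Ornstein-Uhlenbeck)
conductance whose stationary mean equals
``rate x efficacy x n_connections x tau`` -- the diffusion limit of a
Poisson synaptic bombardment -- clipped at zero.

NMDA gates saturate per afferent synapse: the row accumulator stores the
afferent-averaged gate (still in [0, 1], jumping by ``alpha (1 - s) / K``
per spike for in-degree ``K``) and the row's conductance scales with K,
so a projection's NMDA drive grows with its anatomical convergence just
as the AMPA/GABA sums do.

Integration is forward Euler at ``dt = 0.1 ms`` with exponential updates
for the pure-decay gating variables; the network loop is JIT-compiled.
Units: mV, ms, nS, pF (so currents are pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .network import (
    PopulationSpec, Projection, population_slices, total_neurons,
)

DT_MS = 0.1


class NumericalDivergenceError(RuntimeError):
    """A membrane potential became non-finite during integration."""


@dataclass(frozen=True)
class ReceptorParams:
    """Synaptic receptor kinetics and reversal potentials."""

    tau_AMPA: float = 2.0     # ms
    tau_NMDA: float = 100.0   # ms
    tau_GABA: float = 5.0     # ms
    alpha: float = 0.63       # NMDA rise rate per afferent spike
    V_E: float = 0.0          # mV, excitatory reversal
    V_I: float = -80.0        # mV, inhibitory reversal

    def __post_init__(self):
        if min(self.tau_AMPA, self.tau_NMDA, self.tau_GABA) <= 0:
            raise ValueError("receptor time constants must be positive")
        if self.tau_NMDA <= self.tau_AMPA:
            raise ValueError("NMDA must decay more slowly than AMPA")

    def tau(self, receptor: str) -> float:
        return {"AMPA": self.tau_AMPA, "NMDA": self.tau_NMDA, "GABA": self.tau_GABA}[receptor]


@dataclass(frozen=True)
class IFBParams:
    """Integrate-and-fire-or-burst membrane parameters for one region."""

    C: float = 500.0          # pF
    g_L: float = 25.0         # nS
    V_L: float = -70.0        # mV
    g_T: float = 0.0          # nS, low-threshold Ca conductance
    V_T: float = 120.0        # mV, Ca reversal
    V_h: float = -60.0        # mV, burst-gate switch voltage
    tau_h_plus: float = 100.0   # ms, de-inactivation below V_h
    tau_h_minus: float = 20.0   # ms, inactivation above V_h
    V_spike: float = -50.0    # mV, spike-emission threshold
    V_reset: float = -55.0    # mV
    t_ref: float = 2.0        # ms

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if self.tau_h_plus <= 0 or self.tau_h_minus <= 0:
            raise ValueError("gating time constants must be positive")
        if self.V_reset >= self.V_spike:
            raise ValueError("V_reset must lie below V_spike")


#: Membrane defaults per region.  Only the thalamic leak conductance
#: (18 nS) is pinned by the firing-rate calibration of this model; the
#: remaining constants follow the conductance-based decision-circuit
#: model family this network descends from, and every value can be
#: overridden from configuration.  The burst-capable T-current is carried
#: by the thalamic and subthalamic populations.
DEFAULT_NEURON_PARAMS: dict[str, IFBParams] = {
    "Cx": IFBParams(),
    "CxI": IFBParams(C=200.0, g_L=20.0, t_ref=1.0),
    "dSPN": IFBParams(),
    "iSPN": IFBParams(),
    "FSI": IFBParams(C=200.0, g_L=20.0, t_ref=1.0),
    "GPi": IFBParams(),
    "GPe": IFBParams(),
    "STN": IFBParams(g_T=15.0),
    "Th": IFBParams(g_L=18.0, g_T=15.0),
}


@dataclass(frozen=True)
class ExternalDriveParams:
    """Mean-reverting background conductance for one (population, receptor)."""

    rate: float               # Hz per external connection
    efficacy: float           # nS added per external spike
    n_connections: int
    receptor: str = "AMPA"    # "AMPA" or "GABA"

    def __post_init__(self):
        if self.rate < 0 or self.efficacy < 0 or self.n_connections < 0:
            raise ValueError("drive parameters must be non-negative")
        if self.receptor not in ("AMPA", "GABA"):
            raise ValueError("external drive receptor must be AMPA or GABA")

    def stationary_mean(self, tau_ms: float) -> float:
        """rate x efficacy x n_connections x tau, in nS."""
        return self.rate * self.efficacy * self.n_connections * tau_ms / 1000.0

    def noise_scale(self) -> float:
        """Wiener amplitude (nS per sqrt(ms)) of the shot-noise diffusion limit."""
        return self.efficacy * np.sqrt(self.rate * self.n_connections / 1000.0)


# ---------------------------------------------------------------------------
# scalar reference operations (unit semantics; the JIT kernel mirrors these)

@dataclass
class NeuronState:
    """Dynamical state of a single neuron (reference implementation)."""

    V: float
    h: float = 0.0
    s_AMPA: float = 0.0
    s_NMDA: float = 0.0
    s_GABA: float = 0.0
    refractory_remaining: float = 0.0


def nmda_voltage_factor(V: float | np.ndarray):
    """Magnesium-block factor of the NMDA conductance."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(V)) / 3.57)


def advance_membrane(
    state: NeuronState,
    params: IFBParams,
    receptors: ReceptorParams,
    g_AMPA: float = 0.0,
    g_NMDA: float = 0.0,
    g_GABA: float = 0.0,
    I_ext: float = 0.0,
    dt: float = DT_MS,
) -> tuple[NeuronState, bool]:
    """One Euler step of the membrane and burst-gate dynamics.

    ``g_*`` multiply the neuron's gating accumulators; ``I_ext`` is an
    additional current in pA (positive = depolarizing).  Returns the new
    state and whether a spike was emitted.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(state.V):
        raise NumericalDivergenceError("membrane potential is non-finite")
    V, h = state.V, state.h
    spiked = False
    if state.refractory_remaining > 0:
        new_refr = max(0.0, state.refractory_remaining - dt)
        V_new = params.V_reset
    else:
        I_syn = (
            g_AMPA * state.s_AMPA * (V - receptors.V_E)
            + g_NMDA * state.s_NMDA * (V - receptors.V_E) * nmda_voltage_factor(V)
            + g_GABA * state.s_GABA * (V - receptors.V_I)
        )
        I_T = params.g_T * h * (V - params.V_T) if V >= params.V_h else 0.0
        dV = (-params.g_L * (V - params.V_L) - I_T - I_syn + I_ext) / params.C
        V_new = V + dt * dV
        new_refr = 0.0
        if V_new >= params.V_spike:
            spiked = True
            V_new = params.V_reset
            new_refr = params.t_ref
    if V >= params.V_h:
        h_new = h * np.exp(-dt / params.tau_h_minus)
    else:
        h_new = 1.0 + (h - 1.0) * np.exp(-dt / params.tau_h_plus)
    return replace(state, V=V_new, h=h_new, refractory_remaining=new_refr), spiked


def update_synaptic_gates(
    state: NeuronState,
    receptors: ReceptorParams,
    n_spikes_AMPA: int = 0,
    n_spikes_NMDA: int = 0,
    n_spikes_GABA: int = 0,
    dt: float = DT_MS,
) -> NeuronState:
    """Exponential decay plus per-spike jumps of the gating accumulators."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s_a = state.s_AMPA * np.exp(-dt / receptors.tau_AMPA) + n_spikes_AMPA
    s_g = state.s_GABA * np.exp(-dt / receptors.tau_GABA) + n_spikes_GABA
    s_n = state.s_NMDA * np.exp(-dt / receptors.tau_NMDA)
    for _ in range(n_spikes_NMDA):
        s_n += receptors.alpha * (1.0 - s_n)
    if min(s_a, s_g, s_n) < 0:
        raise RuntimeError("negative gating accumulator")
    return replace(state, s_AMPA=s_a, s_NMDA=min(s_n, 1.0), s_GABA=s_g)


def update_external_drive(
    S: float,
    params: ExternalDriveParams,
    receptors: ReceptorParams,
    dt: float = DT_MS,
    rng: np.random.Generator | None = None,
) -> float:
    """One step of the mean-reverting external-conductance process."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = receptors.tau_AMPA if params.receptor == "AMPA" else receptors.tau_GABA
    mu = params.stationary_mean(tau)
    noise = 0.0
    if rng is not None and params.noise_scale() > 0:
        noise = params.noise_scale() * np.sqrt(dt) * rng.standard_normal()
    S_new = S + dt * (mu - S) / tau + noise
    return max(0.0, S_new)


# ---------------------------------------------------------------------------
# spike records and rate estimation

@dataclass
class SpikeRecord:
    """Spike times (ms, strictly increasing) of one neuron."""

    neuron_id: int
    times: np.ndarray


@dataclass
class RateTrace:
    """Per-neuron-normalized instantaneous population rate (Hz)."""

    population: str
    times: np.ndarray         # ms
    rates: np.ndarray         # Hz
    window: float             # ms


def estimate_population_rate(
    spikes: list[SpikeRecord],
    population: str,
    n_neurons: int,
    window: float,
    time_grid: np.ndarray,
) -> RateTrace:
    """Causal trailing-window population rate.

    rate(t) = (# spikes in (t - window, t]) / (n_neurons * window), in Hz.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if n_neurons <= 0:
        raise ValueError("empty population")
    all_times = np.sort(np.concatenate([s.times for s in spikes])) if spikes else np.empty(0)
    t = np.asarray(time_grid, dtype=float)
    counts = np.searchsorted(all_times, t, side="right") - np.searchsorted(
        all_times, t - window, side="right")
    rates = counts / (n_neurons * window / 1000.0)
    return RateTrace(population, t, rates, window)


# ---------------------------------------------------------------------------
# packed network + JIT kernel

@dataclass
class PackedNetwork:
    """Flat array representation of populations, membranes and synapses."""

    populations: list[PopulationSpec]
    receptors: ReceptorParams
    n_neurons: int
    pop_labels: list[str]
    pop_slices: dict[str, slice]
    # per-neuron membrane parameters
    C: np.ndarray
    gL: np.ndarray
    VL: np.ndarray
    gT: np.ndarray
    VT: np.ndarray
    Vh: np.ndarray
    tauhp: np.ndarray
    tauhm: np.ndarray
    Vspike: np.ndarray
    Vreset: np.ndarray
    tref_steps: np.ndarray
    # projections
    proj_g: np.ndarray
    proj_rec: np.ndarray          # 0=AMPA 1=NMDA 2=GABA
    proj_post_start: np.ndarray
    proj_post_end: np.ndarray
    proj_decay: np.ndarray
    proj_indeg: np.ndarray        # (n_proj, n_neurons) realized in-degrees
    # outgoing synapse lists (CSR over neurons)
    out_ptr: np.ndarray
    out_target: np.ndarray
    out_proj: np.ndarray

    def drive_arrays(self, drives: dict[str, list[ExternalDriveParams]],
                     cx_rate: float | None = None) -> tuple[np.ndarray, ...]:
        """Per-neuron OU parameters (mu_a, sw_a, mu_g, sw_g).

        ``cx_rate`` overrides the rate of the cortical AMPA drive (the
        stimulus knob of the trial protocol).
        """
        mu_a = np.zeros(self.n_neurons)
        sw_a = np.zeros(self.n_neurons)
        mu_g = np.zeros(self.n_neurons)
        sw_g = np.zeros(self.n_neurons)
        for region, dlist in drives.items():
            labels = [lb for lb in self.pop_labels
                      if lb == region or lb.startswith(region + "_")]
            for d in dlist:
                if cx_rate is not None and region == "Cx" and d.receptor == "AMPA":
                    d = replace(d, rate=cx_rate)
                tau = (self.receptors.tau_AMPA if d.receptor == "AMPA"
                       else self.receptors.tau_GABA)
                for lb in labels:
                    sl = self.pop_slices[lb]
                    if d.receptor == "AMPA":
                        mu_a[sl] += d.stationary_mean(tau)
                        sw_a[sl] = np.hypot(sw_a[sl], d.noise_scale())
                    else:
                        mu_g[sl] += d.stationary_mean(tau)
                        sw_g[sl] = np.hypot(sw_g[sl], d.noise_scale())
        return mu_a, sw_a, mu_g, sw_g


def pack_network(
    populations: list[PopulationSpec],
    projections: list[Projection],
    neuron_params: dict[str, IFBParams] | None = None,
    receptors: ReceptorParams | None = None,
    dt: float = DT_MS,
) -> PackedNetwork:
    neuron_params = dict(DEFAULT_NEURON_PARAMS if neuron_params is None else neuron_params)
    receptors = ReceptorParams() if receptors is None else receptors
    slices = population_slices(populations)
    n = total_neurons(populations)

    def per_neuron(attr):
        arr = np.empty(n)
        for p in populations:
            arr[slices[p.label]] = getattr(neuron_params[p.name], attr)
        return arr

    tref = np.empty(n, dtype=np.int32)
    for p in populations:
        tref[slices[p.label]] = int(round(neuron_params[p.name].t_ref / dt))

    rec_code = {"AMPA": 0, "NMDA": 1, "GABA": 2}
    taus = {0: receptors.tau_AMPA, 1: receptors.tau_NMDA, 2: receptors.tau_GABA}
    n_proj = len(projections)
    proj_g = np.array([p.g for p in projections])
    proj_rec = np.array([rec_code[p.row.receptor] for p in projections], dtype=np.int32)
    proj_post_start = np.array([p.post_slice.start for p in projections], dtype=np.int32)
    proj_post_end = np.array([p.post_slice.stop for p in projections], dtype=np.int32)
    proj_decay = np.array([np.exp(-dt / taus[proj_rec[i]]) for i in range(n_proj)])
    proj_indeg = np.zeros((n_proj, n), dtype=np.float64)
    for pid, p in enumerate(projections):
        proj_indeg[pid, p.post_slice] = p.in_degrees()

    # outgoing CSR over all neurons: (target, projection) pairs
    deg = np.zeros(n, dtype=np.int64)
    for p in projections:
        pre0 = p.pre_slice.start
        deg[pre0:p.pre_slice.stop] += np.diff(p.indptr)
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(deg, out=out_ptr[1:])
    m = int(out_ptr[-1])
    out_target = np.empty(m, dtype=np.int32)
    out_proj = np.empty(m, dtype=np.int32)
    cursor = out_ptr[:-1].copy()
    for pid, p in enumerate(projections):
        counts = np.diff(p.indptr)
        n_pre = counts.size
        pre_ids = p.pre_slice.start + np.arange(n_pre)
        for i in range(n_pre):
            c0, c1 = p.indptr[i], p.indptr[i + 1]
            if c1 == c0:
                continue
            dst = cursor[pre_ids[i]]
            out_target[dst:dst + (c1 - c0)] = p.targets[c0:c1]
            out_proj[dst:dst + (c1 - c0)] = pid
            cursor[pre_ids[i]] += c1 - c0

    return PackedNetwork(
        populations=populations, receptors=receptors, n_neurons=n,
        pop_labels=[p.label for p in populations], pop_slices=slices,
        C=per_neuron("C"), gL=per_neuron("g_L"), VL=per_neuron("V_L"),
        gT=per_neuron("g_T"), VT=per_neuron("V_T"), Vh=per_neuron("V_h"),
        tauhp=per_neuron("tau_h_plus"), tauhm=per_neuron("tau_h_minus"),
        Vspike=per_neuron("V_spike"), Vreset=per_neuron("V_reset"), tref_steps=tref,
        proj_g=proj_g, proj_rec=proj_rec, proj_post_start=proj_post_start,
        proj_post_end=proj_post_end, proj_decay=proj_decay, proj_indeg=proj_indeg,
        out_ptr=out_ptr, out_target=out_target, out_proj=out_proj,
    )


@dataclass
class SimState:
    """Mutable per-trial state of a packed network."""

    V: np.ndarray
    h: np.ndarray
    refr: np.ndarray          # int32, remaining refractory steps
    s: np.ndarray             # (n_proj, n_neurons) gating accumulators
    Sa: np.ndarray            # external AMPA conductance, nS
    Sg: np.ndarray            # external GABA conductance, nS


def init_state(net: PackedNetwork, mu_a, mu_g, rng: np.random.Generator) -> SimState:
    """Randomized resting initial condition."""
    n = net.n_neurons
    V0 = net.VL + rng.uniform(0.0, 10.0, size=n)
    return SimState(
        V=V0,
        h=rng.uniform(0.0, 0.3, size=n),
        refr=np.zeros(n, dtype=np.int32),
        s=np.zeros((len(net.proj_g), n)),
        Sa=mu_a.copy(),
        Sg=mu_g.copy(),
    )


@njit(cache=True)
def _run_chunk(
    # state (mutated in place)
    V, h, refr, s, Sa, Sg,
    # per-neuron params
    C, gL, VL, gT, VT, Vh, tauhp, tauhm, Vspike, Vreset, tref_steps,
    # projections
    proj_g, proj_rec, proj_post_start, proj_post_end, proj_decay, proj_indeg,
    out_ptr, out_target, out_proj,
    # receptors / drives
    VE, VI, alpha, mu_a, sw_a, mu_g, sw_g, g_noise_idx, tau_a, tau_g,
    # pre-generated noise for this chunk
    noise_a, noise_g, tie_coins,
    # run control
    dt, step0, m,
    # decision detection (disabled when thr_counts <= 0); ring buffers and
    # running sums persist across chunks
    th_a_start, th_a_end, th_b_start, th_b_end, win_steps, thr_counts,
    ring_a, ring_b, det_sums,
    # per-subpopulation spike counting
    pop_of, pop_counts,
    # binned per-subpop counts (written if bins.shape[0] > 0)
    bins, bin_steps,
):
    n = V.size
    n_proj = proj_g.size
    exp_hm = np.exp(-dt / tauhm)
    exp_hp = np.exp(-dt / tauhp)
    gacc_a = np.zeros(n)
    gacc_n = np.zeros(n)
    gacc_g = np.zeros(n)
    spiked = np.empty(n, dtype=np.int32)
    sqdt = np.sqrt(dt)
    n_gn = g_noise_idx.size
    record_bins = bins.shape[0] > 0

    for t in range(m):
        step = step0 + t
        # --- external OU conductances
        xa = noise_a[t]
        for i in range(n):
            Sa[i] += dt * (mu_a[i] - Sa[i]) / tau_a + sw_a[i] * sqdt * xa[i]
            if Sa[i] < 0.0:
                Sa[i] = 0.0
            if mu_g[i] > 0.0 or Sg[i] > 0.0:
                Sg[i] += dt * (mu_g[i] - Sg[i]) / tau_g
        for k in range(n_gn):
            i = g_noise_idx[k]
            Sg[i] += sw_g[i] * sqdt * noise_g[t, k]
            if Sg[i] < 0.0:
                Sg[i] = 0.0

        # --- synaptic conductance accumulation (per projection, g-weighted)
        for i in range(n):
            gacc_a[i] = Sa[i]
            gacc_n[i] = 0.0
            gacc_g[i] = Sg[i]
        for p in range(n_proj):
            g = proj_g[p]
            d = proj_decay[p]
            rec = proj_rec[p]
            row = s[p]
            if rec == 0:
                for i in range(proj_post_start[p], proj_post_end[p]):
                    row[i] *= d
                    gacc_a[i] += g * row[i]
            elif rec == 1:
                krow = proj_indeg[p]
                for i in range(proj_post_start[p], proj_post_end[p]):
                    row[i] *= d
                    gacc_n[i] += g * krow[i] * row[i]
            else:
                for i in range(proj_post_start[p], proj_post_end[p]):
                    row[i] *= d
                    gacc_g[i] += g * row[i]

        # --- membrane update and spike detection
        n_spiked = 0
        for i in range(n):
            v = V[i]
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = Vreset[i]
            else:
                nmda_f = 1.0 / (1.0 + np.exp(-0.062 * v) / 3.57)
                I_syn = (gacc_a[i] * (v - VE)
                         + gacc_n[i] * (v - VE) * nmda_f
                         + gacc_g[i] * (v - VI))
                I_T = 0.0
                if gT[i] > 0.0 and v >= Vh[i]:
                    I_T = gT[i] * h[i] * (v - VT[i])
                v_new = v + dt * (-gL[i] * (v - VL[i]) - I_T - I_syn) / C[i]
                if v_new >= Vspike[i]:
                    spiked[n_spiked] = i
                    n_spiked += 1
                    V[i] = Vreset[i]
                    refr[i] = tref_steps[i]
                else:
                    V[i] = v_new
            # burst gate
            if v >= Vh[i]:
                h[i] *= exp_hm[i]
            else:
                h[i] = 1.0 + (h[i] - 1.0) * exp_hp[i]

        # --- propagate spikes to gating accumulators
        for k in range(n_spiked):
            j = spiked[k]
            for mm in range(out_ptr[j], out_ptr[j + 1]):
                p = out_proj[mm]
                tgt = out_target[mm]
                if proj_rec[p] == 1:
                    s[p, tgt] += alpha * (1.0 - s[p, tgt]) / proj_indeg[p, tgt]
                else:
                    s[p, tgt] += 1.0

        # --- bookkeeping: spike counts per subpopulation
        cnt_a = 0
        cnt_b = 0
        for k in range(n_spiked):
            j = spiked[k]
            pop_counts[pop_of[j]] += 1
            if th_a_start <= j < th_a_end:
                cnt_a += 1
            elif th_b_start <= j < th_b_end:
                cnt_b += 1
            if record_bins:
                bins[step // bin_steps, pop_of[j]] += 1

        # --- threshold detection on trailing-window thalamic rates
        if thr_counts > 0.0:
            slot = step % win_steps
            det_sums[0] += cnt_a - ring_a[slot]
            ring_a[slot] = cnt_a
            det_sums[1] += cnt_b - ring_b[slot]
            ring_b[slot] = cnt_b
            a_hit = det_sums[0] >= thr_counts
            b_hit = det_sums[1] >= thr_counts
            if a_hit or b_hit:
                if a_hit and b_hit:
                    # simultaneous crossing: higher rate wins, tie by coin flip
                    if det_sums[0] > det_sums[1]:
                        winner = 1
                    elif det_sums[1] > det_sums[0]:
                        winner = 2
                    else:
                        winner = 1 if tie_coins[t] < 0.5 else 2
                elif a_hit:
                    winner = 1
                else:
                    winner = 2
                return step, winner

        if step % 1000 == 999:
            for i in range(n):
                if not np.isfinite(V[i]):
                    return -2, i

    return -1, 0


def run_segment(
    net: PackedNetwork,
    state: SimState,
    n_steps: int,
    drive: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    seed: int,
    dt: float = DT_MS,
    decision: dict | None = None,
    pop_counts: np.ndarray | None = None,
    bin_ms: float | None = None,
) -> dict:
    """Integrate ``n_steps`` steps; optionally watch for a threshold crossing.

    ``decision`` (when given) holds ``threshold`` (Hz), ``window`` (ms).
    Returns a dict with ``decision_step`` (-1 if none), ``winner``
    ("A"/"B"/None), per-subpop ``pop_counts`` and optional binned counts.
    """
    mu_a, sw_a, mu_g, sw_g = drive
    slices = net.pop_slices
    if decision is not None:
        th_a = slices["Th_A"]
        th_b = slices["Th_B"]
        n_th = th_a.stop - th_a.start
        win_steps = max(1, int(round(decision["window"] / dt)))
        thr_counts = decision["threshold"] * n_th * (decision["window"] / 1000.0)
        det = (th_a.start, th_a.stop, th_b.start, th_b.stop, win_steps, thr_counts)
    else:
        det = (0, 0, 0, 0, 1, -1.0)

    pop_of = np.empty(net.n_neurons, dtype=np.int32)
    for k, lb in enumerate(net.pop_labels):
        pop_of[slices[lb]] = k
    if pop_counts is None:
        pop_counts = np.zeros(len(net.pop_labels), dtype=np.int64)
    if bin_ms is not None:
        bin_steps = max(1, int(round(bin_ms / dt)))
        n_bins = int(np.ceil(n_steps / bin_steps))
        bins = np.zeros((n_bins, len(net.pop_labels)), dtype=np.int64)
    else:
        bin_steps = 1
        bins = np.zeros((0, len(net.pop_labels)), dtype=np.int64)

    g_noise_idx = np.nonzero(sw_g > 0)[0].astype(np.int64)
    win_steps = det[4]
    ring_a = np.zeros(win_steps, dtype=np.int64)
    ring_b = np.zeros(win_steps, dtype=np.int64)
    det_sums = np.zeros(2, dtype=np.int64)
    rng = np.random.default_rng(np.uint32(seed) & 0x7FFFFFFF)
    chunk = 500
    decision_step, winner = -1, 0
    step0 = 0
    while step0 < n_steps:
        m = min(chunk, n_steps - step0)
        noise_a = rng.standard_normal((m, net.n_neurons))
        noise_g = rng.standard_normal((m, g_noise_idx.size))
        tie_coins = rng.random(m)
        decision_step, winner = _run_chunk(
            state.V, state.h, state.refr, state.s, state.Sa, state.Sg,
            net.C, net.gL, net.VL, net.gT, net.VT, net.Vh, net.tauhp, net.tauhm,
            net.Vspike, net.Vreset, net.tref_steps,
            net.proj_g, net.proj_rec, net.proj_post_start, net.proj_post_end,
            net.proj_decay, net.proj_indeg, net.out_ptr, net.out_target, net.out_proj,
            net.receptors.V_E, net.receptors.V_I, net.receptors.alpha,
            mu_a, sw_a, mu_g, sw_g, g_noise_idx,
            net.receptors.tau_AMPA, net.receptors.tau_GABA,
            noise_a, noise_g, tie_coins,
            dt, step0, m,
            *det[:4], win_steps, det[5],
            ring_a, ring_b, det_sums,
            pop_of, pop_counts,
            bins, bin_steps,
        )
        if decision_step != -1:
            break
        step0 += m
    if decision_step == -2:
        raise NumericalDivergenceError(f"non-finite membrane potential at neuron {winner}")
    return {
        "decision_step": int(decision_step),
        "winner": {0: None, 1: "A", 2: "B"}[int(winner)],
        "pop_counts": pop_counts,
        "bins": bins if bin_ms is not None else None,
        "steps_run": n_steps if decision_step < 0 else int(decision_step) + 1,
    }
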