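"""Decision-trial protocol: stimulus onset to thalamic threshold crossing.

A trial integrates the network at baseline for a settle period, then steps
the cortical external rate up (the "stimulus").  The first thalamic
subpopulation whose trailing-window rate reaches the decision threshold
determines the choice; the reaction time is measured from stimulus onset
to that crossing.  If neither channel crosses within the timeout the trial
is recorded as undecided.  Trials are stateless: each re-initializes the
network state from a randomized resting distribution, which matches the
per-trial independence assumed by the downstream diffusion-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net_mod
from .config import TrialProtocol, default_external_drives
from .network import (
    ConnectionSpec, PopulationSpec, WeightConfig, build_connectivity,
    build_populations, connection_table, CHANNEL_REGIONS,
)
from .simulator import (
    DT_MS, ExternalDriveParams, IFBParams, PackedNetwork, ReceptorParams,
    init_state, pack_network, run_segment,
)

#: Fixed column order of the 16 firing-rate features: per-region channel
#: sums (A+B), per-region channel differences (A-B), then the two shared
#: interneuron pools.
RATE_FEATURE_COLUMNS = (
    tuple(f"{r}_sum" for r in CHANNEL_REGIONS)
    + tuple(f"{r}_diff" for r in CHANNEL_REGIONS)
    + ("CxI", "FSI")
)


@dataclass
class TrialResult:
    """Outcome of one decision trial."""

    choice: str | None            # "A", "B" or None
    rt: float                     # ms; NaN when undecided
    mean_rates: dict[str, float]  # Hz per subpopulation over [onset, decision]
    bins: np.ndarray | None = None  # optional binned spike counts (diagnostics)

    @property
    def decided(self) -> bool:
        return self.choice is not None


@dataclass
class BehaviorSummary:
    """Session-level behavioral aggregates (decided trials only)."""

    n_trials: int
    n_decided: int
    p_A: float
    rt_mean: float
    rt_mean_A: float
    rt_mean_B: float
    mean_rates: dict[str, float]

    @classmethod
    def from_trials(cls, trials: list[TrialResult]) -> "BehaviorSummary":
        decided = [t for t in trials if t.decided]
        n_a = sum(t.choice == "A" for t in decided)
        rts = np.array([t.rt for t in decided])
        rts_a = np.array([t.rt for t in decided if t.choice == "A"])
        rts_b = np.array([t.rt for t in decided if t.choice == "B"])
        if decided:
            labels = decided[0].mean_rates.keys()
            mean_rates = {lb: float(np.mean([t.mean_rates[lb] for t in decided]))
                          for lb in labels}
        else:
            mean_rates = {}
        return cls(
            n_trials=len(trials),
            n_decided=len(decided),
            p_A=n_a / len(decided) if decided else np.nan,
            rt_mean=float(rts.mean()) if rts.size else np.nan,
            rt_mean_A=float(rts_a.mean()) if rts_a.size else np.nan,
            rt_mean_B=float(rts_b.mean()) if rts_b.size else np.nan,
            mean_rates=mean_rates,
        )


class NoDecidedTrialsError(RuntimeError):
    """A network produced no decided trials; it must be excluded."""


class DecisionCircuit:
    """A concrete CBGT network instance ready to run decision trials.

    Parameters
    ----------
    weights
        The 14-dimensional variable-weight configuration; defaults to the
        control conductances.
    connectivity_seed
        Seed of the Bernoulli connectivity draw (one fixed anatomical
        realization per circuit instance).
    """

    def __init__(
        self,
        weights: WeightConfig | None = None,
        sizes: dict[str, int] | None = None,
        table: list[ConnectionSpec] | None = None,
        neuron_params: dict[str, IFBParams] | None = None,
        receptors: ReceptorParams | None = None,
        drives: dict[str, list[ExternalDriveParams]] | None = None,
        connectivity_seed: int = 0,
        dt: float = DT_MS,
    ):
        self.table = connection_table() if table is None else table
        self.weights = WeightConfig.control(self.table) if weights is None else weights
        self.populations = build_populations(sizes)
        self.projections = build_connectivity(
            self.populations, self.table, self.weights, seed=connectivity_seed)
        self.packed = pack_network(self.populations, self.projections,
                                   neuron_params, receptors, dt=dt)
        self.drives = default_external_drives() if drives is None else drives
        self.dt = dt

    # -- drive arrays for the two phases of a trial
    def _drive(self, cx_rate: float):
        return self.packed.drive_arrays(self.drives, cx_rate=cx_rate)

    def run_trial(self, protocol: TrialProtocol | None = None, seed: int = 0,
                  bin_ms: float | None = None) -> TrialResult:
        """Run a single decision trial (settle, stimulate, detect crossing)."""
        protocol = TrialProtocol() if protocol is None else protocol
        rng = np.random.default_rng(seed)
        base = self._drive(protocol.cx_baseline_rate)
        stim = self._drive(protocol.cx_stimulus_rate)
        state = init_state(self.packed, base[0], base[2], rng)
        seeds = rng.integers(0, 2**31 - 1, size=2)
        n_settle = int(round(protocol.settle_time / self.dt))
        run_segment(self.packed, state, n_settle, base, int(seeds[0]), dt=self.dt)
        n_timeout = int(round(protocol.timeout / self.dt))
        res = run_segment(
            self.packed, state, n_timeout, stim, int(seeds[1]), dt=self.dt,
            decision={"threshold": protocol.decision_threshold,
                      "window": protocol.rate_window},
            bin_ms=bin_ms,
        )
        elapsed_ms = res["steps_run"] * self.dt
        sizes = {p.label: p.n_neurons for p in self.populations}
        mean_rates = {
            lb: float(c) / (sizes[lb] * elapsed_ms / 1000.0)
            for lb, c in zip(self.packed.pop_labels, res["pop_counts"])
        }
        if res["decision_step"] >= 0:
            rt = (res["decision_step"] + 1) * self.dt
            return TrialResult(choice=res["winner"], rt=rt, mean_rates=mean_rates,
                               bins=res["bins"])
        return TrialResult(choice=None, rt=float("nan"), mean_rates=mean_rates,
                           bins=res["bins"])

    def run_session(
        self,
        protocol: TrialProtocol | None = None,
        n_trials: int = 300,
        seed: int = 0,
    ) -> tuple[BehaviorSummary, list[TrialResult]]:
        """Run independent trials with per-trial derived seeds."""
        if n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        protocol = TrialProtocol() if protocol is None else protocol
        ss = np.random.SeedSequence(seed)
        trial_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n_trials)]
        trials = [self.run_trial(protocol, seed=s) for s in trial_seeds]
        return BehaviorSummary.from_trials(trials), trials

    def baseline_rates(self, duration: float = 1000.0, seed: int = 0,
                       protocol: TrialProtocol | None = None) -> dict[str, float]:
        """Population mean rates at rest (no stimulus), Hz per neuron."""
        protocol = TrialProtocol() if protocol is None else protocol
        rng = np.random.default_rng(seed)
        base = self._drive(protocol.cx_baseline_rate)
        state = init_state(self.packed, base[0], base[2], rng)
        n_settle = int(round(protocol.settle_time / self.dt))
        run_segment(self.packed, state, n_settle, base,
                    int(rng.integers(2**31 - 1)), dt=self.dt)
        n_steps = int(round(duration / self.dt))
        res = run_segment(self.packed, state, n_steps, base,
                          int(rng.integers(2**31 - 1)), dt=self.dt)
        sizes = {p.label: p.n_neurons for p in self.populations}
        return {lb: float(c) / (sizes[lb] * duration / 1000.0)
                for lb, c in zip(self.packed.pop_labels, res["pop_counts"])}


def region_rates(mean_rates: dict[str, float]) -> dict[str, float]:
    """Per-region rates averaged over channels (shared pools as-is)."""
    out = {}
    for region in CHANNEL_REGIONS:
        out[region] = 0.5 * (mean_rates[f"{region}_A"] + mean_rates[f"{region}_B"])
    out["CxI"] = mean_rates["CxI"]
    out["FSI"] = mean_rates["FSI"]
    return out


def compute_rate_features(trials: list[TrialResult]) -> np.ndarray:
    """16-vector of trial-averaged rate features for one network.

    Rates are averaged over decided trials, then expressed as the seven
    channel sums (A+B), the seven channel differences (A-B), and the two
    shared pools, in the order of ``RATE_FEATURE_COLUMNS``.
    """
    decided = [t for t in trials if t.decided]
    if not decided:
        raise NoDecidedTrialsError("no decided trials; network must be excluded")
    labels = decided[0].mean_rates.keys()
    avg = {lb: float(np.mean([t.mean_rates[lb] for t in decided])) for lb in labels}
    feats = []
    for region in CHANNEL_REGIONS:
        feats.append(avg[f"{region}_A"] + avg[f"{region}_B"])
    for region in CHANNEL_REGIONS:
        feats.append(avg[f"{region}_A"] - avg[f"{region}_B"])
    feats.append(avg["CxI"])
    feats.append(avg["FSI"])
    return np.array(feats)


def trials_frame(trials: list[TrialResult]) -> pd.DataFrame:
    """Per-trial behavior table (trial id, choice, rt, per-subpop rates)."""
    rows = []
    for i, t in enumerate(trials):
        row = {"trial": i, "choice": t.choice if t.decided else "none",
               "rt_ms": t.rt}
        row.update({f"rate_{k}": v for k, v in t.mean_rates.items()})
        rows.append(row)
    return pd.DataFrame(rows)
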