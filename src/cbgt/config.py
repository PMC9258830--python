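"""Protocol constants, external-input table and experiment configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulator import ExternalDriveParams, IFBParams, ReceptorParams, DEFAULT_NEURON_PARAMS


@dataclass(frozen=True)
class TrialProtocol:
    """Constants of one decision trial.

    The stimulus steps the cortical external input rate from the baseline
    2.2 Hz to 2.5 Hz; a decision is registered when either channel's
    thalamic population rate first reaches the 30 Hz threshold, and the
    trial times out undecided after 800 ms.  After a decision the stimulus
    would continue for 300 ms at 75% strength; trials here are stateless
    (state is re-initialized per trial), so that tail carries no
    information and is not integrated.
    """

    cx_baseline_rate: float = 2.2      # Hz
    cx_stimulus_rate: float = 2.5      # Hz
    decision_threshold: float = 30.0   # Hz
    timeout: float = 800.0             # ms
    post_decision_hold: float = 300.0  # ms
    post_decision_scale: float = 0.75
    rate_window: float = 20.0          # ms, trailing window of the rate estimator
    settle_time: float = 200.0         # ms of baseline integration before onset

    def __post_init__(self):
        if self.cx_stimulus_rate <= self.cx_baseline_rate:
            raise ValueError("stimulus rate must exceed baseline rate")
        if self.decision_threshold <= 0:
            raise ValueError("decision threshold must be positive")


def default_external_drives() -> dict[str, list[ExternalDriveParams]]:
    """Background input per population (rate Hz, efficacy nS, #connections).

    These set each population's operating point; they were calibrated so
    that the control network's baseline and decision-epoch firing rates
    fall inside the experimentally reported ranges and the behavior of the
    control network matches its reference statistics.  The cortical AMPA
    rate is the protocol's stimulus knob (2.2 Hz baseline, 2.5 Hz during
    the stimulus).
    """
    return {
        "Cx": [
            ExternalDriveParams(rate=2.2, efficacy=3.0, n_connections=6570, receptor="AMPA"),
            ExternalDriveParams(rate=4.0, efficacy=2.2, n_connections=3520, receptor="GABA"),
        ],
        "CxI": [ExternalDriveParams(rate=3.6863, efficacy=4.4, n_connections=500, receptor="AMPA")],
        "dSPN": [ExternalDriveParams(rate=2.2, efficacy=2.0, n_connections=1281, receptor="AMPA")],
        "iSPN": [ExternalDriveParams(rate=2.2, efficacy=2.0, n_connections=1281, receptor="AMPA")],
        "FSI": [ExternalDriveParams(rate=2.2231, efficacy=4.8, n_connections=600, receptor="AMPA")],
        "GPe": [ExternalDriveParams(rate=1.7973, efficacy=8.0, n_connections=1125, receptor="AMPA")],
        "GPi": [ExternalDriveParams(rate=1.4760, efficacy=8.0, n_connections=700, receptor="AMPA")],
        "STN": [ExternalDriveParams(rate=2.1121, efficacy=6.4, n_connections=450, receptor="AMPA")],
        "Th": [ExternalDriveParams(rate=1.7, efficacy=5.2, n_connections=550, receptor="AMPA")],
    }


#: Experimentally reported firing-rate ranges (Hz): baseline and full
#: (decision-epoch) windows per region.  Cx has no reported baseline range.
DEFAULT_RATE_RANGES: dict[str, dict[str, tuple[float, float] | None]] = {
    "dSPN": {"baseline": (0.0, 5.0), "full": (0.0, 35.0)},
    "iSPN": {"baseline": (0.0, 5.0), "full": (0.0, 35.0)},
    "GPe": {"baseline": (40.0, 90.0), "full": (40.0, 150.0)},
    "GPi": {"baseline": (40.0, 90.0), "full": (40.0, 150.0)},
    "STN": {"baseline": (10.0, 35.0), "full": (10.0, 55.0)},
    "Th": {"baseline": (5.0, 20.0), "full": (5.0, 85.0)},
    "Cx": {"baseline": None, "full": (0.0, 100.0)},
    "FSI": {"baseline": (5.0, 40.0), "full": (5.0, 70.0)},
}


@dataclass
class RateRangeSpec:
    """Admissible firing-rate windows used by the bound-calibration loop."""

    ranges: dict[str, dict[str, tuple[float, float] | None]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATE_RANGES.items()})

    def __post_init__(self):
        for pop, spec in self.ranges.items():
            base, full = spec.get("baseline"), spec.get("full")
            if base is not None and full is not None:
                if not (full[0] <= base[0] and base[1] <= full[1]):
                    raise ValueError(f"{pop}: baseline range must lie within full range")

    def full(self, pop: str) -> tuple[float, float] | None:
        return self.ranges.get(pop, {}).get("full")

    def baseline(self, pop: str) -> tuple[float, float] | None:
        return self.ranges.get(pop, {}).get("baseline")


@dataclass
class ExperimentConfig:
    """Top-level configuration of a sampling experiment."""

    n_networks: int = 300
    n_trials: int = 300
    master_seed: int = 12345
    output_dir: str = "experiment_out"
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    ddm_n_starts: int = 8
    cca_max_components: dict[str, int] = field(
        default_factory=lambda: {"WR": 14, "RP": 4})
    cv_folds: int = 4
    kmeans_k_grid: tuple[int, ...] = tuple(range(2, 11))
    sensitivity_runs: int = 100_000
    sensitivity_step: float = 0.1

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["protocol"] = asdict(self.protocol)
        data["kmeans_k_grid"] = list(self.kmeans_k_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "protocol" in data and isinstance(data["protocol"], dict):
            data["protocol"] = TrialProtocol(**data["protocol"])
        if "kmeans_k_grid" in data:
            data["kmeans_k_grid"] = tuple(data["kmeans_k_grid"])
        return cls(**data)
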