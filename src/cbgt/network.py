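"""Populations and probabilistic channel-structured connectivity of the CBGT circuit.

The circuit contains nine regions.  Seven of them (Cx, dSPN, iSPN, GPi, GPe,
STN, Th) are duplicated into two *action channels* A and B; the inhibitory
interneuron pools (CxI, FSI) are shared between channels.  Neurons are
connected population-to-population with fixed probabilities and synaptic
conductances (nS).  Fourteen feed-forward projections are *variable*: their
conductances are the coordinates explored by the Latin hypercube sweep.

Most projections are *focal* (restricted to one channel); three are
*diffuse* and also cross channels: GPe->GPe, STN->GPi and Th->Cx.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("CxI", "Cx", "dSPN", "iSPN", "FSI", "GPi", "GPe", "STN", "Th")
SHARED_REGIONS = ("CxI", "FSI")
CHANNEL_REGIONS = ("Cx", "dSPN", "iSPN", "GPi", "GPe", "STN", "Th")
CHANNELS = ("A", "B")

#: Default number of neurons per population (shared pools are totals,
#: channel pools are per channel).
DEFAULT_SIZES = {
    "CxI": 186,
    "Cx": 204,
    "dSPN": 75,
    "iSPN": 75,
    "FSI": 75,
    "GPi": 75,
    "GPe": 750,
    "STN": 750,
    "Th": 75,
}

RECEPTORS = ("AMPA", "NMDA", "GABA")
#: Projections that also cross action channels.
DIFFUSE_PAIRS = {("GPe", "GPe"), ("STN", "GPi"), ("Th", "Cx")}


class ConfigurationError(ValueError):
    """Raised for invalid network configuration input."""


class BoundsError(ValueError):
    """Raised when a variable conductance falls outside its allowed range."""


@dataclass(frozen=True)
class PopulationSpec:
    """One concrete subpopulation (region x channel)."""

    name: str          # region name, e.g. "GPe"
    channel: str       # "A", "B" or "shared"
    n_neurons: int

    @property
    def label(self) -> str:
        if self.channel == "shared":
            return self.name
        return f"{self.name}_{self.channel}"


@dataclass(frozen=True)
class ConnectionSpec:
    """One row of the connection table (a projection for one receptor)."""

    pre: str
    post: str
    receptor: str
    probability: float
    g_control: float
    g_lower: float | None = None
    g_upper: float | None = None
    topology: str = "focal"     # "focal" or "diffuse"
    variable: bool = False
    group: str = ""             # variable-weight name shared by yoked rows
    reference: bool = False     # True for the row whose bounds define the group

    def __post_init__(self):
        if self.pre not in REGIONS or self.post not in REGIONS:
            raise ConfigurationError(f"unknown population in {self.pre}->{self.post}")
        if self.receptor not in RECEPTORS:
            raise ConfigurationError(f"unknown receptor {self.receptor!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("connection probability must lie in [0, 1]")
        if self.g_control < 0:
            raise ConfigurationError("conductance must be non-negative")
        if self.variable:
            if self.g_lower is None or self.g_upper is None:
                raise ConfigurationError("variable rows need bounds")
            if not (self.g_lower <= self.g_control <= self.g_upper):
                raise BoundsError(
                    f"{self.pre}->{self.post} {self.receptor}: control conductance "
                    f"{self.g_control} outside [{self.g_lower}, {self.g_upper}]"
                )

    @property
    def name(self) -> str:
        return f"{self.pre}-{self.post}:{self.receptor}"


def _row(pre, post, rec, p, g, lo=None, hi=None, ref=False):
    variable = lo is not None
    topology = "diffuse" if (pre, post) in DIFFUSE_PAIRS else "focal"
    return ConnectionSpec(
        pre=pre, post=post, receptor=rec, probability=p, g_control=g,
        g_lower=lo, g_upper=hi, topology=topology, variable=variable,
        group=f"{pre}-{post}" if variable else "", reference=ref,
    )


def connection_table() -> list[ConnectionSpec]:
    """Default CBGT connection table.

    The fourteen variable projections are identified per (pre, post) pair;
    where a pair has both an AMPA and an NMDA row (Cx->dSPN, Cx->iSPN,
    Cx->Th) one sampled value scales both rows proportionally, with the
    row marked ``reference`` carrying the absolute bounds.
    """
    return [
        _row("Cx", "Cx", "AMPA", 0.43, 0.0127),
        _row("Cx", "Cx", "NMDA", 0.43, 0.15),
        _row("Cx", "CxI", "AMPA", 0.2417, 0.113),
        _row("Cx", "CxI", "NMDA", 0.2417, 0.525),
        _row("CxI", "Cx", "GABA", 1.0, 1.75),
        _row("CxI", "CxI", "GABA", 1.0, 3.5833),
        _row("Cx", "dSPN", "NMDA", 1.0, 0.027, 0.012, 0.033, ref=True),
        _row("Cx", "iSPN", "NMDA", 1.0, 0.027, 0.0195, 0.0885, ref=True),
        _row("Cx", "dSPN", "AMPA", 1.0, 0.018, 0.008, 0.022),
        _row("Cx", "iSPN", "AMPA", 1.0, 0.018, 0.008, 0.059),
        _row("Cx", "Th", "NMDA", 1.0, 0.035, 0.008, 0.0548, ref=True),
        _row("Cx", "Th", "AMPA", 1.0, 0.035, 0.008, 0.0548),
        _row("Cx", "FSI", "AMPA", 1.0, 0.198, 0.1905, 0.63, ref=True),
        _row("dSPN", "dSPN", "GABA", 0.45, 0.28),
        _row("dSPN", "iSPN", "GABA", 0.45, 0.28),
        _row("dSPN", "GPi", "GABA", 1.0, 2.09, 0.418, 2.413, ref=True),
        _row("iSPN", "dSPN", "GABA", 0.5, 0.28),
        _row("iSPN", "iSPN", "GABA", 0.45, 0.28),
        _row("iSPN", "GPe", "GABA", 1.0, 4.07, 2.47, 4.46, ref=True),
        _row("GPe", "STN", "GABA", 0.067, 0.35, 0.33, 0.39, ref=True),
        _row("GPe", "GPe", "GABA", 0.067, 1.75),
        _row("GPe", "GPi", "GABA", 1.0, 0.06, 0.05733, 0.067, ref=True),
        _row("GPi", "Th", "GABA", 1.0, 0.3315, 0.32017, 0.357, ref=True),
        _row("FSI", "dSPN", "GABA", 1.0, 1.7776),
        _row("FSI", "iSPN", "GABA", 1.0, 1.66987),
        _row("FSI", "FSI", "GABA", 1.0, 3.2583),
        _row("STN", "GPe", "AMPA", 0.1617, 0.07, 0.05, 0.1, ref=True),
        _row("STN", "GPe", "NMDA", 0.1617, 1.51),
        _row("STN", "GPi", "NMDA", 1.0, 0.038, 0.036, 0.03833, ref=True),
        _row("Th", "Cx", "NMDA", 0.83, 0.03, 0.021, 0.035, ref=True),
        _row("Th", "CxI", "NMDA", 0.83, 0.015),
        _row("Th", "dSPN", "AMPA", 1.0, 0.3825, 0.0015, 0.3915, ref=True),
        _row("Th", "iSPN", "AMPA", 1.0, 0.3825, 0.3525, 0.3975, ref=True),
        _row("Th", "FSI", "AMPA", 0.83, 0.1),
    ]


def variable_groups(table: list[ConnectionSpec] | None = None) -> dict[str, tuple[float, float, float]]:
    """Map each variable-weight name to (control, lower, upper) of its reference row."""
    table = connection_table() if table is None else table
    out: dict[str, tuple[float, float, float]] = {}
    for row in table:
        if row.variable and row.reference:
            out[row.group] = (row.g_control, row.g_lower, row.g_upper)
    return out


VARIABLE_WEIGHT_NAMES = tuple(variable_groups())


@dataclass
class WeightConfig:
    """The 14-dimensional variable-weight vector (conductances in nS).

    A single value per (pre, post) projection; the same conductance is
    applied to the A- and B-channel copies, and yoked receptor rows are
    scaled proportionally to the reference row.
    """

    values: dict[str, float] = field(default_factory=dict)

    @classmethod
    def control(cls, table: list[ConnectionSpec] | None = None) -> "WeightConfig":
        return cls({name: ctl for name, (ctl, _, _) in variable_groups(table).items()})

    @classmethod
    def from_vector(cls, vector: np.ndarray, names: tuple[str, ...] = None) -> "WeightConfig":
        names = VARIABLE_WEIGHT_NAMES if names is None else names
        if len(vector) != len(names):
            raise ConfigurationError(f"expected {len(names)} weights, got {len(vector)}")
        return cls(dict(zip(names, map(float, vector))))

    def to_vector(self, names: tuple[str, ...] = None) -> np.ndarray:
        names = VARIABLE_WEIGHT_NAMES if names is None else names
        return np.array([self.values[n] for n in names], dtype=float)

    def validate(self, table: list[ConnectionSpec] | None = None) -> None:
        groups = variable_groups(table)
        for name, (_, lo, hi) in groups.items():
            if name not in self.values:
                raise ConfigurationError(f"missing variable weight {name!r}")
            v = self.values[name]
            if not (lo <= v <= hi):
                raise BoundsError(f"{name} = {v} outside [{lo}, {hi}]")

    def row_conductance(self, row: ConnectionSpec, table: list[ConnectionSpec] | None = None) -> float:
        """Concrete conductance for a table row under this weight configuration."""
        if not row.variable:
            return row.g_control
        groups = variable_groups(table)
        if row.group not in groups:
            # subset tables may omit the group's reference row; the yoking
            # ratio is defined by the full default table
            groups = variable_groups()
        ref_control = groups[row.group][0]
        return self.values[row.group] * row.g_control / ref_control


# ---------------------------------------------------------------------------
# population instantiation

def build_populations(sizes: dict[str, int] | None = None) -> list[PopulationSpec]:
    """Expand the nine regions into 16 concrete subpopulations.

    Order is fixed: the shared pools first, then the seven channel regions
    for channel A, then for channel B.
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    for name, n in sizes.items():
        if name not in REGIONS:
            raise ConfigurationError(f"unknown population {name!r}")
        if int(n) <= 0:
            raise ConfigurationError(f"population {name!r} must have a positive size")
    pops = [PopulationSpec(r, "shared", int(sizes[r])) for r in SHARED_REGIONS]
    for ch in CHANNELS:
        pops.extend(PopulationSpec(r, ch, int(sizes[r])) for r in CHANNEL_REGIONS)
    return pops


def population_slices(populations: list[PopulationSpec]) -> dict[str, slice]:
    """Global neuron-index slice for each subpopulation label."""
    out, start = {}, 0
    for p in populations:
        out[p.label] = slice(start, start + p.n_neurons)
        start += p.n_neurons
    return out


def total_neurons(populations: list[PopulationSpec]) -> int:
    return sum(p.n_neurons for p in populations)


# ---------------------------------------------------------------------------
# connectivity instantiation

@dataclass
class Projection:
    """A realized synapse bundle: all synapses of one table row for one
    (pre-channel, post-channel) branch, sharing a receptor and conductance.

    ``indptr``/``targets`` form a CSR structure over the presynaptic slice:
    the targets of pre neuron ``pre_slice.start + i`` are
    ``targets[indptr[i]:indptr[i + 1]]`` (global indices).
    """

    row: ConnectionSpec
    pre_label: str
    post_label: str
    g: float
    pre_slice: slice
    post_slice: slice
    indptr: np.ndarray
    targets: np.ndarray

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    def in_degrees(self) -> np.ndarray:
        """Number of afferents each postsynaptic neuron receives from this bundle."""
        n_post = self.post_slice.stop - self.post_slice.start
        return np.bincount(self.targets - self.post_slice.start, minlength=n_post)


def _branches(row: ConnectionSpec) -> list[tuple[str, str]]:
    """(pre_channel, post_channel) branches instantiated for a table row."""
    pre_shared = row.pre in SHARED_REGIONS
    post_shared = row.post in SHARED_REGIONS
    if pre_shared and post_shared:
        return [("shared", "shared")]
    if pre_shared:
        return [("shared", ch) for ch in CHANNELS]
    if post_shared:
        return [(ch, "shared") for ch in CHANNELS]
    if row.topology == "diffuse":
        return [(a, b) for a in CHANNELS for b in CHANNELS]
    return [(ch, ch) for ch in CHANNELS]


def build_connectivity(
    populations: list[PopulationSpec],
    table: list[ConnectionSpec],
    weights: WeightConfig | None = None,
    seed: int = 0,
    channel_symmetric: bool = True,
) -> list[Projection]:
    """Instantiate concrete synapses from the connection table.

    Each candidate (pre, post) ordered pair of a row's branch is linked by
    an independent Bernoulli draw with the row's probability;
    self-connections are excluded.  The draw sequence is fully determined
    by ``seed``, so identical seeds give identical synapse lists.

    With ``channel_symmetric`` (the default) the two action channels are
    anatomically mirrored: one Bernoulli pattern is drawn per row and
    reused for the matching branch of the other channel, so the realized
    network is exactly isomorphic under the A/B relabeling permutation
    and quenched anatomical asymmetry cannot bias choice.  Set it False
    for fully independent draws per branch.
    """
    weights = WeightConfig.control(table) if weights is None else weights
    weights.validate(table)
    slices = population_slices(populations)
    rng = np.random.default_rng(seed)
    projections: list[Projection] = []
    for row in table:
        g = weights.row_conductance(row, table)
        branch_masks: dict[tuple[str, str], np.ndarray] = {}
        for pre_ch, post_ch in _branches(row):
            pre_label = row.pre if pre_ch == "shared" else f"{row.pre}_{pre_ch}"
            post_label = row.post if post_ch == "shared" else f"{row.post}_{post_ch}"
            s_pre, s_post = slices[pre_label], slices[post_label]
            n_pre = s_pre.stop - s_pre.start
            n_post = s_post.stop - s_post.start
            mirror = _mirror_branch(pre_ch, post_ch)
            if channel_symmetric and mirror in branch_masks:
                mask = branch_masks[mirror]
            elif row.probability >= 1.0:
                mask = np.ones((n_pre, n_post), dtype=bool)
            elif row.probability <= 0.0:
                mask = np.zeros((n_pre, n_post), dtype=bool)
            else:
                mask = rng.random((n_pre, n_post)) < row.probability
            branch_masks[(pre_ch, post_ch)] = mask
            if s_pre == s_post:
                mask = mask.copy()
                np.fill_diagonal(mask, False)
            counts = mask.sum(axis=1)
            indptr = np.zeros(n_pre + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            targets = (np.nonzero(mask)[1] + s_post.start).astype(np.int32)
            projections.append(
                Projection(row, pre_label, post_label, g, s_pre, s_post, indptr, targets)
            )
    return projections


def _mirror_branch(pre_ch: str, post_ch: str) -> tuple[str, str]:
    swap = {"A": "B", "B": "A", "shared": "shared"}
    return swap[pre_ch], swap[post_ch]


def synapse_frame(projections: list[Projection]) -> pd.DataFrame:
    """All synapses as a table (pre_neuron, post_neuron, receptor, g).

    Intended for small networks and tests; the simulator consumes the
    projection CSR structures directly.
    """
    frames = []
    for p in projections:
        n_pre = p.pre_slice.stop - p.pre_slice.start
        pre = np.repeat(np.arange(n_pre) + p.pre_slice.start, np.diff(p.indptr))
        frames.append(pd.DataFrame({
            "pre_neuron": pre.astype(np.int64),
            "post_neuron": p.targets.astype(np.int64),
            "receptor": p.row.receptor,
            "g": p.g,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# connection-table serialization

_TABLE_COLUMNS = ["pre", "post", "receptor", "probability", "g_control",
                  "g_lower", "g_upper", "topology", "variable", "group", "reference"]


def write_connection_table(table: list[ConnectionSpec], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in table])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_connection_table(path) -> list[ConnectionSpec]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"connection table missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        lo, hi = rec["g_lower"], rec["g_upper"]
        rows.append(ConnectionSpec(
            pre=rec["pre"], post=rec["post"], receptor=rec["receptor"],
            probability=float(rec["probability"]), g_control=float(rec["g_control"]),
            g_lower=None if pd.isna(lo) else float(lo),
            g_upper=None if pd.isna(hi) else float(hi),
            topology=rec["topology"], variable=bool(rec["variable"]),
            group="" if pd.isna(rec["group"]) else str(rec["group"]),
            reference=bool(rec["reference"]),
        ))
    return rows
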