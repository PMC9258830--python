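"""Latin hypercube sampling over the variable conductances and bound calibration."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .network import VARIABLE_WEIGHT_NAMES, variable_groups


@dataclass
class LHSDesign:
    """An n_samples x n_dims Latin hypercube design in absolute units."""

    matrix: np.ndarray
    bounds: np.ndarray          # (n_dims, 2)
    names: tuple[str, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.names))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def default_bounds() -> tuple[np.ndarray, tuple[str, ...]]:
    """(lower, upper) per variable weight from the connection table."""
    groups = variable_groups()
    names = tuple(groups)
    b = np.array([[groups[n][1], groups[n][2]] for n in names])
    return b, names


def latin_hypercube(
    bounds: np.ndarray | None = None,
    n_samples: int = 300,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> LHSDesign:
    """Classic per-dimension-permutation Latin hypercube sample.

    Each dimension's range is partitioned into ``n_samples`` equal bins;
    bins are selected without replacement (each exactly once) and the
    sample is drawn uniformly within its bin, independently per dimension.
    """
    if bounds is None:
        bounds, names = default_bounds()
    bounds = np.asarray(bounds, dtype=float)
    if names is None:
        names = tuple(f"w{i}" for i in range(bounds.shape[0]))
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo >= hi):
        bad = [names[i] for i in np.nonzero(lo >= hi)[0]]
        raise ValueError(f"degenerate bounds (lower >= upper) for {bad}")
    rng = np.random.default_rng(seed)
    n_dims = bounds.shape[0]
    u = np.empty((n_samples, n_dims))
    for d in range(n_dims):
        perm = rng.permutation(n_samples)
        u[:, d] = (perm + rng.random(n_samples)) / n_samples
    matrix = lo + u * (hi - lo)
    return LHSDesign(matrix=matrix, bounds=bounds, names=names, seed=seed)


class CalibrationError(RuntimeError):
    """Bound calibration failed to converge; carries the last offenders."""

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = offenders or []


def calibrate_bounds(
    initial_bounds: np.ndarray,
    control: np.ndarray,
    rate_evaluator: Callable[[np.ndarray], dict[str, float]],
    rate_ranges: dict[str, tuple[float, float]],
    batch_size: int = 30,
    seed: int = 0,
    shrink: float = 0.8,
    max_iter: int = 20,
    names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Shrink sampling bounds until a whole LHS batch keeps rates in range.

    ``rate_evaluator`` maps a weight vector to pre-decision population
    rates (Hz).  At each iteration an LHS batch is drawn and evaluated;
    for every population whose batch-mean rate leaves its admissible
    range, the weight most associated with that rate (largest
    standardized regression slope over the batch) has its interval
    shrunk toward the control value by ``shrink``.  The control point
    always remains inside the returned bounds.
    """
    bounds = np.asarray(initial_bounds, dtype=float).copy()
    control = np.asarray(control, dtype=float)
    if np.any(control < bounds[:, 0]) or np.any(control > bounds[:, 1]):
        raise ValueError("initial bounds must contain the control point")
    if not 0.0 < shrink <= 1.0:
        raise ValueError("shrink factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    pops = list(rate_ranges)
    offenders: list[str] = []
    for iteration in range(max_iter):
        design = latin_hypercube(bounds, batch_size,
                                 seed=int(rng.integers(2**31 - 1)), names=names)
        rates = np.array([[rate_evaluator(w)[p] for p in pops]
                          for w in design.matrix])
        mean_rates = rates.mean(axis=0)
        offenders = [
            p for j, p in enumerate(pops)
            if not (rate_ranges[p][0] <= mean_rates[j] <= rate_ranges[p][1])
        ]
        if not offenders:
            return bounds
        W = design.matrix
        Wz = (W - W.mean(0)) / np.where(W.std(0) > 0, W.std(0), 1.0)
        for p in offenders:
            j = pops.index(p)
            r = rates[:, j]
            rz = (r - r.mean()) / (r.std() if r.std() > 0 else 1.0)
            slopes = np.abs(Wz.T @ rz) / batch_size
            d = int(np.argmax(slopes))
            if shrink >= 1.0:
                continue  # no shrinking possible; will hit the cap
            lo, hi = bounds[d]
            c = control[d]
            bounds[d, 0] = c - shrink * (c - lo)
            bounds[d, 1] = c + shrink * (hi - c)
    raise CalibrationError(
        f"bound calibration did not converge in {max_iter} iterations; "
        f"last offending populations: {offenders}", offenders)
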