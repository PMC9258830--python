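"""Drift-diffusion model: simulation and first-passage-time likelihood fitting.

Evidence ``theta`` evolves as ``d theta = nu d tau + sigma dW`` between the
absorbing boundaries 0 and ``a``, starting from ``z * a`` after the onset
(non-decision) time ``t``.  The upper boundary codes choice A, the lower
boundary choice B.  The diffusion SD ``sigma`` is fixed at 1, which pins
the scale of (a, nu).

Fitting maximizes the Wiener first-passage-time likelihood over the
quadruple (a, nu, t, z) from multiple jittered starts; an optional
random-walk Metropolis pass around the optimum supplies a posterior
summary and the deviance information criterion (DIC).  Internal time unit
is seconds; millisecond data should be divided by 1000 before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize


@dataclass(frozen=True)
class DDMParams:
    """Quadruple (a, nu, t, z) with fixed diffusion SD."""

    a: float            # boundary separation (> 0)
    nu: float           # drift rate, evidence units per second
    t: float            # onset (non-decision) time, seconds (>= 0)
    z: float            # starting bias factor in (0, 1); start point is z*a
    sigma: float = 1.0  # diffusion SD, fixed

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if not 0.0 < self.z < 1.0:
            raise ValueError("bias factor z must lie strictly in (0, 1)")
        if self.t < 0:
            raise ValueError("onset time t must be non-negative")
        if self.sigma != 1.0:
            raise ValueError("diffusion SD is fixed at 1")

    def to_array(self) -> np.ndarray:
        return np.array([self.a, self.nu, self.t, self.z])


@dataclass
class BehaviorSample:
    """Paired reaction times (seconds) and boundary hits (upper=A)."""

    rt: np.ndarray
    upper: np.ndarray          # bool; True = upper boundary (choice A)
    n_censored: int = 0        # trials censored / undecided (already removed)

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.upper = np.asarray(self.upper, dtype=bool)
        if self.rt.shape != self.upper.shape:
            raise ValueError("rt and boundary arrays must be the same length")

    def __len__(self):
        return self.rt.size

    def mirrored(self) -> "BehaviorSample":
        """Swap boundary labels (A <-> B)."""
        return BehaviorSample(self.rt.copy(), ~self.upper, self.n_censored)


# ---------------------------------------------------------------------------
# Wiener first-passage density (dual small-time / large-time series)

@njit(cache=True)
def _wfpt_lower_logpdf(t_dec, v, a, w, err):
    """Log density of first passage through the LOWER boundary at decision
    time ``t_dec`` (> 0), for unit diffusion SD.  Truncation of either
    series is chosen so the absolute error is below ``err``."""
    if t_dec <= 0.0:
        return -np.inf
    tt = t_dec / (a * a)
    # number of terms needed (Navarro-Fuss switching rule)
    if np.pi * tt * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err) / (np.pi * np.pi * tt))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(tt)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * np.sqrt(2.0 * np.pi * tt) * err))
        ks = max(ks, np.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(np.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + ((K - 1) % 2)
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * np.exp(-wk * wk / (2.0 * tt))
        p /= np.sqrt(2.0 * np.pi * tt * tt * tt)
    else:        # large-time expansion
        K = int(np.ceil(kl))
        for k in range(1, K + 1):
            p += k * np.exp(-k * k * np.pi * np.pi * tt / 2.0) * np.sin(k * np.pi * w)
        p *= np.pi
    if p <= 0.0:
        return -np.inf
    return np.log(p) - v * a * w - v * v * t_dec / 2.0 - 2.0 * np.log(a)


@njit(cache=True)
def _loglik(rt, upper, a, v, t0, w, err):
    total = 0.0
    for i in range(rt.size):
        td = rt[i] - t0
        if td <= 0.0:
            return -np.inf
        if upper[i]:
            lp = _wfpt_lower_logpdf(td, -v, a, 1.0 - w, err)
        else:
            lp = _wfpt_lower_logpdf(td, v, a, w, err)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def fpt_log_density(rt, boundary, params: DDMParams, err: float = 1e-10):
    """Log first-passage density at reaction time ``rt`` (seconds).

    ``boundary`` is "upper"/"A" or "lower"/"B" (or a boolean, True=upper).
    Returns -inf for rt <= t (zero density before the onset time).
    """
    rts = np.atleast_1d(np.asarray(rt, dtype=float))
    if isinstance(boundary, str):
        up = boundary.lower() in ("upper", "a")
        ups = np.full(rts.shape, up)
    else:
        ups = np.broadcast_to(np.asarray(boundary, dtype=bool), rts.shape)
    out = np.empty(rts.shape)
    for i in range(rts.size):
        td = rts.flat[i] - params.t
        if ups.flat[i]:
            out.flat[i] = _wfpt_lower_logpdf(td, -params.nu, params.a, 1.0 - params.z, err)
        else:
            out.flat[i] = _wfpt_lower_logpdf(td, params.nu, params.a, params.z, err)
    return float(out[0]) if np.isscalar(rt) else out


# ---------------------------------------------------------------------------
# simulation

def _simulate_paths(n, a, v, t0, w, dt, max_time, seed):
    """Vectorized Euler-Maruyama with Brownian-bridge crossing correction.

    The bridge correction removes the O(sqrt(dt)) bias of naive absorption
    detection: between consecutive interior points the path may still have
    touched a boundary, with probability exp(-2 d0 d1 / dt) for distances
    d0, d1 to that boundary."""
    rng = np.random.default_rng(seed)
    rts = np.full(n, t0 + max_time)
    upper = np.zeros(n, dtype=bool)
    censored = np.ones(n, dtype=bool)
    idx = np.arange(n)
    x = np.full(n, w * a)
    sqdt = np.sqrt(dt)
    max_steps = int(max_time / dt)
    for step in range(max_steps):
        m = idx.size
        if m == 0:
            break
        xn = x + v * dt + sqdt * rng.standard_normal(m)
        hit_up = xn >= a
        hit_lo = xn <= 0.0
        interior = ~(hit_up | hit_lo)
        if interior.any():
            xi, xni = x[interior], xn[interior]
            p_up = np.exp(-2.0 * (a - xi) * (a - xni) / dt)
            p_lo = np.exp(-2.0 * xi * xni / dt)
            u = rng.random(xi.size)
            bu = u < p_up
            bl = (~bu) & (u < p_up + p_lo)
            hit_up[interior] |= bu
            hit_lo[interior] |= bl
        hit = hit_up | hit_lo
        if hit.any():
            gi = idx[hit]
            rts[gi] = t0 + (step + 1) * dt
            upper[gi] = hit_up[hit]
            censored[gi] = False
            keep = ~hit
            idx = idx[keep]
            x = xn[keep]
        else:
            x = xn
    return rts, upper, censored


def simulate_ddm(params: DDMParams, n: int, dt: float = 1e-4, seed: int = 0,
                 max_time: float = 30.0) -> BehaviorSample:
    """Euler-Maruyama first-passage sampling from ``z*a`` between 0 and a.

    Paths not absorbed by ``max_time`` are censored and flagged via
    ``n_censored`` (they are excluded from the returned rt/boundary lists).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rts, upper, censored = _simulate_paths(
        n, params.a, params.nu, params.t, params.z, dt, max_time,
        int(np.uint32(seed) & 0x7FFFFFFF))
    keep = ~censored
    return BehaviorSample(rts[keep], upper[keep], n_censored=int(censored.sum()))


def mean_rt_ddm(params: DDMParams, n_runs: int = 100_000, seed: int = 0,
                dt: float = 1e-4) -> float:
    """Monte-Carlo mean reaction time (absorption time + onset), seconds."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    sample = simulate_ddm(params, n_runs, dt=dt, seed=seed)
    return float(np.mean(sample.rt))


def absorption_probability_upper(params: DDMParams) -> float:
    """Closed-form probability of hitting the upper boundary."""
    a, v, z = params.a, params.nu, params.z
    if abs(v) < 1e-12:
        return z
    return (1.0 - np.exp(-2.0 * v * z * a)) / (1.0 - np.exp(-2.0 * v * a))


# ---------------------------------------------------------------------------
# fitting

_BOUNDS = {"a": (0.1, 8.0), "nu": (-10.0, 10.0), "z": (0.02, 0.98)}


@dataclass
class DDMFitResult:
    """Maximum-likelihood fit of the quadruple (a, nu, t, z)."""

    params: DDMParams
    log_likelihood: float
    converged: bool
    n_obs: int
    flags: list[str] = field(default_factory=list)
    starts: np.ndarray | None = None          # per-start optima, for landscape checks
    posterior_mean: np.ndarray | None = None
    posterior_sd: np.ndarray | None = None
    dic: float | None = None

    def summary(self) -> str:
        lines = [
            "Wiener diffusion fit (maximum likelihood)",
            "=" * 45,
            f"{'n trials':<22}{self.n_obs:>10d}",
            f"{'log-likelihood':<22}{self.log_likelihood:>10.3f}",
            f"{'converged':<22}{str(self.converged):>10}",
        ]
        names = ["a", "nu", "t", "z"]
        vals = self.params.to_array()
        lines.append("-" * 45)
        lines.append(f"{'param':<8}{'estimate':>10}" +
                     ("" if self.posterior_sd is None else f"{'post. sd':>12}"))
        for i, nm in enumerate(names):
            row = f"{nm:<8}{vals[i]:>10.4f}"
            if self.posterior_sd is not None:
                row += f"{self.posterior_sd[i]:>12.4f}"
            lines.append(row)
        if self.dic is not None:
            lines.append("-" * 45)
            lines.append(f"{'DIC':<22}{self.dic:>10.2f}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _neg_loglik(x, rt, upper, err=1e-8):
    a, v, t0, w = x
    ll = _loglik(rt, upper, a, v, t0, w, err)
    if not np.isfinite(ll):
        return 1e12  # finite penalty keeps numerical gradients defined
    return -ll


def fit_ddm(sample: BehaviorSample, n_starts: int = 8, seed: int = 0,
            mcmc: bool = False, mcmc_iter: int = 2000) -> DDMFitResult:
    """Fit (a, nu, t, z) by multi-start maximum likelihood.

    The onset time is constrained below the minimum observed RT.  With
    ``mcmc=True`` a random-walk Metropolis pass around the optimum adds a
    posterior summary and the DIC.
    """
    rt, upper = sample.rt, sample.upper
    if rt.size < 2:
        raise ValueError("need at least two decided trials")
    flags = []
    if upper.all() or (~upper).all():
        flags.append("all trials on one boundary; z and nu at interior bounds")
    rng = np.random.default_rng(seed)
    min_rt = float(rt.min())
    t_hi = max(min_rt - 1e-4, 1e-4)
    bounds = [_BOUNDS["a"], _BOUNDS["nu"], (1e-4, t_hi), _BOUNDS["z"]]

    # heuristic center: method-of-moments-flavored start
    mrt = float(rt.mean())
    p_up = float(upper.mean())
    a0 = np.clip(2.0 * np.sqrt(max(mrt - 0.6 * min_rt, 1e-3)), *_BOUNDS["a"])
    x_center = np.array([a0, np.clip(2.0 * (p_up - 0.5), -2, 2),
                         np.clip(0.6 * min_rt, *bounds[2]), 0.5])

    best, per_start = None, []
    for k in range(max(1, n_starts)):
        if k == 0:
            x0 = x_center
        else:
            x0 = x_center * rng.uniform(0.5, 1.6, size=4)
            x0[1] = x_center[1] + rng.normal(0, 1.0)
            x0[2] = rng.uniform(bounds[2][0], bounds[2][1])
            x0[3] = np.clip(0.5 + rng.normal(0, 0.12), *_BOUNDS["z"])
            x0[0] = np.clip(x0[0], *_BOUNDS["a"])
            x0[1] = np.clip(x0[1], *_BOUNDS["nu"])
        res = minimize(_neg_loglik, x0, args=(rt, upper), method="L-BFGS-B",
                       bounds=bounds)
        if np.isfinite(res.fun):
            per_start.append(np.concatenate([res.x, [-res.fun]]))
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    a, v, t0, w = best.x
    params = DDMParams(a=float(a), nu=float(v), t=float(t0), z=float(w))
    result = DDMFitResult(
        params=params, log_likelihood=float(-best.fun),
        converged=bool(best.success), n_obs=int(rt.size), flags=flags,
        starts=np.array(per_start),
    )
    if mcmc:
        _metropolis_dic(result, sample, rng, n_iter=mcmc_iter)
    return result


def _metropolis_dic(result: DDMFitResult, sample: BehaviorSample,
                    rng: np.random.Generator, n_iter: int = 2000) -> None:
    """Random-walk Metropolis around the MLE (flat prior inside bounds)."""
    rt, upper = sample.rt, sample.upper
    min_rt = float(rt.min())
    lo = np.array([_BOUNDS["a"][0], _BOUNDS["nu"][0], 1e-4, _BOUNDS["z"][0]])
    hi = np.array([_BOUNDS["a"][1], _BOUNDS["nu"][1],
                   max(min_rt - 1e-4, 2e-4), _BOUNDS["z"][1]])
    x = result.params.to_array().clip(lo, hi)
    ll = _loglik(rt, upper, *x, 1e-8)
    scale = np.array([0.03, 0.08, 0.004, 0.015])
    draws = np.empty((n_iter, 4))
    devs = np.empty(n_iter)
    accept = 0
    for i in range(n_iter):
        prop = x + scale * rng.standard_normal(4)
        if np.all(prop >= lo) and np.all(prop <= hi):
            ll_prop = _loglik(rt, upper, *prop, 1e-8)
            if np.log(rng.random()) < ll_prop - ll:
                x, ll = prop, ll_prop
                accept += 1
        draws[i] = x
        devs[i] = -2.0 * ll
    burn = n_iter // 4
    draws, devs = draws[burn:], devs[burn:]
    mean_dev = float(devs.mean())
    theta_bar = draws.mean(axis=0)
    dev_at_mean = -2.0 * _loglik(rt, upper, *theta_bar, 1e-8)
    result.posterior_mean = theta_bar
    result.posterior_sd = draws.std(axis=0)
    result.dic = 2.0 * mean_dev - float(dev_at_mean)


class WienerDiffusionModel:
    """Two-boundary Wiener diffusion model bound to one choice/RT data set.

    Parameters
    ----------
    rt
        Reaction times in seconds (undecided trials already removed).
    upper
        Boolean array; True where the upper boundary (choice A) was hit.

    ``fit()`` returns a :class:`DDMFitResult`.
    """

    def __init__(self, rt, upper):
        self.sample = BehaviorSample(np.asarray(rt, float), np.asarray(upper, bool))

    @classmethod
    def from_dataframe(cls, df, rt_col: str = "rt_ms", choice_col: str = "choice",
                       upper_value="A", rt_unit: str = "ms") -> "WienerDiffusionModel":
        decided = df[df[choice_col].astype(str).isin(["A", "B"])]
        rt = decided[rt_col].to_numpy(dtype=float)
        if rt_unit == "ms":
            rt = rt / 1000.0
        return cls(rt, decided[choice_col].astype(str).to_numpy() == upper_value)

    def loglike(self, params: DDMParams) -> float:
        return float(_loglik(self.sample.rt, self.sample.upper,
                             params.a, params.nu, params.t, params.z, 1e-8))

    def fit(self, n_starts: int = 8, seed: int = 0, mcmc: bool = False,
            mcmc_iter: int = 2000) -> DDMFitResult:
        return fit_ddm(self.sample, n_starts=n_starts, seed=seed,
                       mcmc=mcmc, mcmc_iter=mcmc_iter)
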