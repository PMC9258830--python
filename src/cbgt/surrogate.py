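"""Surrogate data generators with the statistical structure the analyses assume.

Two generators: (a) row-aligned (W, R, P) matrix triples with planted
linear latent structure at specified canonical correlations, so the CCA
pipeline can be validated against a known ground truth; (b) choice/RT
samples from known diffusion-model parameters with a stated fraction of
censored ("no decision") trials, exercising the removal path of the fit.

Latents and noise are Gaussian, which makes the population canonical
correlations analytically known: with a latent entering block Y along a
unit direction with coefficient c over unit noise, the canonical
correlation is c / sqrt(c^2 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddm import BehaviorSample, DDMParams, simulate_ddm
from .ensemble import FeatureMatrices


@dataclass
class SurrogateSpec:
    """Construction plan for a planted-latent (W, R, P) triple.

    ``rho_wr`` / ``rho_rp`` are the planted canonical correlations linking
    W to R and R to P (each in (0, 1]); their lengths set the latent
    dimensions.  Noise is iid standard normal on top of unit-variance
    latent contributions.
    """

    n_samples: int = 300
    rho_wr: tuple[float, ...] = (0.9, 0.8, 0.7)
    rho_rp: tuple[float, ...] = (0.9, 0.8, 0.7)
    n_w: int = 14
    n_r: int = 16
    n_p: int = 4
    seed: int = 0

    def __post_init__(self):
        for rho in (*self.rho_wr, *self.rho_rp):
            if not 0.0 < rho <= 1.0:
                raise ValueError("planted correlations must lie in (0, 1]")
        if len(self.rho_wr) > min(self.n_w, self.n_r):
            raise ValueError("too many W->R latents for the block sizes")
        if len(self.rho_rp) > min(self.n_r, self.n_p):
            raise ValueError("too many R->P latents for the block sizes")


def _orthonormal(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return q[:, :k]


def generate_wrp(spec: SurrogateSpec) -> FeatureMatrices:
    """Draw a (W, R, P) triple with planted canonical correlations.

    W has iid standard-normal columns.  Latents for the W->R link are
    projections of W onto orthonormal directions; each enters R along an
    orthonormal direction with coefficient c = rho / sqrt(1 - rho^2)
    relative to unit noise (giving population canonical correlation rho),
    and analogously for R->P.  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    W = rng.standard_normal((n, spec.n_w))

    def planted_block(X, rhos, out_dim):
        k = len(rhos)
        u = _orthonormal(rng, X.shape[1], k)
        latents = (X - X.mean(0)) / X.std(0) @ u
        latents = (latents - latents.mean(0)) / latents.std(0)
        v = _orthonormal(rng, out_dim, k)
        Y = rng.standard_normal((X.shape[0], out_dim))
        for i, r in enumerate(rhos):
            if r >= 1.0:
                # noise-free direction: the latent itself
                Y -= np.outer(Y @ v[:, i], v[:, i])
                Y += np.outer(latents[:, i], v[:, i])
            else:
                c = r / np.sqrt(1.0 - r * r)
                Y += np.outer(latents[:, i] * c, v[:, i])
        return Y

    R = planted_block(W, spec.rho_wr, spec.n_r)
    P = planted_block(R, spec.rho_rp, spec.n_p)
    return FeatureMatrices(W=W, R=R, P=P)


def generate_behavior(
    params: DDMParams,
    n_trials: int,
    no_decision_rate: float = 0.0,
    seed: int = 0,
    dt: float = 1e-4,
) -> BehaviorSample:
    """Diffusion-simulated trials with a censored ("no decision") fraction.

    Each trial is independently censored with probability
    ``no_decision_rate``; censored trials are removed from the returned
    sample and counted in ``n_censored``, mirroring the preprocessing of
    network sessions.
    """
    if not 0.0 <= no_decision_rate < 1.0:
        raise ValueError("no_decision_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sample = simulate_ddm(params, n_trials, dt=dt,
                          seed=int(rng.integers(2**31 - 1)))
    censor = rng.random(len(sample)) < no_decision_rate
    return BehaviorSample(sample.rt[~censor], sample.upper[~censor],
                          n_censored=int(censor.sum()) + sample.n_censored)
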