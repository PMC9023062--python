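"""Reference Bayesian ball-and-stick estimator.

Per voxel: a Levenberg-Marquardt least-squares initialization seeded from a
log-linear tensor fit, followed by single-site Metropolis MCMC over the
eight parameters ``(d, S0, f1, f2, th1, ph1, th2, ph2)`` with an automatic
relevance determination (ARD) shrinkage prior on the second fibre fraction.

Two engine variants emulate the discrepancy sources between a serial CPU
implementation and a massively parallel GPU one:

``sequential``
    one random-number stream per trial, consumed voxel-by-voxel in scan
    order, with double-precision accumulation throughout;
``phase_parallel``
    all initializations first, then all MCMC, each voxel on its own
    independent RNG substream; with ``precision_mode='single_accumulate'``
    the residual sum-of-squares is additionally rounded to 32-bit float at
    every accumulation step (in both the initialization residuals and the
    MCMC likelihood), emulating single-precision math libraries.

The likelihood is Gaussian with the noise variance marginalized under a
Jeffreys prior, giving ``log L = -(N/2) log(sum_i (y_i - mu_i)^2)``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit
from scipy.optimize import least_squares

from .core import (
    PARAM_NAMES,
    BallStickParams,
    DegenerateInputError,
    GradientTable,
    spherical_to_unit,
    unit_to_spherical,
)
from .phantom import DWIDataset

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "init_fit",
    "log_likelihood",
    "log_prior",
    "metropolis_run",
    "run_engine",
    "write_bedpostx_layout",
    "read_bedpostx_layout",
    "ARD_F_FLOOR",
]

#: Shrinkage cap of the ARD prior: below this fraction the -log(f) penalty
#: is held constant, which keeps the prior proper and the chain mixing while
#: preserving the shrink-to-zero behaviour.
ARD_F_FLOOR = 0.001

_RSS_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# configuration and sample containers


@dataclass
class MCMCConfig:
    """Sampler schedule and engine options.

    The recording schedule follows the reference workflow: of
    ``n_iterations`` total Metropolis iterations the final
    ``n_record_window`` are eligible for recording, one full parameter
    vector every ``thin`` iterations, so each trial contributes
    ``n_record_window / thin`` samples and ``n_trials`` independent trials
    are merged.  Burn-in is the derived difference
    ``n_iterations - n_record_window``.
    """

    n_iterations: int = 2250
    n_record_window: int = 1250
    thin: int = 25
    n_fibres: int = 2
    n_trials: int = 20
    seed_base: int = 0
    engine_variant: str = "sequential"
    precision_mode: str = "double"
    proposal_tune_interval: int = 40

    def __post_init__(self):
        if self.n_record_window > self.n_iterations:
            raise ValueError("n_record_window must not exceed n_iterations")
        if self.thin <= 0 or self.n_record_window % self.thin:
            raise ValueError("thin must divide n_record_window")
        if self.n_fibres != 2:
            raise ValueError("only the two-fibre model is supported")
        if self.engine_variant not in ("sequential", "phase_parallel"):
            raise ValueError(f"unknown engine variant: {self.engine_variant!r}")
        if self.precision_mode not in ("double", "single_accumulate"):
            raise ValueError(f"unknown precision mode: {self.precision_mode!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.proposal_tune_interval < 1:
            raise ValueError("proposal_tune_interval must be >= 1")

    @property
    def burn_in(self) -> int:
        return self.n_iterations - self.n_record_window

    @property
    def samples_per_trial(self) -> int:
        return self.n_record_window // self.thin

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    @property
    def single_accumulate(self) -> bool:
        return self.precision_mode == "single_accumulate"


@dataclass
class PosteriorSamples:
    """Merged per-voxel posterior samples from one engine run.

    ``samples[p]`` has shape ``(n_voxels, n_trials * samples_per_trial)``
    for each parameter p; ``init_values[p]`` has shape
    ``(n_trials, n_voxels)`` and holds each trial's post-initialization
    value (the one-iteration probe of the initialization stage).
    """

    shape: Tuple[int, int, int]
    mask: np.ndarray
    voxel_index: np.ndarray
    samples: Dict[str, np.ndarray]
    init_values: Dict[str, np.ndarray]
    engine_tag: str
    n_trials: int
    samples_per_trial: int
    accept_fraction: float = float("nan")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_index)

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    def volume_from(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3D grid."""
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = values
        return out

    def mean_volume(self, param: str) -> np.ndarray:
        """3D volume of per-voxel posterior means for one parameter."""
        return self.volume_from(self.samples[param].mean(axis=1))


# ---------------------------------------------------------------------------
# likelihood / prior (reference Python forms; the MCMC kernel mirrors them)


def _predict_vector(x: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
                    dtype=np.float64) -> np.ndarray:
    """Two-stick forward model for a flat parameter vector (unclipped)."""
    d, S0, f1, f2, th1, ph1, th2, ph2 = (dtype(v) for v in x)
    b = bvals.astype(dtype)
    g = bvecs.astype(dtype)
    v1 = spherical_to_unit(float(th1), float(ph1)).astype(dtype)
    v2 = spherical_to_unit(float(th2), float(ph2)).astype(dtype)
    c1 = g @ v1
    c2 = g @ v2
    e_ball = np.exp(np.clip(-b * d, -700, 50))
    e1 = np.exp(np.clip(-b * d * c1 * c1, -700, 50))
    e2 = np.exp(np.clip(-b * d * c2 * c2, -700, 50))
    return (S0 * ((1.0 - f1 - f2) * e_ball + f1 * e1 + f2 * e2)).astype(dtype)


def log_likelihood(params: BallStickParams, signal, gradients: GradientTable) -> float:
    """Marginalized-variance Gaussian log likelihood, ``-(N/2) log RSS``.

    A residual sum of squares of exactly zero is floored at a tiny epsilon
    so noiseless data remain finite.
    """
    y = np.asarray(signal, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise ValueError("need at least two volumes")
    mu = _predict_vector(params.to_vector(2), gradients.bvals, gradients.bvecs)
    rss = float(np.sum((y - mu) ** 2))
    return -0.5 * n * math.log(max(rss, _RSS_FLOOR))


def log_prior(params: BallStickParams, ard_on: bool = True,
              f_floor: float = ARD_F_FLOOR) -> float:
    """Log prior density (up to a constant) of a ball-and-stick state.

    Improper uniform on ``d > 0`` and ``S0 > 0``; uniform-on-the-sphere
    ``sin(theta_j)`` term per stick; flat on ``f1``; for secondary fibres
    with ARD active, a ``-log(max(f_j, f_floor))`` shrinkage term.  Returns
    ``-inf`` outside the support (including ``sum f > 1``).
    """
    p = params
    if p.d <= 0 or p.S0 <= 0:
        return -np.inf
    if np.any(p.f < 0) or np.any(p.f > 1) or p.f.sum() > 1:
        return -np.inf
    if np.any(p.theta < 0) or np.any(p.theta > np.pi):
        return -np.inf
    if np.any(p.phi < -np.pi) or np.any(p.phi > np.pi):
        return -np.inf
    s = np.sin(p.theta)
    if np.any(s <= 0):
        return -np.inf
    lp = float(np.sum(np.log(s)))
    if ard_on:
        for j in range(1, p.n_fibres):
            lp -= math.log(max(p.f[j], f_floor))
    return lp


# ---------------------------------------------------------------------------
# initialization


def _tensor_seed(y: np.ndarray, gradients: GradientTable) -> np.ndarray:
    """Tensor-style starting point: log-linear diffusion-tensor regression."""
    b0 = gradients.b0_mask
    dw = gradients.dwi_mask
    S0 = float(np.mean(y[b0]))
    if S0 <= 0:
        raise DegenerateInputError("non-positive mean b0 signal")
    s = np.clip(y[dw] / S0, 1e-10, None)
    b = gradients.bvals[dw]
    g = gradients.bvecs[dw]
    adc = -np.log(s) / b
    design = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    coef, *_ = np.linalg.lstsq(design, adc, rcond=None)
    D = np.array([
        [coef[0], coef[3], coef[4]],
        [coef[3], coef[1], coef[5]],
        [coef[4], coef[5], coef[2]],
    ])
    lam, vec = np.linalg.eigh(D)
    lam_c = np.clip(lam, 0.0, None)
    md = float(lam_c.mean())
    d0 = max(md, 1e-7)
    v1 = vec[:, np.argmax(lam)]
    th1, ph1 = unit_to_spherical(v1)
    # fractional-anisotropy-like seed for f1
    denom = float(np.sum(lam_c ** 2))
    if denom > 0:
        fa = math.sqrt(1.5 * float(np.sum((lam_c - md) ** 2)) / denom)
    else:
        fa = 0.0
    f1 = float(np.clip(fa, 0.01, 0.9))
    # second stick perpendicular to the first, small fraction
    e = np.zeros(3)
    e[np.argmin(np.abs(v1))] = 1.0
    v2 = np.cross(v1, e)
    v2 /= np.linalg.norm(v2)
    th2, ph2 = unit_to_spherical(v2)
    return np.array([d0, S0, f1, 0.05, th1, ph1, th2, ph2])


def _canonicalize(x: np.ndarray) -> np.ndarray:
    """Clip a raw fitted vector into the model's support."""
    x = x.copy()
    x[0] = max(x[0], 0.0)
    if x[1] <= 0:
        x[1] = 1e-6
    x[2] = min(max(x[2], 0.0), 1.0)
    x[3] = min(max(x[3], 0.0), 1.0)
    s = x[2] + x[3]
    if s > 1.0:
        x[2] *= (1.0 - 1e-9) / s
        x[3] *= (1.0 - 1e-9) / s
    for j in (0, 1):
        v = spherical_to_unit(x[4 + 2 * j], x[5 + 2 * j])
        th, ph = unit_to_spherical(v)
        x[4 + 2 * j] = th
        x[5 + 2 * j] = ph
    return x


def init_fit(signal, gradients: GradientTable, n_fibres: int = 2,
             single_precision: bool = False) -> BallStickParams:
    """Levenberg-Marquardt least-squares initialization for one voxel.

    Minimizes the sum of squared ball-and-stick residuals by damped least
    squares, started from a log-linear tensor-style seed (S0 from the mean
    b0 signal, d and the first orientation from the tensor fit, f1 from its
    anisotropy, a small perpendicular second stick).  With
    ``single_precision`` the residual pipeline runs in 32-bit float with a
    correspondingly coarser finite-difference step, emulating a
    single-precision math library.
    """
    if n_fibres != 2:
        raise ValueError("only the two-fibre model is supported")
    y = np.asarray(signal, dtype=float).ravel()
    if not np.any(y):
        raise DegenerateInputError("all-zero voxel signal")
    if gradients.b0_mask.sum() < 1:
        raise ValueError("at least one b=0 volume required")
    if gradients.dwi_mask.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted volumes required")

    x0 = _tensor_seed(y, gradients)
    bvals = gradients.bvals
    bvecs = gradients.bvecs

    if single_precision:
        y_work = y.astype(np.float32)

        def residual(x):
            mu = _predict_vector(x, bvals, bvecs, dtype=np.float32)
            return (y_work - mu).astype(np.float64)

        diff_step = 3.5e-4  # ~sqrt(float32 machine epsilon)
    else:
        def residual(x):
            return y - _predict_vector(x, bvals, bvecs)

        diff_step = None

    try:
        res = least_squares(residual, x0, method="lm", diff_step=diff_step,
                            ftol=1e-6, xtol=1e-6, gtol=1e-6, max_nfev=400)
        x = res.x
    except Exception:
        x = x0
    return BallStickParams.from_vector(_canonicalize(x)).validate()


# ---------------------------------------------------------------------------
# Metropolis kernel (numba)


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _rss_accum(y, E, A1, A2, S0, f1, f2, single_acc):
    acc = 0.0
    f0 = 1.0 - f1 - f2
    for i in range(y.shape[0]):
        mu = S0 * (f0 * E[i] + f1 * A1[i] + f2 * A2[i])
        r = y[i] - mu
        acc = acc + r * r
        if single_acc:
            acc = float(np.float32(acc))
    return acc


@njit(cache=True)
def _fill_dirsq(bvecs, th, ph, out):
    st = math.sin(th)
    vx = st * math.cos(ph)
    vy = st * math.sin(ph)
    vz = math.cos(th)
    for i in range(bvecs.shape[0]):
        c = bvecs[i, 0] * vx + bvecs[i, 1] * vy + bvecs[i, 2] * vz
        out[i] = c * c


@njit(cache=True)
def _fill_stick_exp(bvals, d, csq, out):
    for i in range(bvals.shape[0]):
        out[i] = math.exp(-bvals[i] * d * csq[i])


@njit(cache=True)
def _fill_ball_exp(bvals, d, out):
    for i in range(bvals.shape[0]):
        out[i] = math.exp(-bvals[i] * d)


@njit(cache=True)
def _metropolis_kernel(y, bvals, bvecs, p0, n_iter, burn, thin, tune_interval,
                       single_acc, do_seed, seed, sd0, f_floor):
    """Single-voxel, single-trial Metropolis chain.

    Returns (records, rec_accepted, rec_proposed): records of all 8
    parameters every `thin` iterations within the final recording window,
    plus acceptance counts over that window.
    """
    if do_seed:
        np.random.seed(seed)

    n = y.shape[0]
    half_n = 0.5 * n
    p = p0.copy()
    sd = sd0.copy()
    sd_lo = sd0 * 0.01
    sd_hi = sd0 * 10.0

    E = np.empty(n)
    E_new = np.empty(n)
    c1sq = np.empty(n)
    c1sq_new = np.empty(n)
    c2sq = np.empty(n)
    c2sq_new = np.empty(n)
    A1 = np.empty(n)
    A1_new = np.empty(n)
    A2 = np.empty(n)
    A2_new = np.empty(n)

    _fill_ball_exp(bvals, p[0], E)
    _fill_dirsq(bvecs, p[4], p[5], c1sq)
    _fill_dirsq(bvecs, p[6], p[7], c2sq)
    _fill_stick_exp(bvals, p[0], c1sq, A1)
    _fill_stick_exp(bvals, p[0], c2sq, A2)
    rss = _rss_accum(y, E, A1, A2, p[1], p[2], p[3], single_acc)
    if rss < 1e-300:
        rss = 1e-300

    n_rec = (n_iter - burn) // thin
    records = np.empty((n_rec, 8))
    rec_idx = 0
    rec_acc = 0
    rec_prop = 0
    acc_cnt = np.zeros(8, dtype=np.int64)
    prop_cnt = np.zeros(8, dtype=np.int64)

    for it in range(1, n_iter + 1):
        for k in range(8):
            step = sd[k] * np.random.standard_normal()
            pnew = p[k] + step
            dlp = 0.0
            valid = True
            recompute = 0  # 0: f/S0 only, 1: d, 2: stick1 angles, 3: stick2 angles

            if k == 0:
                if pnew <= 0.0:
                    valid = False
                else:
                    recompute = 1
            elif k == 1:
                if pnew <= 0.0:
                    valid = False
            elif k == 2:
                if pnew < 0.0 or pnew > 1.0 or pnew + p[3] > 1.0:
                    valid = False
            elif k == 3:
                if pnew < 0.0 or pnew > 1.0 or p[2] + pnew > 1.0:
                    valid = False
                else:
                    f_old = p[3] if p[3] > f_floor else f_floor
                    f_new = pnew if pnew > f_floor else f_floor
                    dlp = math.log(f_old) - math.log(f_new)
            elif k == 4 or k == 6:
                # reflect theta into [0, pi]
                t = pnew
                while t < 0.0 or t > math.pi:
                    if t < 0.0:
                        t = -t
                    if t > math.pi:
                        t = 2.0 * math.pi - t
                pnew = t
                s_new = math.sin(pnew)
                s_old = math.sin(p[k])
                if s_new <= 0.0:
                    valid = False
                else:
                    dlp = math.log(s_new) - math.log(s_old)
                    recompute = 2 if k == 4 else 3
            else:
                # wrap phi into [-pi, pi]
                pnew = (pnew + math.pi) % (2.0 * math.pi) - math.pi
                recompute = 2 if k == 5 else 3

            accepted = False
            if valid:
                if recompute == 1:
                    _fill_ball_exp(bvals, pnew, E_new)
                    _fill_stick_exp(bvals, pnew, c1sq, A1_new)
                    _fill_stick_exp(bvals, pnew, c2sq, A2_new)
                    rss_new = _rss_accum(y, E_new, A1_new, A2_new,
                                         p[1], p[2], p[3], single_acc)
                elif recompute == 2:
                    th = pnew if k == 4 else p[4]
                    ph = pnew if k == 5 else p[5]
                    _fill_dirsq(bvecs, th, ph, c1sq_new)
                    _fill_stick_exp(bvals, p[0], c1sq_new, A1_new)
                    rss_new = _rss_accum(y, E, A1_new, A2,
                                         p[1], p[2], p[3], single_acc)
                elif recompute == 3:
                    th = pnew if k == 6 else p[6]
                    ph = pnew if k == 7 else p[7]
                    _fill_dirsq(bvecs, th, ph, c2sq_new)
                    _fill_stick_exp(bvals, p[0], c2sq_new, A2_new)
                    rss_new = _rss_accum(y, E, A1, A2_new,
                                         p[1], p[2], p[3], single_acc)
                else:
                    S0 = pnew if k == 1 else p[1]
                    f1 = pnew if k == 2 else p[2]
                    f2 = pnew if k == 3 else p[3]
                    rss_new = _rss_accum(y, E, A1, A2, S0, f1, f2, single_acc)
                if rss_new < 1e-300:
                    rss_new = 1e-300
                dll = -half_n * (math.log(rss_new) - math.log(rss))
                if math.log(np.random.random()) < dll + dlp:
                    accepted = True
                    p[k] = pnew
                    rss = rss_new
                    if recompute == 1:
                        E, E_new = E_new, E
                        A1, A1_new = A1_new, A1
                        A2, A2_new = A2_new, A2
                    elif recompute == 2:
                        c1sq, c1sq_new = c1sq_new, c1sq
                        A1, A1_new = A1_new, A1
                    elif recompute == 3:
                        c2sq, c2sq_new = c2sq_new, c2sq
                        A2, A2_new = A2_new, A2

            prop_cnt[k] += 1
            if accepted:
                acc_cnt[k] += 1
            if it > burn:
                rec_prop += 1
                if accepted:
                    rec_acc += 1

        # joint fraction-exchange move: shift weight between the two sticks
        # at fixed total.  When the sticks are (near-)aligned the likelihood
        # is flat along this ridge and single-site updates diffuse slowly;
        # the exchange move lets the ARD prior drain the secondary fraction.
        eps = 0.05 * np.random.standard_normal()
        f1x = p[2] - eps
        f2x = p[3] + eps
        if 0.0 <= f1x <= 1.0 and 0.0 <= f2x <= 1.0 and f1x + f2x <= 1.0:
            f_old = p[3] if p[3] > f_floor else f_floor
            f_new = f2x if f2x > f_floor else f_floor
            dlp = math.log(f_old) - math.log(f_new)
            rss_new = _rss_accum(y, E, A1, A2, p[1], f1x, f2x, single_acc)
            if rss_new < 1e-300:
                rss_new = 1e-300
            dll = -half_n * (math.log(rss_new) - math.log(rss))
            if math.log(np.random.random()) < dll + dlp:
                p[2] = f1x
                p[3] = f2x
                rss = rss_new

        # label-swap move: exchange the two sticks wholesale.  The
        # likelihood is invariant, so acceptance depends only on the ARD
        # prior ratio; this frees chains trapped in the label-switched mode
        # (large fraction on the ARD-penalized second stick) that
        # single-site updates cannot leave.
        if np.random.random() < 0.5:
            f_old = p[3] if p[3] > f_floor else f_floor
            f_new = p[2] if p[2] > f_floor else f_floor
            if math.log(np.random.random()) < math.log(f_old) - math.log(f_new):
                p[2], p[3] = p[3], p[2]
                p[4], p[6] = p[6], p[4]
                p[5], p[7] = p[7], p[5]
                c1sq, c2sq = c2sq, c1sq
                A1, A2 = A2, A1

        # antipodal representation flips: (th, ph) and (pi - th, ph + pi)
        # denote the same stick axis; exchanging them is a symmetric,
        # posterior-invariant move that keeps both representations equally
        # occupied so angle marginals do not depend on which one a chain
        # happens to settle in
        for j in range(2):
            if np.random.random() < 0.5:
                kt = 4 + 2 * j
                p[kt] = math.pi - p[kt]
                p[kt + 1] = (p[kt + 1] + 2.0 * math.pi) % (2.0 * math.pi) - math.pi

        # proposal adaptation toward ~50% acceptance, burn-in only
        if it <= burn and it % tune_interval == 0:
            for k in range(8):
                if prop_cnt[k] > 0:
                    rate = acc_cnt[k] / prop_cnt[k]
                    if rate > 0.5:
                        sd[k] *= 1.1
                    else:
                        sd[k] *= 0.9
                    if sd[k] < sd_lo[k]:
                        sd[k] = sd_lo[k]
                    if sd[k] > sd_hi[k]:
                        sd[k] = sd_hi[k]
                acc_cnt[k] = 0
                prop_cnt[k] = 0

        if it > burn and (it - burn) % thin == 0:
            for k in range(8):
                records[rec_idx, k] = p[k]
            rec_idx += 1

    return records, rec_acc, rec_prop


def _default_proposal_sd(s0_init: float) -> np.ndarray:
    """Initial proposal sds: 10% of each parameter's plausible range."""
    return np.array([
        5e-4,                # d: range ~ [0, 5e-3]
        0.2 * max(s0_init, 1e-6),  # S0: range ~ [0, 2 S0]
        0.1,                 # f1
        0.1,                 # f2
        0.1 * np.pi,         # th1: range [0, pi]
        0.2 * np.pi,         # ph1: range [-pi, pi]
        0.1 * np.pi,         # th2
        0.2 * np.pi,         # ph2
    ])


def metropolis_run(signal, gradients: GradientTable, init: BallStickParams,
                   config: MCMCConfig, seed: int) -> np.ndarray:
    """Run one voxel's Metropolis chain for one trial; returns records.

    Records have shape ``(n_record_window / thin, 8)`` in canonical
    parameter order.  A thin wrapper over the compiled kernel that seeds a
    fresh RNG stream; :func:`run_engine` manages streams across voxels.
    """
    init.validate()
    y = np.asarray(signal, dtype=float).ravel()
    p0 = init.to_vector(2)
    records, _, _ = _metropolis_kernel(
        y, gradients.bvals, gradients.bvecs, p0,
        config.n_iterations, config.burn_in, config.thin,
        config.proposal_tune_interval, config.single_accumulate,
        True, int(seed) % (2 ** 31), _default_proposal_sd(p0[1]), ARD_F_FLOOR,
    )
    return records


# ---------------------------------------------------------------------------
# engines


def _trial_seed(seed_base: int, trial: int) -> int:
    ss = np.random.SeedSequence([int(seed_base), int(trial)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _voxel_seed(seed_base: int, trial: int, voxel: int) -> int:
    ss = np.random.SeedSequence([int(seed_base), int(trial), int(voxel)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_engine(dataset: DWIDataset, config: MCMCConfig) -> PosteriorSamples:
    """Fit the whole volume with one engine variant; merge all trials.

    The L-M initialization is deterministic for a given precision mode, so
    every trial starts from the same per-voxel state (recorded per trial in
    ``init_values``); trials differ only in their MCMC random streams.
    """
    mask = dataset.mask
    if not mask.any():
        raise ValueError("dataset mask is empty")
    voxels = np.argwhere(mask)
    n_vox = len(voxels)
    gradients = dataset.gradients
    single = config.single_accumulate

    # initialization phase (order is irrelevant to the result: no RNG used)
    init_mat = np.empty((n_vox, 8))
    signals = np.empty((n_vox, gradients.n_volumes))
    for vi, (i, j, k) in enumerate(voxels):
        y = dataset.signal[i, j, k, :].astype(float)
        signals[vi] = y
        init_mat[vi] = init_fit(y, gradients, single_precision=single).to_vector(2)

    n_per_trial = config.samples_per_trial
    all_samples = np.empty((n_vox, config.n_samples, 8))
    tot_acc = 0
    tot_prop = 0

    for t in range(config.n_trials):
        lo = t * n_per_trial
        hi = lo + n_per_trial
        if config.engine_variant == "sequential":
            _seed_rng(_trial_seed(config.seed_base, t))
            for vi in range(n_vox):
                rec, a, pr = _metropolis_kernel(
                    signals[vi], gradients.bvals, gradients.bvecs,
                    init_mat[vi].copy(), config.n_iterations, config.burn_in,
                    config.thin, config.proposal_tune_interval, single,
                    False, 0, _default_proposal_sd(init_mat[vi, 1]), ARD_F_FLOOR,
                )
                all_samples[vi, lo:hi] = rec
                tot_acc += a
                tot_prop += pr
        else:
            for vi in range(n_vox):
                rec, a, pr = _metropolis_kernel(
                    signals[vi], gradients.bvals, gradients.bvecs,
                    init_mat[vi].copy(), config.n_iterations, config.burn_in,
                    config.thin, config.proposal_tune_interval, single,
                    True, _voxel_seed(config.seed_base, t, vi),
                    _default_proposal_sd(init_mat[vi, 1]), ARD_F_FLOOR,
                )
                all_samples[vi, lo:hi] = rec
                tot_acc += a
                tot_prop += pr

    samples = {name: np.ascontiguousarray(all_samples[:, :, k])
               for k, name in enumerate(PARAM_NAMES)}
    init_values = {name: np.tile(init_mat[:, k], (config.n_trials, 1))
                   for k, name in enumerate(PARAM_NAMES)}
    return PosteriorSamples(
        shape=dataset.shape,
        mask=mask.copy(),
        voxel_index=voxels,
        samples=samples,
        init_values=init_values,
        engine_tag=f"{config.engine_variant}/{config.precision_mode}",
        n_trials=config.n_trials,
        samples_per_trial=n_per_trial,
        accept_fraction=tot_acc / tot_prop if tot_prop else float("nan"),
    )


# ---------------------------------------------------------------------------
# bedpostx-style on-disk layout

_MERGED_PARAMS = ("f1", "f2", "ph1", "th1", "ph2", "th2", "d", "S0")


def write_bedpostx_layout(samples: PosteriorSamples, out_dir: str) -> None:
    """Write merged sample volumes in the bedpostx output convention.

    4D ``merged_<p>samples`` volumes (4th axis = sample index) for the six
    compared parameters plus d and S0, 3D ``mean_dsamples`` /
    ``mean_S0samples``, per-trial 4D ``init_<p>samples`` volumes (4th axis =
    trial), the brain mask, and a JSON sidecar with run metadata.
    Masked-out voxels hold 0 everywhere.
    """
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    aff = np.eye(4)
    idx = tuple(samples.voxel_index.T)
    for p in _MERGED_PARAMS:
        vol = np.zeros(samples.shape + (samples.n_samples,))
        vol[idx] = samples.samples[p]
        nib.save(nib.Nifti1Image(vol, aff),
                 os.path.join(out_dir, f"merged_{p}samples.nii.gz"))
    for p in ("d", "S0"):
        mean = np.zeros(samples.shape)
        mean[idx] = samples.samples[p].mean(axis=1)
        nib.save(nib.Nifti1Image(mean, aff),
                 os.path.join(out_dir, f"mean_{p}samples.nii.gz"))
    for p in PARAM_NAMES:
        vol = np.zeros(samples.shape + (samples.n_trials,))
        vol[idx] = samples.init_values[p].T
        nib.save(nib.Nifti1Image(vol, aff),
                 os.path.join(out_dir, f"init_{p}samples.nii.gz"))
    nib.save(nib.Nifti1Image(samples.mask.astype(np.uint8), aff),
             os.path.join(out_dir, "nodif_brain_mask.nii.gz"))
    meta = {
        "engine_tag": samples.engine_tag,
        "n_trials": samples.n_trials,
        "samples_per_trial": samples.samples_per_trial,
        "accept_fraction": samples.accept_fraction,
    }
    with open(os.path.join(out_dir, "run_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_bedpostx_layout(in_dir: str) -> PosteriorSamples:
    """Read a directory written by :func:`write_bedpostx_layout`."""
    import nibabel as nib

    mask = np.asarray(
        nib.load(os.path.join(in_dir, "nodif_brain_mask.nii.gz")).dataobj
    ).astype(bool)
    voxels = np.argwhere(mask)
    idx = tuple(voxels.T)
    with open(os.path.join(in_dir, "run_meta.json")) as fh:
        meta = json.load(fh)
    samples = {}
    for p in _MERGED_PARAMS:
        vol = np.asarray(
            nib.load(os.path.join(in_dir, f"merged_{p}samples.nii.gz")).dataobj
        ).astype(float)
        samples[p] = vol[idx]
    init_values = {}
    for p in PARAM_NAMES:
        vol = np.asarray(
            nib.load(os.path.join(in_dir, f"init_{p}samples.nii.gz")).dataobj
        ).astype(float)
        init_values[p] = vol[idx].T
    return PosteriorSamples(
        shape=mask.shape,
        mask=mask,
        voxel_index=voxels,
        samples=samples,
        init_values=init_values,
        engine_tag=meta["engine_tag"],
        n_trials=int(meta["n_trials"]),
        samples_per_trial=int(meta["samples_per_trial"]),
        accept_fraction=float(meta["accept_fraction"]),
    )
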