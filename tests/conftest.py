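"""Shared fixtures and factories for the test suite."""

import numpy as np
import pytest

import ballstick as bs
from ballstick.core import PARAM_NAMES


@pytest.fixture(scope="session")
def gtab():
    """The reference single-shell scheme: 64 directions + 6 b0 at b=1000."""
    return bs.make_gradient_table(64, 6, 1000)


@pytest.fixture(scope="session")
def gtab_small():
    """A minimal legal scheme for fast sampler schedule tests."""
    return bs.make_gradient_table(6, 1, 1000)


def noiseless_voxel(params, gtab):
    """Noiseless signal vector for one set of parameters."""
    return np.array([
        bs.ball_stick_signal(params, b, g)
        for b, g in zip(gtab.bvals, gtab.bvecs)
    ])


def make_posterior(samples_by_param, n_trials=1, init_by_param=None, tag="A"):
    """Build a PosteriorSamples container from raw per-voxel sample arrays.

    ``samples_by_param`` maps parameter names to (n_voxels, n_samples)
    arrays; missing parameters are filled with zeros (d, S0 with small
    positive constants).  Voxels are laid out on an (n_voxels, 1, 1) grid.
    """
    ref = next(iter(samples_by_param.values()))
    n_vox, n_samples = np.asarray(ref).shape
    if n_samples % n_trials:
        raise ValueError("n_trials must divide the sample count")
    fills = {"d": 1e-3, "S0": 100.0}
    samples = {}
    for p in PARAM_NAMES:
        if p in samples_by_param:
            samples[p] = np.asarray(samples_by_param[p], dtype=float)
        else:
            samples[p] = np.full((n_vox, n_samples), fills.get(p, 0.0))
    init_values = {}
    for p in PARAM_NAMES:
        if init_by_param and p in init_by_param:
            base = np.asarray(init_by_param[p], dtype=float)
        else:
            base = samples[p].mean(axis=1)
        init_values[p] = np.tile(base, (n_trials, 1))
    shape = (n_vox, 1, 1)
    mask = np.ones(shape, dtype=bool)
    return bs.PosteriorSamples(
        shape=shape,
        mask=mask,
        voxel_index=np.argwhere(mask),
        samples=samples,
        init_values=init_values,
        engine_tag=tag,
        n_trials=n_trials,
        samples_per_trial=n_samples // n_trials,
    )


def ks_brute(a, b):
    """Independent oracle: ECDF sup-difference by scanning pooled points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pts = np.concatenate([a, b])
    fa = np.searchsorted(a, pts, side="right") / len(a)
    fb = np.searchsorted(b, pts, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))
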