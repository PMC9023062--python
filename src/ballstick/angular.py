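"""Directional statistics on fibre-orientation posterior samples.

Orientation samples are axial data: a stick along ``v`` is the same fibre
as one along ``-v``.  All angles here are therefore computed modulo sign
(``arccos |u.v|``, at most 90 degrees).  The mean principal diffusion
direction (PDD) of a sample set is the principal eigenvector of the mean
dyadic tensor -- the standard axial-data mean, invariant to antiparallel
flips of any subset of samples.  The cone of angular uncertainty (CAU) is a
percentile (95th by default) of the per-sample axial deviations from that
mean.

Also provided: the per-voxel [phi, theta]-pair significance rule (a pair is
significant when either angle's distribution differs; the pair's S score is
the larger of the two), per-S-range angular summary tables, and the
label-switch correction that swaps the two fibres' samples wherever the
second fraction exceeds the first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .compare import ComparisonResult, S_BINS, bin_s
from .core import spherical_to_unit, unit_to_spherical
from .inference import PosteriorSamples

__all__ = [
    "PDDSet",
    "spherical_to_unit",
    "unit_to_spherical",
    "axial_angle",
    "mean_pdd",
    "cau",
    "compute_pdd_set",
    "pair_significance",
    "angular_table",
    "swap_correction",
]


def axial_angle(u, v, full: bool = False) -> np.ndarray:
    """Angle between orientations in degrees.

    Axial by default: ``arccos |u.v|`` in [0, 90], treating antiparallel
    vectors as identical.  With ``full=True`` returns the ordinary angle in
    [0, 180] (exposed for exploration only).  Broadcasts over leading axes.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dot = np.sum(u * v, axis=-1)
    if full:
        ang = np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))
    else:
        ang = np.degrees(np.arccos(np.clip(np.abs(dot), 0.0, 1.0)))
    return ang if ang.ndim else float(ang)


def mean_pdd(vectors: np.ndarray) -> np.ndarray:
    """Mean axis of a set of unit vectors via the mean dyadic tensor.

    Returns the principal eigenvector of ``mean(v v^T)``, sign-fixed so its
    largest-magnitude component is positive.  Antiparallel inputs are
    equivalent by construction.  A (near-)degenerate top eigenvalue pair is
    resolved deterministically by eigenvector index.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if len(vectors) < 1:
        raise ValueError("need at least one vector")
    T = vectors.T @ vectors / len(vectors)
    w, V = np.linalg.eigh(T)
    # eigh sorts ascending; the last column is the principal axis and ties
    # resolve to the highest index deterministically
    v = V[:, -1]
    k = int(np.argmax(np.abs(v)))
    if v[k] < 0:
        v = -v
    return v


def cau(vectors: np.ndarray, percentile: float = 95.0) -> float:
    """Cone of angular uncertainty: percentile of axial deviations (degrees).

    Deviations are measured from the sample set's own dyadic mean axis;
    linear interpolation between order statistics.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    axis = mean_pdd(vectors)
    angles = axial_angle(vectors, axis)
    return float(np.percentile(angles, percentile))


@dataclass
class PDDSet:
    """Per-voxel mean principal diffusion directions and uncertainty cones."""

    fibre: int
    mean_pdd: np.ndarray      # (n_voxels, 3), unit axes
    cau: np.ndarray           # (n_voxels,), degrees
    percentile: float = 95.0


def compute_pdd_set(samples: PosteriorSamples, fibre: int,
                    percentile: float = 95.0) -> PDDSet:
    """Mean PDD and CAU per voxel for one fibre of an engine run."""
    th = samples.samples[f"th{fibre}"]
    ph = samples.samples[f"ph{fibre}"]
    vecs = spherical_to_unit(th, ph)          # (V, n, 3)
    n_vox = vecs.shape[0]
    # batched dyadic means and eigendecomposition
    T = np.einsum("vni,vnj->vij", vecs, vecs) / vecs.shape[1]
    w, V = np.linalg.eigh(T)
    axes = V[:, :, -1]
    k = np.argmax(np.abs(axes), axis=1)
    signs = np.sign(axes[np.arange(n_vox), k])
    signs[signs == 0] = 1.0
    axes = axes * signs[:, None]
    angles = axial_angle(vecs, axes[:, None, :])
    cau_vec = np.percentile(angles, percentile, axis=1)
    return PDDSet(fibre=fibre, mean_pdd=axes, cau=cau_vec, percentile=percentile)


def pair_significance(result: ComparisonResult, fibre: int):
    """[phi, theta]-pair significance per voxel for one fibre.

    A voxel's orientation pair is significant when phi OR theta is; the
    pair's S is the maximum of the two.  Returns
    ``(significant, S_pair, s_bin)`` arrays.
    """
    ph, th = f"ph{fibre}", f"th{fibre}"
    for p in (ph, th):
        if p not in result.params:
            raise ValueError(f"comparison does not cover {p!r}")
    sig = result.significant[ph] | result.significant[th]
    s_pair = np.maximum(result.S[ph], result.S[th])
    bins = np.array([bin_s(s, g) for s, g in zip(s_pair, sig)])
    return sig, s_pair, bins


def angular_table(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    result: ComparisonResult,
    fibre: int,
    restrict: str = "none",
    tissue_labels: Optional[np.ndarray] = None,
    percentile: float = 95.0,
    f2_floor: float = 0.05,
    full_angle: bool = False,
) -> pd.DataFrame:
    """Per-S-range summary of mean-PDD differences and uncertainty cones.

    Rows cover the four S ranges plus "All" over voxels whose [phi, theta]
    pair is significantly different for the given fibre.  ``restrict`` may
    additionally limit rows to white matter (``'wm_only'``) or to white
    matter with mean f2 >= ``f2_floor`` in either engine
    (``'wm_and_f2floor'``); both need ``tissue_labels``.
    """
    if restrict not in ("none", "wm_only", "wm_and_f2floor"):
        raise ValueError(f"unknown restriction: {restrict!r}")
    if restrict != "none" and tissue_labels is None:
        raise ValueError("tissue_labels required for white-matter restriction")

    sig, s_pair, bins = pair_significance(result, fibre)
    pdd_a = compute_pdd_set(samples_a, fibre, percentile)
    pdd_b = compute_pdd_set(samples_b, fibre, percentile)
    delta = axial_angle(pdd_a.mean_pdd, pdd_b.mean_pdd, full=full_angle)

    keep = np.ones(result.n_voxels, dtype=bool)
    if restrict != "none":
        labels = tissue_labels[tuple(result.voxel_index.T)]
        keep &= (labels == 3) | (labels == 4)
    if restrict == "wm_and_f2floor":
        mean_f2 = np.maximum(samples_a.samples["f2"].mean(axis=1),
                             samples_b.samples["f2"].mean(axis=1))
        keep &= mean_f2 >= f2_floor

    rows = []
    for label in list(S_BINS) + ["All"]:
        sel = (sig if label == "All" else (bins == label)) & keep
        n = int(sel.sum())
        if n:
            rows.append({
                "s_range": label,
                "n_voxels": n,
                "mean_delta_pdd_deg": float(delta[sel].mean()),
                "sd_delta_pdd_deg": float(delta[sel].std(ddof=0)),
                "median_delta_pdd_deg": float(np.median(delta[sel])),
                "mean_cau_a_deg": float(pdd_a.cau[sel].mean()),
                "mean_cau_b_deg": float(pdd_b.cau[sel].mean()),
            })
        else:
            rows.append({
                "s_range": label, "n_voxels": 0,
                "mean_delta_pdd_deg": np.nan, "sd_delta_pdd_deg": np.nan,
                "median_delta_pdd_deg": np.nan,
                "mean_cau_a_deg": np.nan, "mean_cau_b_deg": np.nan,
            })
    return pd.DataFrame(rows).set_index("s_range")


def swap_correction(samples: PosteriorSamples, per_sample: bool = True) -> PosteriorSamples:
    """Relabel fibres so the first fraction dominates: swap where f2 > f1.

    Label switching makes "fibre 1" and "fibre 2" interchangeable between
    runs when the two sub-fibre populations have comparable fractions.  The
    correction exchanges ``(f1, ph1, th1)`` with ``(f2, ph2, th2)``
    per sample wherever ``f2 > f1`` (the stricter convention); with
    ``per_sample=False`` whole voxels are swapped based on their posterior
    means instead.  Initialization values are relabelled by the same rule.
    Idempotent: corrected output has f1 >= f2 everywhere.
    """
    s = {p: samples.samples[p].copy() for p in samples.samples}
    iv = {p: samples.init_values[p].copy() for p in samples.init_values}

    if per_sample:
        swap = s["f2"] > s["f1"]
    else:
        swap = (s["f2"].mean(axis=1) > s["f1"].mean(axis=1))[:, None]
        swap = np.broadcast_to(swap, s["f1"].shape).copy()
    for a, b in (("f1", "f2"), ("ph1", "ph2"), ("th1", "th2")):
        s[a][swap], s[b][swap] = s[b][swap], s[a][swap]

    iswap = iv["f2"] > iv["f1"]
    for a, b in (("f1", "f2"), ("ph1", "ph2"), ("th1", "th2")):
        iv[a][iswap], iv[b][iswap] = iv[b][iswap], iv[a][iswap]

    return replace(samples, samples=s, init_values=iv,
                   engine_tag=samples.engine_tag + "+swap"
                   if not samples.engine_tag.endswith("+swap")
                   else samples.engine_tag)
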