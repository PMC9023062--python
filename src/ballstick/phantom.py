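"""Synthetic single-shell diffusion-weighted phantom generation.

Builds small whole-volume datasets with known ground-truth ball-and-stick
parameters, four tissue compartments (CSF, grey matter, single-fibre white
matter, crossing-fibre white matter) and controllable measurement noise,
emulating the structure of a b = 1000 s/mm^2, 64-direction + 6 b0 clinical
acquisition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (
    PARAM_NAMES,
    BallStickParams,
    GradientTable,
    spherical_to_unit,
)

__all__ = [
    "TISSUE_LABELS",
    "CompartmentSpec",
    "ParameterGrid",
    "DWIDataset",
    "make_gradient_table",
    "ball_stick_signal",
    "predict_signal",
    "default_layout",
    "build_phantom",
    "simulate_dwi",
    "save_dataset",
    "load_dataset",
]

#: Tissue label codes used in tissue_labels volumes.
TISSUE_LABELS = {
    0: "outside",
    1: "csf",
    2: "gm",
    3: "wm_single",
    4: "wm_crossing",
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def make_gradient_table(n_directions: int, n_b0: int, bval: float) -> GradientTable:
    """Deterministic single-shell gradient scheme.

    ``n_b0`` zero-b entries are followed by ``n_directions`` entries at
    ``bval`` whose unit directions form a spherical Fibonacci spiral —
    approximately uniform on the sphere, pairwise distinct, and identical on
    every call.

    Parameters
    ----------
    n_directions : int
        Number of diffusion-weighted directions; must be >= 6.
    n_b0 : int
        Number of non-diffusion-weighted (b = 0) volumes.
    bval : float
        Shell b-value in s/mm^2; must be positive when ``n_directions > 0``.
    """
    if n_directions < 6:
        raise ValueError("at least 6 diffusion-weighted directions required")
    if n_b0 < 0:
        raise ValueError("n_b0 must be non-negative")
    if n_directions > 0 and bval <= 0:
        raise ValueError("bval must be positive for diffusion-weighted volumes")

    k = np.arange(n_directions)
    z = 1.0 - (2.0 * k + 1.0) / n_directions
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    az = k * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def ball_stick_signal(params: BallStickParams, bval: float, bvec) -> float:
    """Predicted ball-and-stick signal for a single volume.

    ``mu = S0 [ (1 - sum f_j) exp(-b d) + sum_j f_j exp(-b d (g.v_j)^2) ]``.
    Returns ``S0`` when ``bval == 0``.
    """
    params.validate()
    g = np.asarray(bvec, dtype=float)
    if bval > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("bvec must be unit-norm when bval > 0")
    if bval == 0:
        return float(params.S0)
    ball = np.exp(-bval * params.d)
    mu = (1.0 - params.f.sum()) * ball
    if params.n_fibres:
        c = params.stick_vectors() @ g
        mu += np.sum(params.f * np.exp(-bval * params.d * c * c))
    return float(params.S0 * mu)


def predict_signal(volumes: Dict[str, np.ndarray], gradients: GradientTable) -> np.ndarray:
    """Vectorised noiseless signal for a grid of two-stick parameter volumes.

    ``volumes`` maps the canonical parameter names to equal-shape arrays;
    returns an array of shape ``volumes shape + (n_volumes,)``.
    """
    shape = volumes["d"].shape
    d = volumes["d"][..., None]
    S0 = volumes["S0"][..., None]
    b = gradients.bvals.reshape((1,) * len(shape) + (-1,))
    g = gradients.bvecs  # (N, 3)

    mu = np.zeros(shape + (gradients.n_volumes,))
    fsum = np.zeros(shape)
    for j in (1, 2):
        f = volumes[f"f{j}"]
        v = spherical_to_unit(volumes[f"th{j}"], volumes[f"ph{j}"])  # (..., 3)
        c = np.tensordot(v, g.T, axes=([-1], [0]))  # (..., N)
        mu += f[..., None] * np.exp(-b * d * c * c)
        fsum += f
    mu += (1.0 - fsum)[..., None] * np.exp(-b * d)
    return S0 * mu


@dataclass
class ParameterGrid:
    """Ground-truth ball-and-stick parameters on a 3D grid.

    ``volumes`` maps each canonical parameter name (d, S0, f1, f2, th1, ph1,
    th2, ph2) to a 3D array of the grid shape.
    """

    volumes: Dict[str, np.ndarray]

    def __post_init__(self):
        missing = set(PARAM_NAMES) - set(self.volumes)
        if missing:
            raise ValueError(f"missing parameter volumes: {sorted(missing)}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError("parameter volumes must share one shape")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.volumes["d"].shape

    def params_at(self, i: int, j: int, k: int) -> BallStickParams:
        v = self.volumes
        return BallStickParams(
            d=float(v["d"][i, j, k]),
            S0=float(v["S0"][i, j, k]),
            f=[v["f1"][i, j, k], v["f2"][i, j, k]],
            theta=[v["th1"][i, j, k], v["th2"][i, j, k]],
            phi=[v["ph1"][i, j, k], v["ph2"][i, j, k]],
        )


@dataclass
class CompartmentSpec:
    """One tissue compartment: a box region and its ball-and-stick parameters."""

    name: str
    label: int
    region: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]
    params: BallStickParams

    def slices(self):
        return tuple(slice(lo, hi) for lo, hi in self.region)


@dataclass
class DWIDataset:
    """A 4D diffusion-weighted volume plus acquisition and truth metadata."""

    signal: np.ndarray
    gradients: GradientTable
    mask: np.ndarray
    tissue_labels: Optional[np.ndarray] = None
    truth: Optional[ParameterGrid] = None

    def __post_init__(self):
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != self.gradients.n_volumes:
            raise ValueError("signal 4th extent must equal the gradient count")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.signal.shape[:3]


def default_layout(shape) -> List[CompartmentSpec]:
    """Four-compartment quadrant layout inside a rectangular in-plane border.

    Defaults (diffusivities in mm^2/s): CSF d = 3.0e-3 with no stick; GM
    d = 0.8e-3, f1 = 0.1; single-fibre WM d = 0.9e-3, f1 = 0.7 along +x;
    crossing WM d = 0.9e-3, f1 = 0.45 along +x and f2 = 0.40 along +y
    (90 degrees apart).  S0 = 100 throughout.
    """
    nx, ny, nz = shape
    bx = max(1, round(0.1 * nx))
    by = max(1, round(0.1 * ny))
    mx = bx + (nx - 2 * bx) // 2
    my = by + (ny - 2 * by) // 2
    zs = (0, nz)
    half_pi = np.pi / 2.0
    return [
        CompartmentSpec(
            "csf", 1, ((bx, mx), (by, my), zs),
            BallStickParams(d=3.0e-3, S0=100.0),
        ),
        CompartmentSpec(
            "gm", 2, ((mx, nx - bx), (by, my), zs),
            BallStickParams(d=0.8e-3, S0=100.0, f=[0.1], theta=[half_pi], phi=[np.pi / 4]),
        ),
        CompartmentSpec(
            "wm_single", 3, ((bx, mx), (my, ny - by), zs),
            BallStickParams(d=0.9e-3, S0=100.0, f=[0.7], theta=[half_pi], phi=[0.0]),
        ),
        CompartmentSpec(
            "wm_crossing", 4, ((mx, nx - bx), (my, ny - by), zs),
            BallStickParams(
                d=0.9e-3, S0=100.0,
                f=[0.45, 0.40],
                theta=[half_pi, half_pi],
                phi=[0.0, half_pi],
            ),
        ),
    ]


def build_phantom(shape, layout: Optional[List[CompartmentSpec]] = None):
    """Assign ground-truth parameters, tissue labels and a mask on a grid.

    Returns ``(truth, tissue_labels, mask)``.  Compartment regions must not
    overlap; voxels covered by no compartment are outside the mask.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError("shape must be three positive extents")
    if layout is None:
        layout = default_layout(shape)

    labels = np.zeros(shape, dtype=np.int16)
    volumes = {name: np.zeros(shape) for name in PARAM_NAMES}
    volumes["S0"][:] = 1.0  # placeholder outside the mask; S0 must stay positive
    covered = np.zeros(shape, dtype=bool)
    for comp in layout:
        comp.params.validate()
        sl = comp.slices()
        if covered[sl].any():
            raise ValueError(f"compartment '{comp.name}' overlaps a previous one")
        covered[sl] = True
        labels[sl] = comp.label
        vec = comp.params.to_vector(n_fibres=2)
        for name, value in zip(PARAM_NAMES, vec):
            volumes[name][sl] = value

    mask = covered.copy()
    return ParameterGrid(volumes=volumes), labels, mask


def simulate_dwi(
    truth: ParameterGrid,
    gradients: GradientTable,
    noise_model: str = "rician",
    snr: float = 20.0,
    snr_profile: Optional[np.ndarray] = None,
    seed: int = 0,
    tissue_labels: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
) -> DWIDataset:
    """Simulate a noisy single-shell acquisition from a truth grid.

    Noise standard deviation per voxel is ``S0 / snr`` divided by the local
    ``snr_profile`` multiplier (profile > 1 means locally higher SNR, e.g.
    near head-coil elements).  ``gaussian`` adds zero-mean noise; ``rician``
    replaces mu by ``sqrt((mu + n1)^2 + n2^2)`` with n1, n2 iid Gaussian.
    Identical seeds yield bit-identical datasets.
    """
    if noise_model not in ("none", "gaussian", "rician"):
        raise ValueError(f"unknown noise model: {noise_model!r}")
    if noise_model != "none" and snr <= 0:
        raise ValueError("snr must be positive when noise is applied")

    signal = predict_signal(truth.volumes, gradients)
    if noise_model != "none":
        rng = np.random.default_rng(seed)
        sd = truth.volumes["S0"] / snr
        if snr_profile is not None:
            sd = sd / snr_profile
        sd = sd[..., None]
        if noise_model == "gaussian":
            signal = signal + rng.standard_normal(signal.shape) * sd
        else:
            n1 = rng.standard_normal(signal.shape) * sd
            n2 = rng.standard_normal(signal.shape) * sd
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    return DWIDataset(
        signal=signal,
        gradients=gradients,
        mask=mask,
        tissue_labels=tissue_labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk layout (FSL-style): data.nii.gz, bvals, bvecs, masks, truth volumes


def save_dataset(dataset: DWIDataset, out_dir: str) -> None:
    """Write a dataset as NIfTI volumes plus FSL-style bvals/bvecs text files."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(dataset.signal.astype(np.float64), aff),
             os.path.join(out_dir, "data.nii.gz"))
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), aff),
             os.path.join(out_dir, "nodif_brain_mask.nii.gz"))
    np.savetxt(os.path.join(out_dir, "bvals"),
               dataset.gradients.bvals[None, :], fmt="%.6g")
    np.savetxt(os.path.join(out_dir, "bvecs"),
               dataset.gradients.bvecs.T, fmt="%.10g")
    if dataset.tissue_labels is not None:
        nib.save(nib.Nifti1Image(dataset.tissue_labels.astype(np.int16), aff),
                 os.path.join(out_dir, "tissue_labels.nii.gz"))
    if dataset.truth is not None:
        for name, vol in dataset.truth.volumes.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float64), aff),
                     os.path.join(out_dir, f"truth_{name}.nii.gz"))


def load_dataset(in_dir: str) -> DWIDataset:
    """Read a dataset written by :func:`save_dataset`."""
    import nibabel as nib

    signal = np.asarray(nib.load(os.path.join(in_dir, "data.nii.gz")).dataobj)
    mask = np.asarray(
        nib.load(os.path.join(in_dir, "nodif_brain_mask.nii.gz")).dataobj
    ).astype(bool)
    bvals = np.loadtxt(os.path.join(in_dir, "bvals")).ravel()
    bvecs = np.loadtxt(os.path.join(in_dir, "bvecs"))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    gradients = GradientTable(bvals=bvals, bvecs=bvecs)

    tissue_labels = None
    labels_path = os.path.join(in_dir, "tissue_labels.nii.gz")
    if os.path.exists(labels_path):
        tissue_labels = np.asarray(nib.load(labels_path).dataobj).astype(np.int16)

    truth = None
    if os.path.exists(os.path.join(in_dir, "truth_d.nii.gz")):
        volumes = {
            name: np.asarray(
                nib.load(os.path.join(in_dir, f"truth_{name}.nii.gz")).dataobj
            ).astype(float)
            for name in PARAM_NAMES
        }
        truth = ParameterGrid(volumes=volumes)

    return DWIDataset(signal=signal, gradients=gradients, mask=mask,
                      tissue_labels=tissue_labels, truth=truth)
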