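"""Per-voxel distribution-shape comparison between two engine runs.

For each in-mask voxel and each of the six posterior distributions
(f1, f2, ph1, th1, ph2, th2), the two engines' merged sample vectors are
compared with a two-sample Kolmogorov-Smirnov test.  Significant voxels are
binned by KS statistic (S) into the ranges 0.1-0.2, 0.2-0.3, 0.3-0.4 and
>0.4, and summarised into per-range tables of posterior-mean and
initialization differences.  Family-wise error is controlled by Bonferroni
over all voxel-parameter tests by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import PDF_PARAMS
from .inference import PosteriorSamples

__all__ = [
    "S_BINS",
    "ComparisonResult",
    "ks_two_sample",
    "significance_threshold",
    "bin_s",
    "compare_all",
    "summarize_fraction_param",
    "init_difference_map",
]

#: Ordered S-range bin labels for significant tests ("none" = not binned).
S_BINS = ("0.1-0.2", "0.2-0.3", "0.3-0.4", ">0.4")

_BIN_EDGES = (0.1, 0.2, 0.3, 0.4)

#: Switch to the exact small-sample KS p-value when n*m is at most this.
_EXACT_LIMIT = 10_000


def ks_two_sample(a, b) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(S, p)`` where S is the supremum of the absolute difference
    between the two empirical CDFs and p the two-sided p-value (exact for
    small samples, asymptotic at the pooled effective size otherwise).
    S x 100% is interpretable as the percentage of deviating samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(a) * len(b) <= _EXACT_LIMIT else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_threshold(alpha: float, n_tests: int, mode: str = "bonferroni") -> float:
    """Per-test p-value threshold under the active multiple-testing rule."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    if mode == "uncorrected":
        return alpha
    if mode == "bonferroni":
        return alpha / n_tests
    raise ValueError(f"unknown correction mode: {mode!r}")


def bin_s(S: float, significant: bool) -> str:
    """S-range bin of one test: "none" unless significant with S >= 0.1."""
    if not 0 <= S <= 1:
        raise ValueError("S must lie in [0, 1]")
    if not significant or S < _BIN_EDGES[0]:
        return "none"
    for label, hi in zip(S_BINS[:3], _BIN_EDGES[1:]):
        if S < hi:
            return label
    return S_BINS[3]


@dataclass
class ComparisonResult:
    """Per-voxel KS comparison of two posterior sample sets.

    Arrays are indexed like the engines' ``voxel_index``; keys are the
    compared parameter names.
    """

    shape: Tuple[int, int, int]
    mask: np.ndarray
    voxel_index: np.ndarray
    params: Tuple[str, ...]
    S: Dict[str, np.ndarray]
    p: Dict[str, np.ndarray]
    significant: Dict[str, np.ndarray]
    s_bin: Dict[str, np.ndarray]
    alpha: float
    mode: str
    p_threshold: float
    n_tests: int

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_index)

    def n_significant(self, param: str) -> int:
        return int(self.significant[param].sum())

    def volume_from(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=values.dtype if values.dtype != bool else float)
        out[tuple(self.voxel_index.T)] = values
        return out


def compare_all(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    alpha: float = 0.05,
    mode: str = "bonferroni",
    params: Sequence[str] = PDF_PARAMS,
    thin: int = 1,
    bonferroni_scope: str = "all",
) -> ComparisonResult:
    """KS-compare every in-mask voxel and parameter between two engines.

    ``thin`` keeps every thin-th merged sample before testing (used to
    approximate independence in null-calibration checks).  With
    ``bonferroni_scope='all'`` the Bonferroni family is all
    voxels x parameters tests; ``'per_parameter'`` corrects within each
    parameter's voxel family only.
    """
    if samples_a.shape != samples_b.shape or not np.array_equal(samples_a.mask, samples_b.mask):
        raise ValueError("sample sets must cover the same mask")
    if samples_a.n_samples != samples_b.n_samples:
        raise ValueError("sample sets must have equal sample counts")
    if bonferroni_scope not in ("all", "per_parameter"):
        raise ValueError(f"unknown bonferroni scope: {bonferroni_scope!r}")

    params = tuple(params)
    n_vox = samples_a.n_voxels
    n_tests = n_vox * len(params) if bonferroni_scope == "all" else n_vox
    threshold = significance_threshold(alpha, n_tests, mode)

    S: Dict[str, np.ndarray] = {}
    P: Dict[str, np.ndarray] = {}
    sig: Dict[str, np.ndarray] = {}
    sbin: Dict[str, np.ndarray] = {}
    for p in params:
        a_all = samples_a.samples[p][:, ::thin]
        b_all = samples_b.samples[p][:, ::thin]
        s_vec = np.empty(n_vox)
        p_vec = np.empty(n_vox)
        for v in range(n_vox):
            s_vec[v], p_vec[v] = ks_two_sample(a_all[v], b_all[v])
        S[p] = s_vec
        P[p] = p_vec
        sig[p] = p_vec < threshold
        sbin[p] = np.array([bin_s(s, g) for s, g in zip(s_vec, sig[p])])

    return ComparisonResult(
        shape=samples_a.shape,
        mask=samples_a.mask.copy(),
        voxel_index=samples_a.voxel_index.copy(),
        params=params,
        S=S,
        p=P,
        significant=sig,
        s_bin=sbin,
        alpha=alpha,
        mode=mode,
        p_threshold=threshold,
        n_tests=n_vox * len(params),
    )


def _range_rows(sbin_vec: np.ndarray, sig_vec: np.ndarray):
    """Yield (label, boolean index) for the four S ranges plus 'All'."""
    for label in S_BINS:
        yield label, sbin_vec == label
    yield "All", sig_vec.astype(bool)


def summarize_fraction_param(
    result: ComparisonResult,
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    param: str,
    f2_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Per-S-range summary table for a fibre-fraction parameter.

    Columns: voxel count, mean (and sd) of engine-A posterior means, mean
    absolute difference of posterior means, and mean absolute difference of
    trial-averaged initializations.  For f2, ``f2_floor`` (default 0.05)
    restricts rows to voxels whose mean f2 in either engine reaches the
    floor, mirroring the reporting convention for secondary fibres.
    """
    if param not in result.params:
        raise ValueError(f"comparison does not cover {param!r}")
    if f2_floor is None and param == "f2":
        f2_floor = 0.05

    mean_a = samples_a.samples[param].mean(axis=1)
    mean_b = samples_b.samples[param].mean(axis=1)
    init_a = samples_a.init_values[param].mean(axis=0)
    init_b = samples_b.init_values[param].mean(axis=0)

    keep = np.ones(result.n_voxels, dtype=bool)
    if f2_floor is not None:
        keep = (mean_a >= f2_floor) | (mean_b >= f2_floor)

    rows = []
    for label, in_range in _range_rows(result.s_bin[param], result.significant[param]):
        sel = in_range & keep
        n = int(sel.sum())
        if n:
            rows.append({
                "s_range": label,
                "n_voxels": n,
                "mean_value_a": float(mean_a[sel].mean()),
                "sd_value_a": float(mean_a[sel].std(ddof=0)),
                "mean_abs_diff": float(np.abs(mean_a[sel] - mean_b[sel]).mean()),
                "mean_abs_init_diff": float(np.abs(init_a[sel] - init_b[sel]).mean()),
            })
        else:
            rows.append({
                "s_range": label, "n_voxels": 0,
                "mean_value_a": np.nan, "sd_value_a": np.nan,
                "mean_abs_diff": np.nan, "mean_abs_init_diff": np.nan,
            })
    return pd.DataFrame(rows).set_index("s_range")


def init_difference_map(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    threshold_frac: float = 0.01,
    params: Sequence[str] = None,
) -> Dict[str, np.ndarray]:
    """Signed 3D maps of trial-averaged initialization differences (A - B).

    Entries whose magnitude falls below ``threshold_frac`` times the
    magnitude of engine A's posterior mean in that voxel are zeroed
    (default 1%), mirroring thresholded difference maps.
    """
    if params is None:
        params = tuple(samples_a.init_values.keys())
    out = {}
    idx = tuple(samples_a.voxel_index.T)
    for p in params:
        diff = samples_a.init_values[p].mean(axis=0) - samples_b.init_values[p].mean(axis=0)
        ref = np.abs(samples_a.samples[p].mean(axis=1))
        diff = np.where(np.abs(diff) < threshold_frac * ref, 0.0, diff)
        vol = np.zeros(samples_a.shape)
        vol[idx] = diff
        out[p] = vol
    return out
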