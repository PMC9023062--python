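"""Tissue-class localization, whole-run roll-ups and report rendering.

Summarises where significantly different posterior distributions fall with
respect to the tissue compartments (CSF, grey matter, white matter), and
rolls the per-parameter counts up into a single headline fraction of
comparisons showing no significant difference.  Two counting conventions
are reported: the voxel-level convention, where each fibre's [phi, theta]
angle pair contributes one count per voxel (significant when either angle
is), and the strict per-distribution convention, where every one of the six
distributions counts individually.  The total number of comparisons is
always in-mask voxels x 6.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .angular import pair_significance
from .compare import ComparisonResult

__all__ = [
    "LocalizationSummary",
    "localize",
    "rollup",
    "headline_not_significant_fraction",
    "render_report",
]

_TISSUE_NAMES = {0: "outside", 1: "csf", 2: "gm", 3: "wm_single", 4: "wm_crossing"}


@dataclass
class LocalizationSummary:
    """Tissue-class breakdown of significant voxels for one test family."""

    name: str
    total_tests: int
    n_significant: int
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.total_tests if self.total_tests else 0.0

    @property
    def fractions(self) -> Dict[str, float]:
        """Per-tissue fractions of the significant set (sum to 1 when non-empty)."""
        if not self.n_significant:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_significant for k, v in self.counts.items()}


def localize(significant: np.ndarray, tissue_labels: np.ndarray,
             voxel_index: Optional[np.ndarray] = None,
             total_tests: Optional[int] = None,
             name: str = "") -> LocalizationSummary:
    """Count significant voxels per tissue class.

    ``significant`` is either a 3D boolean map or a per-voxel vector with a
    matching ``voxel_index``.  White-matter sub-classes are reported both
    separately and pooled under ``"wm"``.
    """
    significant = np.asarray(significant)
    if significant.ndim == 3:
        if significant.shape != tissue_labels.shape:
            raise ValueError("maps must share a grid")
        labels = tissue_labels[significant.astype(bool)]
        n_total = total_tests if total_tests is not None else int(np.prod(significant.shape))
    else:
        if voxel_index is None:
            raise ValueError("voxel_index required for per-voxel vectors")
        labels = tissue_labels[tuple(voxel_index.T)][significant.astype(bool)]
        n_total = total_tests if total_tests is not None else len(significant)

    counts = {v: int(np.sum(labels == k)) for k, v in _TISSUE_NAMES.items()}
    counts["wm"] = counts["wm_single"] + counts["wm_crossing"]
    return LocalizationSummary(
        name=name,
        total_tests=n_total,
        n_significant=int(len(labels)),
        counts=counts,
    )


def headline_not_significant_fraction(pair_counts: Sequence[int], n_voxels: int) -> float:
    """Fraction of comparisons with no significant difference.

    ``pair_counts`` are the per-family significant-voxel counts (f1, f2 and
    the two [phi, theta] pairs, each counted at voxel level); the
    denominator is ``n_voxels * 6`` distributions.  Pure arithmetic on
    printed counts.
    """
    total = n_voxels * 6
    return 1.0 - sum(int(c) for c in pair_counts) / total


def rollup(result: ComparisonResult) -> Dict[str, float]:
    """Whole-run significance roll-up across all six distributions.

    Returns both conventions, labelled: ``voxel_pair`` counts each fibre's
    angle pair once per voxel (the headline convention) and ``strict``
    counts every distribution.  The strict count is always >= the pair
    count.
    """
    required = {"f1", "f2", "ph1", "th1", "ph2", "th2"}
    if not required <= set(result.params):
        raise ValueError("roll-up needs all six compared parameters")

    n_vox = result.n_voxels
    total = n_vox * 6
    sig1, _, _ = pair_significance(result, 1)
    sig2, _, _ = pair_significance(result, 2)
    pair_counts = [
        result.n_significant("f1"),
        result.n_significant("f2"),
        int(sig1.sum()),
        int(sig2.sum()),
    ]
    strict_count = sum(result.n_significant(p) for p in required)
    pair_total = sum(pair_counts)
    return {
        "n_voxels": n_vox,
        "total_tests": total,
        "n_significant_voxel_pair": pair_total,
        "n_significant_strict": strict_count,
        "not_significant_fraction_voxel_pair":
            headline_not_significant_fraction(pair_counts, n_vox),
        "not_significant_fraction_strict": 1.0 - strict_count / total,
        "per_family_counts": {
            "f1": pair_counts[0],
            "f2": pair_counts[1],
            "ph1_th1_pair": pair_counts[2],
            "ph2_th2_pair": pair_counts[3],
        },
    }


def render_report(summaries: Dict[str, object], out_dir: str) -> None:
    """Write tables (CSV), a metrics JSON and a plain-text summary.

    ``summaries`` maps names to pandas DataFrames (written as
    ``table_<name>.csv``), LocalizationSummary objects, roll-up dicts or
    plain scalars (collected into ``metrics.json``).  Output ordering is
    deterministic; rendering the same summaries twice yields byte-identical
    files.
    """
    os.makedirs(out_dir, exist_ok=True)
    metrics: Dict[str, object] = {}
    lines = []

    for name in sorted(summaries):
        obj = summaries[name]
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"table_{name}.csv")
            obj.to_csv(path, float_format="%.10g")
            lines.append(f"[table] {name}: {len(obj)} rows -> {os.path.basename(path)}")
            all_row = obj.loc["All"].to_dict() if "All" in obj.index else {}
            metrics[name] = {k: (None if pd.isna(v) else v) for k, v in all_row.items()}
        elif isinstance(obj, LocalizationSummary):
            metrics[name] = {
                "total_tests": obj.total_tests,
                "n_significant": obj.n_significant,
                "fraction_significant": obj.fraction_significant,
                "counts": obj.counts,
                "fractions": obj.fractions,
            }
            pct = {k: round(100 * v) for k, v in obj.fractions.items()}
            lines.append(
                f"[localization] {name}: {obj.n_significant}/{obj.total_tests} "
                f"significant; tissue % of significant: {pct}"
            )
        elif isinstance(obj, dict):
            metrics[name] = obj
            if "not_significant_fraction_voxel_pair" in obj:
                pct = round(100 * obj["not_significant_fraction_voxel_pair"])
                lines.append(
                    f"[rollup] {name}: {obj['total_tests']} comparisons, "
                    f"{pct}% showed no significant difference "
                    f"(strict convention: "
                    f"{round(100 * obj['not_significant_fraction_strict'])}%)"
                )
            else:
                lines.append(f"[metrics] {name}")
        else:
            metrics[name] = obj
            lines.append(f"[metric] {name} = {obj}")

    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
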