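"""Segmentation evaluation: DSC, Hausdorff distance, paired comparison.

DSC(A, B) = 2|A ∩ B| / (|A| + |B|) over voxel sets, in [0, 1].
HD(A, B) = max(h(A, B), h(B, A)) with the directed distance
h(A, B) = max_{a∈A} min_{b∈B} ||a − b|| taken over *all* foreground voxel
centers in physical mm (spacing-aware), so anisotropic grids are handled
correctly. Method arms are compared case-paired: a Shapiro–Wilk test on
the paired differences (α = 0.05) selects between the paired t-test and
the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .volumes import BinaryMask, DegenerateInputError, GridMismatchError


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient between two masks on the same grid.

    Defined whenever at least one mask is non-empty; an empty prediction
    against a non-empty reference scores 0.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise DegenerateInputError("DSC of two empty masks is undefined (0/0)")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def directed_hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """h(A, B): the farthest A point's distance to its nearest B point (mm)."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError("masks must share grid and spacing")
    if a.n_foreground == 0 or b.n_foreground == 0:
        raise DegenerateInputError("directed Hausdorff needs two non-empty masks")
    pa = a.foreground_points_mm()
    pb = b.foreground_points_mm()
    dmin, _ = cKDTree(pb).query(pa, k=1)
    return float(dmin.max())


def hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A)) in mm."""
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


@dataclasses.dataclass
class PairedComparison:
    test_name: str  # "paired-t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    significant: bool
    normality_p: float


def paired_compare(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> PairedComparison:
    """Compare two paired metric samples.

    Shapiro–Wilk on the paired differences gates the test choice: normal
    differences (p > α) get the paired t-test, otherwise the Wilcoxon
    signed-rank test. Two-sided p-values; significance at p < 0.05.
    All-zero differences are flagged degenerate and no test is run.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    if np.allclose(diff, 0.0):
        return PairedComparison("degenerate", float("nan"), float("nan"), False, float("nan"))
    sw_stat, sw_p = stats.shapiro(diff)
    if sw_p > alpha:
        stat, p = stats.ttest_rel(x, y)
        name = "paired-t"
    else:
        stat, p = stats.wilcoxon(x, y)
        name = "wilcoxon"
    return PairedComparison(name, float(stat), float(p), bool(p < 0.05), float(sw_p))


@dataclasses.dataclass
class MetricsReport:
    """Per-case metric rows plus mean ± sd aggregates and comparisons.

    ``per_case`` rows are dicts with at least ``case_id`` and one or more
    metric columns (NaN marks an undefined value, e.g. HD of an empty
    prediction). ``aggregate`` maps metric name to (mean, sd, n_defined);
    sd uses the sample convention (ddof=1) and is reported as 0.0 with
    ``single_case=True`` when only one value is defined.
    """

    per_case: list
    aggregate: dict
    comparisons: dict = dataclasses.field(default_factory=dict)
    single_case: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_case)

    def to_csv(self, path: str) -> str:
        self.to_frame().to_csv(path, index=False)
        return str(path)

    def to_json(self, path: str) -> str:
        payload = {
            "aggregate": {
                k: {"mean": m, "sd": s, "n": n} for k, (m, s, n) in self.aggregate.items()
            },
            "comparisons": {
                k: dataclasses.asdict(v) for k, v in self.comparisons.items()
            },
            "single_case": self.single_case,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)
        return str(path)


def aggregate_report(per_case: Sequence[dict]) -> MetricsReport:
    """Aggregate per-case metric rows into mean ± sample-sd summaries."""
    per_case = list(per_case)
    if not per_case:
        raise ValueError("no cases to aggregate")
    frame = pd.DataFrame(per_case)
    aggregate = {}
    single = False
    for col in frame.columns:
        if col == "case_id" or not np.issubdtype(frame[col].dtype, np.number):
            continue
        vals = frame[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            aggregate[col] = (float("nan"), float("nan"), 0)
        elif vals.size == 1:
            aggregate[col] = (float(vals[0]), 0.0, 1)
            single = True
        else:
            aggregate[col] = (float(vals.mean()), float(vals.std(ddof=1)), int(vals.size))
    return MetricsReport(per_case, aggregate, single_case=single)
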