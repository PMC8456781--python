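"""Flow-cytometry activity indices, qPCR fold change and resampling statistics.

The two integrin-activity indices consume per-condition summaries of gated
per-cell intensity tables:

* fibronectin-fragment assay:  AI = (F - F_EDTA) / F_PB1
* conformation-antibody assay: IA = (F_9EG7 - F_2ndAb) / (F_P5D2 - F_2ndAb)

qPCR fold changes use the 2^-ddCt method against a reference gene (GAPDH in
the original workflow) and a control condition.  Group comparisons across
the pipeline use a label-randomization (permutation) test and a bootstrap
effect size, both with explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import as_1d_float
from .errors import ArgumentError


@dataclass
class FlowSample:
    """Gated per-cell stain intensities for one condition.

    ``intensities`` is a tidy table with one row per cell and one column per
    stain (e.g. F, F_EDTA, F_PB1 or F_9EG7, F_P5D2, F_2ndAb).
    """

    condition: str
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ArgumentError("stain intensities must be >= 0")

    def summary(self, stain: str, how: str = "mean") -> float:
        if stain not in self.intensities.columns:
            raise ArgumentError(f"stain {stain!r} missing from {self.condition!r}")
        col = self.intensities[stain].to_numpy(dtype=float)
        return float(np.median(col) if how == "median" else col.mean())


@dataclass
class CtTable:
    """qPCR Ct values per (gene, sample) with a reference gene."""

    table: pd.DataFrame  # columns: gene, sample, ct
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        required = {"gene", "sample", "ct"}
        if not required.issubset(self.table.columns):
            raise ArgumentError(f"Ct table needs columns {sorted(required)}")
        if (self.table["ct"] <= 0).any():
            raise ArgumentError("Ct values must be > 0")

    def ct(self, gene: str, sample: str) -> float:
        rows = self.table[(self.table["gene"] == gene) & (self.table["sample"] == sample)]
        if rows.empty:
            raise ArgumentError(f"missing Ct for gene={gene!r}, sample={sample!r}")
        return float(rows["ct"].mean())


def activity_index_fn(f: float, f_edta: float, f_pb1: float) -> float:
    """Fibronectin-fragment activity index AI = (F - F_EDTA) / F_PB1.

    F is the FN7-10 signal, F_EDTA the same signal after EDTA treatment
    (abolishing cation-dependent binding) and F_PB1 the total alpha-5
    integrin surface level.
    """
    if not f_pb1 > 0:
        raise ArgumentError("F_PB1 must be > 0")
    return (f - f_edta) / f_pb1


def activity_index_9eg7(f_9eg7: float, f_p5d2: float, f_2ndab: float) -> float:
    """Antibody activity index IA = (F_9EG7 - F_2ndAb) / (F_P5D2 - F_2ndAb).

    9EG7 reports the active beta-1 conformation, P5D2 total beta-1, and the
    secondary-only stain sets the background floor.
    """
    if not f_p5d2 - f_2ndab > 0:
        raise ArgumentError("total staining (F_P5D2) must exceed background (F_2ndAb)")
    return (f_9eg7 - f_2ndab) / (f_p5d2 - f_2ndab)


def relative_expression_ddct(
    ct: CtTable, gene: str, sample: str, control: str
) -> float:
    """Fold change by the 2^-ddCt method, normalized to the reference gene."""
    d_sample = ct.ct(gene, sample) - ct.ct(ct.reference_gene, sample)
    d_control = ct.ct(gene, control) - ct.ct(ct.reference_gene, control)
    return float(2.0 ** -(d_sample - d_control))


def _stat_fn(statistic: str):
    if statistic == "mean":
        return lambda v, axis=None: np.mean(v, axis=axis)
    if statistic == "median":
        return lambda v, axis=None: np.median(v, axis=axis)
    raise ArgumentError(f"unknown statistic {statistic!r}")


def randomization_test(
    group_a,
    group_b,
    n_resamples: int = 1000,
    statistic: str = "mean",
    seed: int | None = None,
    exact: bool = False,
) -> float:
    """Two-sided label-randomization test for a difference between groups.

    The observed statistic is ``stat(a) - stat(b)``; group labels are
    shuffled ``n_resamples`` times preserving group sizes, and
    ``p = (1 + #{|s*| >= |s_obs|}) / (n_resamples + 1)``.

    With ``exact=True`` all label assignments are enumerated instead and the
    unadjusted exact proportion is returned (only sensible for small n).
    """
    a = as_1d_float(group_a, "group_a", min_len=2)
    b = as_1d_float(group_b, "group_b", min_len=2)
    stat = _stat_fn(statistic)
    pooled = np.concatenate([a, b])
    n_a = a.size
    s_obs = abs(stat(a) - stat(b))

    if exact:
        count = total = 0
        for idx in combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            s = abs(stat(pooled[mask]) - stat(pooled[~mask]))
            count += s >= s_obs - 1e-12
            total += 1
        return count / total

    if n_resamples < 1:
        raise ArgumentError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.tile(pooled, (int(n_resamples), 1)), axis=1)
    s_null = np.abs(stat(mat[:, :n_a], axis=1) - stat(mat[:, n_a:], axis=1))
    return float((1 + np.sum(s_null >= s_obs - 1e-12)) / (n_resamples + 1))


def effect_size(
    group_a,
    group_b,
    n_boot: int = 1000,
    statistic: str = "mean",
    seed: int | None = None,
    ci_level: float = 95.0,
) -> tuple[float, tuple[float, float]]:
    """Difference between group statistics with a percentile bootstrap CI.

    Each bootstrap replicate resamples within each group independently.
    Returns ``(difference, (ci_low, ci_high))``.
    """
    a = as_1d_float(group_a, "group_a", min_len=2)
    b = as_1d_float(group_b, "group_b", min_len=2)
    if n_boot < 1:
        raise ArgumentError("n_boot must be >= 1")
    stat = _stat_fn(statistic)
    diff = float(stat(a) - stat(b))
    rng = np.random.default_rng(seed)
    boot_a = stat(a[rng.integers(0, a.size, (int(n_boot), a.size))], axis=1)
    boot_b = stat(b[rng.integers(0, b.size, (int(n_boot), b.size))], axis=1)
    alpha = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(boot_a - boot_b, [alpha, 100.0 - alpha])
    return diff, (float(lo), float(hi))


@dataclass
class TukeySummary:
    """Tukey boxplot summary: quartiles, 1.5*IQR whiskers and outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))


def tukey_summary(values) -> TukeySummary:
    """Tukey boxplot summary of a sample.

    Quartiles use linear interpolation (numpy's default, R type 7); whiskers
    extend to the most extreme observations within 1.5*IQR of the quartiles,
    and points beyond are flagged as outliers.
    """
    v = as_1d_float(values, "values", min_len=1)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return TukeySummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    )


def rectangular_gate(table: pd.DataFrame, limits: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Keep rows whose stain values fall inside [lo, hi] for every channel.

    A minimal gate for synthetic populations; real gating happens upstream.
    """
    keep = np.ones(len(table), dtype=bool)
    for col, (lo, hi) in limits.items():
        if col not in table.columns:
            raise ArgumentError(f"gate channel {col!r} missing")
        keep &= (table[col] >= lo) & (table[col] <= hi)
    return table[keep].reset_index(drop=True)
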