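"""Filopodia map construction: 40-bin profiles, averages, enrichment, positivity.

To compare filopodia of different lengths, each tip-to-base intensity
profile is reduced to a fixed number of bins (40) by taking the median of
the samples assigned to each bin; maps average hundreds of binned profiles
per channel/condition.  Two per-filopodium statistics follow the same
binning: the tip/shaft enrichment ratio (mean of bins 1-6 over mean of bins
7-40) and tip positivity (tip-bin average >= 5000 on the normalized
0-65535 scale).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, UndefinedRatioError
from .profiles import ProfileRecord

N_BINS = 40
TIP_BINS = slice(0, 6)      # bins 1-6, tip region (0-based slice)
SHAFT_BINS = slice(6, 40)   # bins 7-40, shaft
POSITIVITY_THRESHOLD = 5000.0  # ADU on the normalized 16-bit scale


@dataclass
class BinnedProfile:
    """A profile reduced to exactly 40 median bins; bin 1 is the tip."""

    filopodium_id: str | int
    channel: str
    bin_values: np.ndarray
    length_um: float
    upsampled: bool = False  # profile had fewer raw samples than bins

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=float).ravel()
        if self.bin_values.size != N_BINS:
            raise ArgumentError(f"binned profile must have {N_BINS} bins")


def bin_profile(record: ProfileRecord, n_bins: int = N_BINS) -> BinnedProfile:
    """Reduce a profile to ``n_bins`` median bins (tip = bin 1).

    Sample ``i`` of ``n`` is assigned to bin ``floor(i * n_bins / n)`` and
    each bin takes the median of its samples — equal-width binning of the
    sample index.  Profiles shorter than ``n_bins`` samples are first
    nearest-neighbour upsampled to ``n_bins`` and flagged.
    """
    if n_bins < 1:
        raise ArgumentError("n_bins must be >= 1")
    values = record.intensities
    n = values.size
    upsampled = False
    if n < n_bins:
        idx = np.round(np.linspace(0, n - 1, n_bins)).astype(int)
        values = values[idx]
        n = n_bins
        upsampled = True
    bins = (np.arange(n) * n_bins) // n
    out = np.empty(n_bins)
    for b in range(n_bins):
        out[b] = np.median(values[bins == b])
    if n_bins != N_BINS:
        # non-default bin counts are supported for exploration but cannot be
        # packed into the 40-bin container
        return out  # type: ignore[return-value]
    return BinnedProfile(
        filopodium_id=record.filopodium_id,
        channel=record.channel,
        bin_values=out,
        length_um=record.length_um,
        upsampled=upsampled,
    )


@dataclass
class FilopodiaMap:
    """Average binned profile per (channel, condition) group."""

    table: pd.DataFrame  # columns: group, bin (1-based), mean, n

    def row(self, group: str) -> np.ndarray:
        sub = self.table[self.table["group"] == group].sort_values("bin")
        if sub.empty:
            raise ArgumentError(f"no map row for group {group!r}")
        return sub["mean"].to_numpy()


def build_map(
    profiles: list[BinnedProfile],
    group_by: str = "channel",
) -> FilopodiaMap:
    """Average binned profiles per group into a heatmap-ready table.

    ``group_by`` is "channel" or a callable mapping a profile to a label.
    """
    if not profiles:
        raise ArgumentError("no profiles to map")
    key = (lambda p: p.channel) if group_by == "channel" else group_by
    groups: dict[str, list[np.ndarray]] = defaultdict(list)
    for p in profiles:
        groups[key(p)].append(p.bin_values)
    rows = []
    for group, vals in groups.items():
        if not vals:
            raise ArgumentError(f"empty group {group!r}")
        mean = np.mean(np.stack(vals), axis=0)
        for b in range(N_BINS):
            rows.append({"group": group, "bin": b + 1, "mean": mean[b], "n": len(vals)})
    return FilopodiaMap(table=pd.DataFrame(rows))


def enrichment_ratio(profile: BinnedProfile) -> float:
    """Tip/shaft enrichment: mean(bins 1-6) / mean(bins 7-40).

    Invariant under multiplying all intensities by a positive constant.
    Raises :class:`UndefinedRatioError` when the shaft mean is zero; callers
    should exclude such profiles and log the exclusion.
    """
    tip = float(profile.bin_values[TIP_BINS].mean())
    shaft = float(profile.bin_values[SHAFT_BINS].mean())
    if shaft == 0:
        raise UndefinedRatioError(
            f"filopodium {profile.filopodium_id!r}: shaft mean is zero"
        )
    return tip / shaft


def classify_tip_positive(
    profile: BinnedProfile,
    threshold: float = POSITIVITY_THRESHOLD,
    tip_bins: slice = TIP_BINS,
) -> bool:
    """True when the tip-bin average is at least ``threshold`` (inclusive).

    The threshold lives on the normalized 0-65535 scale, so images must be
    normalized before profile extraction for the default to be meaningful.
    """
    if not 0 <= threshold <= 65535:
        raise ArgumentError("threshold must lie in [0, 65535]")
    return bool(profile.bin_values[tip_bins].mean() >= threshold)


def percent_positive(
    profiles: list[BinnedProfile],
    threshold: float = POSITIVITY_THRESHOLD,
    tip_bins: slice = TIP_BINS,
) -> float:
    """Percentage of profiles classified tip-positive."""
    if not profiles:
        raise ArgumentError("no profiles to classify")
    flags = [classify_tip_positive(p, threshold, tip_bins) for p in profiles]
    return 100.0 * sum(flags) / len(flags)


def filopodium_length(record: ProfileRecord) -> float:
    """Filopodium length in um, read off the profile's arc positions."""
    return record.length_um


def per_filopodium_table(binned: list[BinnedProfile], threshold: float = POSITIVITY_THRESHOLD) -> pd.DataFrame:
    """Per-filopodium summary: length, enrichment ratio, tip positivity."""
    rows = []
    for p in binned:
        try:
            ratio = enrichment_ratio(p)
        except UndefinedRatioError:
            ratio = np.nan
        rows.append(
            {
                "filopodium_id": p.filopodium_id,
                "channel": p.channel,
                "length_um": p.length_um,
                "enrichment": ratio,
                "tip_positive": classify_tip_positive(p, threshold),
            }
        )
    return pd.DataFrame(rows)
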