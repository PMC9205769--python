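"""Cross-build overlay of viewpoint profiles and differential contact tracks.

Profiles from different engineered lines live on different modified genomes.
To compare them, fragment ends are shifted onto shared base-genome
coordinates (via the coordinate maps) so that common fragment ends align,
then per-fragment normalized coverage is averaged in 5-kb bins per profile
and subtracted.  The resulting differential-contact (DC) track is rendered
with the convention: |difference| < 50 normalized reads is white (no call),
50-500 is linearly color-scaled, and above 500 is saturated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_norm import NormalizedProfile

__all__ = [
    "OverlayProfile",
    "DifferentialTrack",
    "overlay",
    "differential_bins",
    "classify_colors",
]


@dataclass
class OverlayProfile:
    """Two profiles aligned on base coordinates.

    ``table`` has one row per fragment end with columns ``base_chrom``,
    ``base_cut``, ``base_mid``, ``side``, ``end_id_a``, ``end_id_b``,
    ``value_a``, ``value_b``, ``smoothed_a``, ``smoothed_b`` and ``status``
    in {shared, A_only, B_only}.  Only shared ends carry paired values.
    """

    table: pd.DataFrame
    label_a: str = "A"
    label_b: str = "B"

    def shared(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "shared"]


@dataclass
class DifferentialTrack:
    """5-kb binned mean differences (B - A) in normalized-read units.

    ``bins`` tiles the analyzed interval; bins containing no fragment end
    carry NaN (blank: no data, distinct from zero difference).
    """

    bins: pd.DataFrame
    bin_size: int
    label: str = "DC"


def overlay(
    norm_a: NormalizedProfile,
    norm_b: NormalizedProfile,
    common_ends: pd.DataFrame,
) -> OverlayProfile:
    """Align two normalized (and optionally smoothed) profiles on base
    coordinates using a common-end table from ``match_common_ends``.

    Ends marked common in the table but absent from a profile (e.g. dropped
    as blind) are ignored; build-specific ends present in a profile are
    carried with the other side's value missing.
    """
    rows = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for rec in common_ends.itertuples(index=False):
        if rec.status == "common":
            ida, idb = rec.end_id_a, rec.end_id_b
            if ida in norm_a.values and idb in norm_b.values:
                seen_a.add(ida)
                seen_b.add(idb)
                rows.append(
                    {
                        "base_chrom": rec.base_chrom,
                        "base_cut": rec.base_cut,
                        "base_mid": rec.base_mid,
                        "side": rec.side,
                        "end_id_a": ida,
                        "end_id_b": idb,
                        "value_a": norm_a.values[ida],
                        "value_b": norm_b.values[idb],
                        "smoothed_a": norm_a.smoothed.get(ida, np.nan),
                        "smoothed_b": norm_b.smoothed.get(idb, np.nan),
                        "status": "shared",
                    }
                )
        elif rec.status == "A_only" and rec.end_id_a in norm_a.values:
            seen_a.add(rec.end_id_a)
            rows.append(
                {
                    "base_chrom": rec.base_chrom,
                    "base_cut": rec.base_cut,
                    "base_mid": rec.base_mid,
                    "side": rec.side,
                    "end_id_a": rec.end_id_a,
                    "end_id_b": None,
                    "value_a": norm_a.values[rec.end_id_a],
                    "value_b": np.nan,
                    "smoothed_a": norm_a.smoothed.get(rec.end_id_a, np.nan),
                    "smoothed_b": np.nan,
                    "status": "A_only",
                }
            )
        elif rec.status == "B_only" and rec.end_id_b in norm_b.values:
            seen_b.add(rec.end_id_b)
            rows.append(
                {
                    "base_chrom": rec.base_chrom,
                    "base_cut": rec.base_cut,
                    "base_mid": rec.base_mid,
                    "side": rec.side,
                    "end_id_a": None,
                    "end_id_b": rec.end_id_b,
                    "value_a": np.nan,
                    "value_b": norm_b.values[rec.end_id_b],
                    "smoothed_a": np.nan,
                    "smoothed_b": norm_b.smoothed.get(rec.end_id_b, np.nan),
                    "status": "B_only",
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "base_chrom", "base_cut", "base_mid", "side", "end_id_a", "end_id_b",
            "value_a", "value_b", "smoothed_a", "smoothed_b", "status",
        ],
    )
    if not (table["status"] == "shared").any():
        raise ValueError("profiles share no common fragment ends; nothing to overlay")
    table = table.sort_values(["base_chrom", "base_cut", "side"], na_position="last", kind="stable")
    return OverlayProfile(table.reset_index(drop=True))


def differential_bins(
    ovl: OverlayProfile, bin_size: int = 5000, chrom: str | None = None
) -> DifferentialTrack:
    """Average normalized (unsmoothed) coverage per profile in fixed bins and
    subtract (B - A).

    The bin grid is anchored at chromosome coordinate 0; a fragment end
    belongs to the bin containing the midpoint of its end region.  Only
    shared ends contribute.  The track covers one chromosome (typically the
    viewpoint chromosome); ``chrom`` may be omitted when the overlay spans a
    single chromosome.  The returned bins tile the interval from the first
    to the last occupied bin; empty bins carry NaN.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    shared = ovl.shared()
    chroms = shared["base_chrom"].unique()
    if chrom is None:
        if len(chroms) != 1:
            raise ValueError(
                "overlay spans several chromosomes "
                f"({list(chroms)}); pass chrom= to select the track chromosome"
            )
        chrom = chroms[0]
    elif chrom not in set(chroms):
        raise ValueError(f"chromosome {chrom!r} absent from the overlay")
    shared = shared[shared["base_chrom"] == chrom]
    mids = shared["base_mid"].to_numpy(dtype=float)
    idx = np.floor(mids / bin_size).astype(int)
    lo, hi = idx.min(), idx.max()
    n_bins = hi - lo + 1
    sum_a = np.zeros(n_bins)
    sum_b = np.zeros(n_bins)
    n = np.zeros(n_bins, dtype=int)
    np.add.at(sum_a, idx - lo, shared["value_a"].to_numpy(dtype=float))
    np.add.at(sum_b, idx - lo, shared["value_b"].to_numpy(dtype=float))
    np.add.at(n, idx - lo, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.where(n > 0, sum_a / np.maximum(n, 1), np.nan)
        mean_b = np.where(n > 0, sum_b / np.maximum(n, 1), np.nan)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": (np.arange(lo, hi + 1)) * bin_size,
            "end": (np.arange(lo, hi + 1) + 1) * bin_size,
            "n_ends": n,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "difference": mean_b - mean_a,
        }
    )
    return DifferentialTrack(bins=bins, bin_size=bin_size)


def classify_colors(
    track: DifferentialTrack, lo: float = 50.0, hi: float = 500.0
) -> DifferentialTrack:
    """Attach the color classification to a differential track.

    |d| < lo is white; lo <= |d| <= hi is color-scaled with linear intensity
    (|d| - lo)/(hi - lo); |d| > hi is saturated (intensity 1).  The sign of
    the difference gives the direction: gained (B over A) or lost.
    """
    if lo >= hi:
        raise ValueError(f"color thresholds must satisfy lo < hi, got lo={lo}, hi={hi}")
    d = track.bins["difference"].to_numpy(dtype=float)
    absd = np.abs(d)
    color_class = np.full(len(d), "white", dtype=object)
    color_class[np.isnan(d)] = "blank"
    color_class[(absd >= lo) & (absd <= hi)] = "scaled"
    color_class[absd > hi] = "saturated"
    intensity = np.clip((absd - lo) / (hi - lo), 0.0, 1.0)
    intensity[np.isnan(d) | (absd < lo)] = 0.0
    direction = np.full(len(d), "none", dtype=object)
    direction[(absd >= lo) & (d > 0)] = "gained"
    direction[(absd >= lo) & (d < 0)] = "lost"
    bins = track.bins.copy()
    bins["color_class"] = color_class
    bins["intensity"] = intensity
    bins["direction"] = direction
    return DifferentialTrack(bins=bins, bin_size=track.bin_size, label=track.label)
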