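"""Normalization and smoothing of viewpoint contact profiles.

A 4C-seq experiment counts ligation events between one viewpoint fragment
and every other fragment end.  Raw counts are made comparable between
experiments by scaling to one million intra-chromosomal (cis) reads, with
the two highest-covered fragments — in practice the over-captured fragments
immediately at the viewpoint — excluded from the denominator.  Profiles are
then smoothed with a 21-fragment-end rolling mean for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_builder import FragmentEndMap

__all__ = [
    "Viewpoint",
    "ContactProfile",
    "NormalizedProfile",
    "drop_blind",
    "normalize",
    "rolling_mean",
    "cis_fraction",
]


@dataclass(frozen=True)
class Viewpoint:
    chrom: str
    position: int
    label: str = "VP"


@dataclass
class ContactProfile:
    """Raw reads per fragment end for one viewpoint."""

    viewpoint: Viewpoint
    counts: dict[str, int]
    genome_build: str = ""

    def __post_init__(self) -> None:
        for end_id, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for fragment end {end_id!r}")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class NormalizedProfile:
    """Coverage per fragment end in reads per one million cis reads.

    ``excluded_fragments`` are the two fragments omitted from the
    normalization denominator; their ends are still carried in ``values``
    (scaled by the same factor) so they remain plottable.
    """

    viewpoint: Viewpoint
    values: dict[str, float]
    excluded_fragments: tuple[str, ...]
    cis_read_total: int
    trans_read_total: int
    scale_factor: float
    normalization_total: float = 1_000_000.0
    genome_build: str = ""
    smoothed: dict[str, float] = field(default_factory=dict)


def drop_blind(profile: ContactProfile, fragmap: FragmentEndMap) -> ContactProfile:
    """Remove blind fragment ends from a profile; other counts untouched."""
    counts = {
        end_id: c
        for end_id, c in profile.counts.items()
        if end_id in fragmap and not fragmap[end_id].blind
    }
    return ContactProfile(profile.viewpoint, counts, genome_build=profile.genome_build)


def cis_fraction(profile: ContactProfile, fragmap: FragmentEndMap) -> tuple[int, int, float]:
    """Split reads into cis (viewpoint chromosome) and trans and return
    ``(cis_reads, trans_reads, percent_cis)``."""
    cis = 0
    trans = 0
    for end_id, c in profile.counts.items():
        if fragmap[end_id].chrom == profile.viewpoint.chrom:
            cis += c
        else:
            trans += c
    total = cis + trans
    if total == 0:
        raise ValueError("profile has zero total reads")
    return cis, trans, 100.0 * cis / total


def normalize(
    profile: ContactProfile,
    fragmap: FragmentEndMap,
    scale_to: float = 1_000_000.0,
    n_exclude: int = 2,
) -> NormalizedProfile:
    """Scale a profile to ``scale_to`` cis reads, excluding the
    ``n_exclude`` highest-covered cis fragments from the denominator.

    Coverage is summed per primary fragment (both ends); the two top
    fragments are dropped from the denominator only — their ends remain in
    the output, multiplied by the same scale factor.  Ties on coverage are
    broken by ascending genomic coordinate.
    """
    vp_chrom = profile.viewpoint.chrom
    frag_cov: dict[str, int] = {}
    frag_start: dict[str, int] = {}
    cis_total = 0
    trans_total = 0
    for end_id, c in profile.counts.items():
        end = fragmap[end_id]
        if end.chrom == vp_chrom:
            cis_total += c
            frag_cov[end.fragment_id] = frag_cov.get(end.fragment_id, 0) + c
            frag_start[end.fragment_id] = end.fragment_start
        else:
            trans_total += c

    if len(frag_cov) < n_exclude + 1:
        raise ValueError(
            f"need at least {n_exclude + 1} cis fragments to normalize, "
            f"got {len(frag_cov)}"
        )
    ranked = sorted(frag_cov, key=lambda f: (-frag_cov[f], frag_start[f]))
    excluded = tuple(ranked[:n_exclude])
    denom = cis_total - sum(frag_cov[f] for f in excluded)
    if denom <= 0:
        raise ValueError("empty profile: no cis reads outside the excluded fragments")
    factor = scale_to / denom
    values = {end_id: c * factor for end_id, c in profile.counts.items()}
    return NormalizedProfile(
        viewpoint=profile.viewpoint,
        values=values,
        excluded_fragments=excluded,
        cis_read_total=cis_total,
        trans_read_total=trans_total,
        scale_factor=factor,
        normalization_total=scale_to,
        genome_build=profile.genome_build,
    )


def rolling_mean(
    norm: NormalizedProfile, fragmap: FragmentEndMap, k: int = 21
) -> NormalizedProfile:
    """Fill ``smoothed`` with a k-fragment-end centered rolling mean.

    The window runs over the profile's retained ends in genomic order, is
    truncated at chromosome boundaries (never crossing chromosomes) and
    shrinks symmetrically-as-available near edges, so every end receives a
    score.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"window k must be odd and >= 1, got {k}")
    ends = sorted(
        (fragmap[end_id] for end_id in norm.values),
        key=lambda e: (e.chrom, e.end_start, e.side),
    )
    smoothed: dict[str, float] = {}
    df = pd.DataFrame(
        {
            "chrom": [e.chrom for e in ends],
            "end_id": [e.end_id for e in ends],
            "value": [norm.values[e.end_id] for e in ends],
        }
    )
    for _, grp in df.groupby("chrom", sort=False):
        sm = grp["value"].rolling(window=k, center=True, min_periods=1).mean()
        smoothed.update(dict(zip(grp["end_id"], sm)))
    out = NormalizedProfile(
        viewpoint=norm.viewpoint,
        values=dict(norm.values),
        excluded_fragments=norm.excluded_fragments,
        cis_read_total=norm.cis_read_total,
        trans_read_total=norm.trans_read_total,
        scale_factor=norm.scale_factor,
        normalization_total=norm.normalization_total,
        genome_build=norm.genome_build,
        smoothed=smoothed,
    )
    return out
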