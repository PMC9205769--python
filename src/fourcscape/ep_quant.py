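"""Enhancer-promoter contact quantification.

From a normalized viewpoint profile (viewpoint at the reporter gene
promoter), E-P contact frequency is the mean normalized coverage over the
fragment ends overlapping the enhancer insert — restricted to ends that are
non-blind and uniquely mappable in every compared build — and, equivalently
in relative units, the percentage of intra-chromosomal 4C contacts captured
by those ends.  Joining these quantifications with expression readouts
across integration distances yields the distance / contact / expression
relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome_builder import FragmentEndMap
from .profile_norm import NormalizedProfile

__all__ = [
    "EnhancerEndSet",
    "EPQuantification",
    "quantify_ep",
    "distance_response_table",
]


@dataclass(frozen=True)
class EnhancerEndSet:
    """Fragment ends designated as enhancer-overlapping.

    Construction validates that every end is non-blind and uniquely mappable
    in all provided builds; the set is an explicit input so the number of
    usable enhancer ends stays a property of the genomes, never a constant.
    """

    end_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.end_ids:
            raise ValueError("enhancer end set is empty")

    @classmethod
    def from_ids(
        cls, end_ids: Iterable[str], fragmaps: Sequence[FragmentEndMap]
    ) -> "EnhancerEndSet":
        ids = tuple(end_ids)
        for end_id in ids:
            for fm in fragmaps:
                if end_id not in fm:
                    raise KeyError(f"fragment end {end_id!r} missing from build {fm.build_label!r}")
                e = fm[end_id]
                if e.blind:
                    raise ValueError(f"fragment end {end_id!r} is blind in {fm.build_label!r}")
                if not e.unique:
                    raise ValueError(
                        f"fragment end {end_id!r} is not uniquely mappable in {fm.build_label!r}"
                    )
        return cls(ids)

    @classmethod
    def from_interval(
        cls,
        fragmap: FragmentEndMap,
        chrom: str,
        start: int,
        end: int,
        extra_fragmaps: Sequence[FragmentEndMap] = (),
    ) -> "EnhancerEndSet":
        """Select the non-blind, unique ends whose end region overlaps
        [start, end) on ``chrom`` (typically the enhancer insert interval)."""
        ids = [
            e.end_id
            for e in fragmap.ends
            if e.chrom == chrom
            and not e.blind
            and e.unique
            and e.end_start < end
            and e.end_end > start
        ]
        keep = []
        for end_id in ids:
            ok = True
            for fm in extra_fragmaps:
                if end_id not in fm or fm[end_id].blind or not fm[end_id].unique:
                    ok = False
                    break
            if ok:
                keep.append(end_id)
        if not keep:
            raise ValueError(
                f"no usable enhancer fragment ends overlap {chrom}:{start}-{end}"
            )
        return cls(tuple(keep))

    def __len__(self) -> int:
        return len(self.end_ids)


@dataclass
class EPQuantification:
    """E-P contact readout for one scenario/condition.

    ``mean_signal`` is in reads per one million cis reads (the unit of the
    normalized profile); ``percent_of_cis`` expresses the same contacts as a
    percentage of intra-chromosomal 4C reads.
    """

    mean_signal: float
    percent_of_cis: float
    ep_distance_kb: float | None = None
    condition_label: str = "untreated"
    scenario: str = ""

    def __post_init__(self) -> None:
        if self.mean_signal < 0:
            raise ValueError("mean_signal must be non-negative")
        if not 0.0 <= self.percent_of_cis <= 100.0:
            raise ValueError("percent_of_cis must lie in [0, 100]")


def quantify_ep(
    norm: NormalizedProfile,
    ends: EnhancerEndSet,
    ep_distance_kb: float | None = None,
    condition_label: str = "untreated",
    scenario: str = "",
) -> EPQuantification:
    """Mean normalized (unsmoothed) coverage over the enhancer end set and
    the corresponding percentage of cis contacts."""
    values = []
    for end_id in ends.end_ids:
        if end_id not in norm.values:
            raise KeyError(f"enhancer fragment end {end_id!r} missing from the profile")
        values.append(norm.values[end_id])
    mean_signal = sum(values) / len(values)
    percent = 100.0 * sum(values) / norm.normalization_total
    return EPQuantification(
        mean_signal=mean_signal,
        percent_of_cis=min(percent, 100.0),
        ep_distance_kb=ep_distance_kb,
        condition_label=condition_label,
        scenario=scenario,
    )


def distance_response_table(
    quants: Sequence[EPQuantification],
    expression: Sequence[tuple[str, str, float]],
) -> pd.DataFrame:
    """Join contact quantifications with expression readouts.

    ``expression`` rows are ``(scenario, condition, median_FI)``.  Returns
    one row per (scenario, condition) with distance, mean signal, percent of
    cis contacts and median fluorescence, sorted by distance — the three
    pairwise projections (expression vs distance, contacts vs distance,
    expression vs contacts) read straight off this table.
    """
    qdf = pd.DataFrame(
        {
            "scenario": [q.scenario for q in quants],
            "condition": [q.condition_label for q in quants],
            "ep_distance_kb": [q.ep_distance_kb for q in quants],
            "mean_signal": [q.mean_signal for q in quants],
            "percent_of_cis": [q.percent_of_cis for q in quants],
        }
    )
    edf = pd.DataFrame(expression, columns=["scenario", "condition", "median_FI"])
    merged = qdf.merge(edf, on=["scenario", "condition"], how="left")
    if merged["median_FI"].isna().any():
        missing = merged.loc[merged["median_FI"].isna(), ["scenario", "condition"]]
        pairs = [tuple(r) for r in missing.itertuples(index=False)]
        raise ValueError(f"no expression entry for: {pairs}")
    return merged.sort_values(
        ["ep_distance_kb", "scenario", "condition"], kind="stable"
    ).reset_index(drop=True)
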