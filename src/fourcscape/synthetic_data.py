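"""Synthetic genomes, 4C contact profiles and FACS samples.

Real 4C-seq viewpoint profiles decay with genomic distance roughly as a
power law, are dominated by over-captured fragments immediately at the
viewpoint (self-ligation and undigested products), gain coverage across an
enhancer-induced contact domain, and show focal peaks at CTCF-anchored loop
positions.  This module generates fragment-end count profiles with exactly
that structure — multiplicative weights per fragment end, multinomial read
sampling — plus log-normal FACS intensity mixtures of silenced vs active
cells, so the whole pipeline can be exercised end-to-end without any
sequencing data.

Generative model per retained cis fragment end at position x (end-region
midpoint), viewpoint at v:

    w(x) = (|x - v| + d0)^(-alpha)                      distance decay
           * gamma     if x inside a domain interval    domain gain
           * prod_a (1 + beta * exp(-(x-a)^2/(2*sigma^2)))   loop anchors
           * kappa     if x on a viewpoint-adjacent fragment  over-capture

    counts ~ Multinomial(n_cis_reads, w / sum w)

Trans reads are spread uniformly over trans fragment ends.  All randomness
is driven by the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .assay_quant import FACSSample
from .genome_builder import FragmentEndMap, Genome
from .profile_norm import ContactProfile, Viewpoint

__all__ = [
    "SimulationScenario",
    "FACSScenario",
    "make_toy_genome",
    "simulate_4c",
    "simulate_facs",
    "preset_scenarios",
    "make_landscape_genome",
    "without_domain_gain",
    "SCENARIO_DISTANCES_KB",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic 4C experiment.

    Distances/positions in bp.  ``domain_intervals`` are (start, end, gain)
    triples; ``loop_anchors`` are (position, amplitude, width) triples
    modelling CTCF binding sites.  The over-capture multiplier ``kappa``
    applies to the (at most two) fragments nearest the viewpoint within
    ``capture_radius``, emulating self-ligation/undigested products and
    guaranteeing that the top-covered fragments are viewpoint-adjacent.
    """

    chrom: str
    chrom_length: int
    viewpoint_position: int
    decay_exponent: float = 1.0
    decay_offset: float = 1000.0
    domain_intervals: tuple[tuple[int, int, float], ...] = ()
    loop_anchors: tuple[tuple[int, float, float], ...] = ()
    viewpoint_capture_multiplier: float = 1000.0
    capture_radius: int = 1000
    n_cis_reads: int = 1_000_000
    trans_fraction: float = 0.3
    seed: int = 0
    label: str = ""
    enhancer_interval: tuple[int, int] | None = None
    ep_distance_kb: float | None = None
    condition: str = "untreated"

    def __post_init__(self) -> None:
        if self.decay_exponent < 0:
            raise ValueError("decay exponent must be >= 0")
        if self.decay_offset <= 0:
            raise ValueError("decay offset must be positive")
        if not 0 <= self.viewpoint_position < self.chrom_length:
            raise ValueError("viewpoint outside chromosome")
        if not 0.0 <= self.trans_fraction < 1.0:
            raise ValueError("trans fraction must lie in [0, 1)")
        if self.viewpoint_capture_multiplier < 0:
            raise ValueError("capture multiplier must be >= 0")
        for s, e, g in self.domain_intervals:
            if g < 0:
                raise ValueError("domain gain must be >= 0")
            if not (0 <= s <= e <= self.chrom_length):
                raise ValueError(f"domain interval ({s}, {e}) outside chromosome")
        for _, b, w in self.loop_anchors:
            if b < 0 or w <= 0:
                raise ValueError("loop anchors need amplitude >= 0 and width > 0")


@dataclass(frozen=True)
class FACSScenario:
    """Log-normal mixture of silenced (negative-mode) and active
    (positive-mode) cells; hemin multiplies active-cell intensities."""

    n_cells: int = 100_000
    silenced_fraction: float = 0.0
    negative_logmean: float = math.log(100.0)
    negative_logsd: float = 0.5
    positive_logmean: float = math.log(5000.0)
    positive_logsd: float = 0.6
    hemin_factor: float = 4.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.silenced_fraction <= 1.0:
            raise ValueError("silenced fraction must lie in [0, 1]")
        if self.hemin_factor < 1.0:
            raise ValueError("hemin factor must be >= 1")
        if self.positive_logmean <= self.negative_logmean:
            raise ValueError("positive mode must sit above the negative mode")


def _scrub_motifs(seq: np.ndarray, motifs: Sequence[str], rng: np.random.Generator) -> None:
    """Mutate bases until no motif (or its reverse complement) occurs.

    Works in place on a byte array; at toy scale a handful of passes
    suffice because each mutation destroys one occurrence.
    """
    from .genome_builder import reverse_complement

    patterns = set()
    for m in motifs:
        patterns.add(m.upper())
        patterns.add(reverse_complement(m.upper()))
    for _ in range(200):
        text = seq.tobytes().decode()
        hits = []
        for p in patterns:
            i = text.find(p)
            while i != -1:
                hits.append((i, len(p)))
                i = text.find(p, i + 1)
        if not hits:
            return
        for start, length in hits:
            j = start + length // 2
            current = text[j]
            choices = [b for b in "ACGT" if b != current]
            seq[j] = choices[rng.integers(len(choices))].encode()
    raise RuntimeError("failed to scrub cutter motifs from background sequence")


def make_toy_genome(
    length: int,
    motif_spacing_first: int = 1000,
    motif_spacing_second: int = 300,
    seed: int = 0,
    first_motif: str = "GTAC",
    second_motif: str = "CATG",
    chrom_name: str = "chrS",
    build_label: str = "toy",
) -> Genome:
    """Random genome with cutter motifs planted at jittered spacings.

    The background is scrubbed of accidental motif occurrences, so after
    digestion the primary fragment count is approximately
    length / motif_spacing_first.  Deterministic given the seed.
    """
    if length < len(first_motif) or length < len(second_motif):
        raise ValueError(f"genome length {length} shorter than a cutter motif")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    _scrub_motifs(seq, [first_motif, second_motif], rng)

    occupied: list[tuple[int, int]] = []

    def plant(motif: str, spacing: int) -> None:
        if spacing >= length:
            return
        motif_b = np.frombuffer(motif.upper().encode(), dtype="S1")
        pos = spacing
        while pos + len(motif) < length:
            jitter = int(rng.integers(-spacing // 5, spacing // 5 + 1))
            p = pos + jitter
            if 0 <= p and p + len(motif) < length:
                if all(p + len(motif) <= s or p >= e for s, e in occupied):
                    seq[p:p + len(motif)] = motif_b
                    occupied.append((p, p + len(motif)))
            pos += spacing
    plant(first_motif, motif_spacing_first)
    plant(second_motif, motif_spacing_second)
    return Genome({chrom_name: seq.tobytes().decode()}, build_label=build_label)


def _capture_fragments(
    fragmap: FragmentEndMap, chrom: str, vp: int, radius: int
) -> set[str]:
    """Fragment ids of the (at most two) primary fragments nearest the
    viewpoint within the capture radius."""
    frags: dict[str, tuple[int, int]] = {}
    for e in fragmap.ends:
        if e.chrom == chrom:
            frags[e.fragment_id] = (e.fragment_start, e.fragment_end)
    dists = []
    for fid, (fs, fe) in frags.items():
        if fs <= vp < fe:
            d = 0
        elif vp < fs:
            d = fs - vp
        else:
            d = vp - fe + 1
        if d <= radius:
            dists.append((d, fs, fid))
    dists.sort()
    return {fid for _, _, fid in dists[:2]}


def simulate_4c(fragmap: FragmentEndMap, scenario: SimulationScenario) -> ContactProfile:
    """Draw a raw contact profile for one viewpoint under a scenario.

    Cis reads are multinomial over the retained (non-blind) cis fragment
    ends with the scenario's weight model; trans reads are uniform over
    retained trans ends.  Blind ends are carried with zero counts.  The
    cis read total equals ``n_cis_reads`` exactly for every seed.
    """
    if scenario.chrom not in {e.chrom for e in fragmap.ends}:
        raise ValueError(f"viewpoint chromosome {scenario.chrom!r} not in fragment map")
    rng = np.random.default_rng(scenario.seed)
    vp = scenario.viewpoint_position
    retained = fragmap.non_blind()
    cis_ends = [e for e in retained if e.chrom == scenario.chrom]
    trans_ends = [e for e in retained if e.chrom != scenario.chrom]
    if not cis_ends:
        raise ValueError("no retained cis fragment ends to simulate")

    capture = _capture_fragments(fragmap, scenario.chrom, vp, scenario.capture_radius)
    x = np.array([e.midpoint for e in cis_ends])
    w = (np.abs(x - vp) + scenario.decay_offset) ** (-scenario.decay_exponent)
    for s, e_, g in scenario.domain_intervals:
        w[(x >= s) & (x < e_)] *= g
    for a, beta, sigma in scenario.loop_anchors:
        w *= 1.0 + beta * np.exp(-((x - a) ** 2) / (2.0 * sigma**2))
    kappa_mask = np.array([e.fragment_id in capture for e in cis_ends])
    w[kappa_mask] *= scenario.viewpoint_capture_multiplier
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("all fragment-end weights are zero; nothing to sample")

    cis_counts = rng.multinomial(scenario.n_cis_reads, w / total_w)
    counts: dict[str, int] = {e.end_id: 0 for e in fragmap.ends}
    for e, c in zip(cis_ends, cis_counts):
        counts[e.end_id] = int(c)

    if trans_ends and scenario.trans_fraction > 0:
        n_trans = int(round(
            scenario.n_cis_reads * scenario.trans_fraction / (1.0 - scenario.trans_fraction)
        ))
        if n_trans > 0:
            p = np.full(len(trans_ends), 1.0 / len(trans_ends))
            trans_counts = rng.multinomial(n_trans, p)
            for e, c in zip(trans_ends, trans_counts):
                counts[e.end_id] = int(c)

    return ContactProfile(
        viewpoint=Viewpoint(scenario.chrom, vp, label="VP"),
        counts=counts,
        genome_build=fragmap.build_label,
    )


def simulate_facs(scenario: FACSScenario, hemin: bool = False) -> FACSSample:
    """Draw a per-cell fluorescence sample from the scenario's mixture.

    Silenced cells come from the negative mode and active cells from the
    positive mode; with ``hemin=True`` the active-cell intensities are
    multiplied by the hemin factor (a deterministic transform of the same
    draws)."""
    rng = np.random.default_rng(scenario.seed)
    silenced = rng.random(scenario.n_cells) < scenario.silenced_fraction
    fi = np.where(
        silenced,
        rng.lognormal(scenario.negative_logmean, scenario.negative_logsd, scenario.n_cells),
        rng.lognormal(scenario.positive_logmean, scenario.positive_logsd, scenario.n_cells),
    )
    if hemin:
        fi = np.where(silenced, fi, fi * scenario.hemin_factor)
    label = scenario.label + ("+hemin" if hemin else "")
    return FACSSample(intensities=fi, label=label)


# ---------------------------------------------------------------------------
# presets


SCENARIO_DISTANCES_KB: dict[str, float] = {
    "E0": 0.0, "E11": 11.0, "E47": 47.0, "E100": 100.0, "E407": 407.0,
}

_CHROM = "chr18s"
_CHROM_LENGTH = 600_000
_VIEWPOINT = 500_000
_ENHANCER_SPAN = 6_500  # compact LCR-sized enhancer cassette


def preset_scenarios(
    seed: int = 0,
    n_cis_reads: int = 1_000_000,
    domain_gain: float = 2.0,
    loop_amplitude: float = 5.0,
    loop_width: float = 2_500.0,
) -> list[SimulationScenario]:
    """Preset scenarios for the engineered-landscape designs.

    A 600-kb inactive chromosomal segment carries the reporter-gene
    viewpoint at 500 kb, with enhancer integrations 0/11/47/100/407 kb
    upstream.  Each enhancer scenario gains contacts (``domain_gain``)
    across the enhancer-to-viewpoint domain; the CTCF-cassette (EC)
    variants add loop-anchor peaks flanking the domain.  The enhancer-less
    ``noE`` control shares the decay model and seed, so enhancer/noE pairs
    differ only by the induced structure.
    """
    base = dict(
        chrom=_CHROM,
        chrom_length=_CHROM_LENGTH,
        viewpoint_position=_VIEWPOINT,
        n_cis_reads=n_cis_reads,
        seed=seed,
    )
    scenarios = [SimulationScenario(label="noE", **base)]
    for variant in ("E", "EC"):
        for name, dist_kb in SCENARIO_DISTANCES_KB.items():
            dist = int(dist_kb * 1000)
            enh_end = _VIEWPOINT - dist
            enh_start = enh_end - _ENHANCER_SPAN
            domain = (enh_start, _VIEWPOINT, domain_gain)
            anchors: tuple[tuple[int, float, float], ...] = ()
            if variant == "EC":
                anchors = (
                    (enh_start - 2_000, loop_amplitude, loop_width),
                    (_VIEWPOINT + 5_000, loop_amplitude, loop_width),
                )
            scenarios.append(
                SimulationScenario(
                    label=variant + name[1:],
                    domain_intervals=(domain,),
                    loop_anchors=anchors,
                    enhancer_interval=(enh_start, enh_end),
                    ep_distance_kb=dist_kb,
                    **base,
                )
            )
    return scenarios


def make_landscape_genome(
    seed: int = 0,
    trans_length: int = 60_000,
    motif_spacing_first: int = 1000,
    motif_spacing_second: int = 300,
) -> Genome:
    """Toy genome matching the preset scenarios: the 600-kb engineered
    segment plus a small trans chromosome that receives the
    inter-chromosomal read fraction."""
    cis = make_toy_genome(
        _CHROM_LENGTH,
        motif_spacing_first=motif_spacing_first,
        motif_spacing_second=motif_spacing_second,
        seed=seed,
        chrom_name=_CHROM,
        build_label=f"landscape-seed{seed}",
    )
    trans = make_toy_genome(
        trans_length,
        motif_spacing_first=motif_spacing_first,
        motif_spacing_second=motif_spacing_second,
        seed=seed + 104729,
        chrom_name="chrT",
    )
    return Genome(
        {**cis.sequences, **trans.sequences}, build_label=cis.build_label
    )


def without_domain_gain(scenario: SimulationScenario) -> SimulationScenario:
    """Pure-decay variant: domain gains and loop amplitudes neutralized
    (gamma = 1, beta = 0), everything else unchanged."""
    return replace(
        scenario,
        domain_intervals=tuple((s, e, 1.0) for s, e, _ in scenario.domain_intervals),
        loop_anchors=tuple((a, 0.0, w) for a, _, w in scenario.loop_anchors),
    )
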