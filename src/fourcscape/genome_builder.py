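"""Modified genomes, coordinate maps and in-silico restriction digestion.

Engineered cell lines carry transgene cassettes (enhancers, reporters, CTCF
cassettes) integrated into a reference genome.  Analysing 4C-seq data from
such lines requires a *modified* reference that contains the inserts at their
validated coordinates, together with a bidirectional coordinate map back to
the unmodified base build so that profiles from different engineered lines
can be overlaid on shared coordinates.

This module builds those modified genomes, performs the two-cutter in-silico
digestion that defines 4C fragment ends (a primary/first cutter partitions
the chromosome into fragments; the secondary cutter defines the mappable
"end" region on each side of a fragment), and matches fragment ends between
builds.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "Genome",
    "InsertionEvent",
    "Block",
    "CoordinateMap",
    "FragmentEnd",
    "FragmentEndMap",
    "build_modified_genome",
    "identity_map",
    "project",
    "digest",
    "flag_unique_ends",
    "match_common_ends",
    "reverse_complement",
]

_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of chromosome sequences with a build label.

    Sequences are plain upper-case strings over the alphabet {A, C, G, T, N}.
    """

    sequences: dict[str, str]
    build_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class InsertionEvent:
    """One insertion into a base genome.

    ``position`` is a 0-based base-genome coordinate; the insert sequence is
    placed immediately *before* the base at that position (``position`` equal
    to the chromosome length appends at the 3' end).
    """

    chrom: str
    position: int
    insert_seq: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.insert_seq:
            raise ValueError(f"insertion {self.label!r}: insert_seq is empty")
        if self.position < 0:
            raise ValueError(f"insertion {self.label!r}: negative position")


@dataclass(frozen=True)
class Block:
    """One block of a coordinate map.

    ``collinear`` blocks cover identical sequence in both builds and have
    equal lengths on both sides.  ``insert`` blocks exist only in the
    modified build; their base interval is the zero-length insertion point.
    """

    base_start: int
    base_end: int
    mod_start: int
    mod_end: int
    kind: Literal["collinear", "insert"]


class CoordinateMap:
    """Piecewise correspondence between a base build and a modified build.

    Blocks tile each modified chromosome without overlap; restricted to
    collinear blocks the map is a bijection.  Only insertions are supported,
    so every base coordinate has a modified counterpart.
    """

    def __init__(
        self,
        blocks: dict[str, list[Block]],
        base_label: str = "",
        modified_label: str = "",
    ) -> None:
        self.blocks = {chrom: sorted(bl, key=lambda b: b.mod_start) for chrom, bl in blocks.items()}
        self.base_label = base_label
        self.modified_label = modified_label
        for chrom, bl in self.blocks.items():
            pos = 0
            for b in bl:
                if b.mod_start != pos:
                    raise ValueError(f"blocks do not tile modified chromosome {chrom!r}")
                if b.kind == "collinear" and (b.base_end - b.base_start) != (b.mod_end - b.mod_start):
                    raise ValueError("collinear block lengths differ between builds")
                if b.kind == "insert" and b.base_start != b.base_end:
                    raise ValueError("insert block must have a zero-length base interval")
                pos = b.mod_end

    def project(self, chrom: str, position: int, direction: str = "base_to_modified") -> int | None:
        """Project a coordinate between builds.

        Returns the counterpart coordinate, or ``None`` ("no counterpart")
        for modified positions that fall inside an insert block.  Positions
        outside every block raise ``ValueError``.  The coordinate one past
        the final block (the chromosome length) projects to the other
        build's length, so fragment boundary cuts at chromosome ends are
        projectable.
        """
        if chrom not in self.blocks:
            raise ValueError(f"chromosome {chrom!r} not covered by this map")
        bl = self.blocks[chrom]
        if direction == "base_to_modified":
            if position == bl[-1].base_end:
                return bl[-1].mod_end
            for b in bl:
                if b.kind == "collinear" and b.base_start <= position < b.base_end:
                    return b.mod_start + (position - b.base_start)
            raise ValueError(f"base position {chrom}:{position} outside mapped blocks")
        if direction == "modified_to_base":
            if position == bl[-1].mod_end:
                return bl[-1].base_end
            for b in bl:
                if b.mod_start <= position < b.mod_end:
                    if b.kind == "insert":
                        return None
                    return b.base_start + (position - b.mod_start)
            raise ValueError(f"modified position {chrom}:{position} outside mapped blocks")
        raise ValueError(f"unknown direction {direction!r}")

    def region_is_collinear(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) in modified coordinates lies entirely inside
        a single collinear block (touches no insert block or block junction).
        """
        if start > end:
            return False
        for b in self.blocks.get(chrom, ()):
            # zero-length regions count as points; block edges are fine for them
            if b.mod_start <= start and end <= b.mod_end:
                if b.kind == "collinear":
                    return True
                if start == end:
                    continue  # an edge shared with a collinear neighbour still qualifies
                return False
        return False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, b.base_start, b.base_end, b.mod_start, b.mod_end, b.kind)
            for chrom, bl in self.blocks.items()
            for b in bl
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "base_start", "base_end", "mod_start", "mod_end", "kind"]
        )


def project(cmap: CoordinateMap, chrom: str, position: int, direction: str = "base_to_modified") -> int | None:
    """Functional wrapper around :meth:`CoordinateMap.project`."""
    return cmap.project(chrom, position, direction)


def identity_map(genome: Genome) -> CoordinateMap:
    """Coordinate map of a genome onto itself (single collinear block per chromosome)."""
    blocks = {
        chrom: [Block(0, len(seq), 0, len(seq), "collinear")]
        for chrom, seq in genome.sequences.items()
    }
    return CoordinateMap(blocks, base_label=genome.build_label, modified_label=genome.build_label)


def build_modified_genome(
    base: Genome, insertions: Iterable[InsertionEvent], build_label: str | None = None
) -> tuple[Genome, CoordinateMap]:
    """Apply insertions to a base genome and return the modified genome with
    its coordinate map.

    Insertions are applied at their base coordinates in ascending order, with
    offsets accumulating; at most one insertion per base position is allowed.
    """
    ins_list = sorted(insertions, key=lambda e: (e.chrom, e.position))
    by_chrom: dict[str, list[InsertionEvent]] = {}
    for ev in ins_list:
        if ev.chrom not in base.sequences:
            raise ValueError(f"insertion {ev.label!r}: unknown chromosome {ev.chrom!r}")
        if ev.position > base.length(ev.chrom):
            raise ValueError(
                f"insertion {ev.label!r}: position {ev.position} out of range "
                f"for {ev.chrom} (length {base.length(ev.chrom)})"
            )
        bad = set(ev.insert_seq.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"insertion {ev.label!r}: invalid characters {sorted(bad)}")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        positions = [e.position for e in evs]
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate insertion position on {chrom!r}: {sorted(positions)}")

    sequences: dict[str, str] = {}
    blocks: dict[str, list[Block]] = {}
    for chrom, seq in base.sequences.items():
        evs = by_chrom.get(chrom, [])
        pieces: list[str] = []
        chrom_blocks: list[Block] = []
        base_pos = 0
        mod_pos = 0
        for ev in evs:
            if ev.position > base_pos:
                length = ev.position - base_pos
                pieces.append(seq[base_pos:ev.position])
                chrom_blocks.append(
                    Block(base_pos, ev.position, mod_pos, mod_pos + length, "collinear")
                )
                mod_pos += length
                base_pos = ev.position
            ins = ev.insert_seq.upper()
            pieces.append(ins)
            chrom_blocks.append(
                Block(base_pos, base_pos, mod_pos, mod_pos + len(ins), "insert")
            )
            mod_pos += len(ins)
        if base_pos < len(seq):
            pieces.append(seq[base_pos:])
            chrom_blocks.append(
                Block(base_pos, len(seq), mod_pos, mod_pos + len(seq) - base_pos, "collinear")
            )
        sequences[chrom] = "".join(pieces)
        blocks[chrom] = chrom_blocks

    label = build_label if build_label is not None else base.build_label + "+mod"
    modified = Genome(sequences, build_label=label)
    cmap = CoordinateMap(blocks, base_label=base.build_label, modified_label=label)
    return modified, cmap


# ---------------------------------------------------------------------------
# digestion


@dataclass
class FragmentEnd:
    """One mappable end of a primary restriction fragment.

    The end region runs between the primary cut and the nearest secondary cut
    inside the fragment.  Fragments lacking an internal secondary cut are
    *blind*: their ends cannot be distinguished by the capture chemistry and
    are excluded from analysis, as are zero-length end regions.
    """

    chrom: str
    fragment_start: int
    fragment_end: int
    primary_cut: int
    end_start: int
    end_end: int
    side: Literal["left", "right"]
    blind: bool
    unique: bool = True

    @property
    def fragment_id(self) -> str:
        return f"{self.chrom}:{self.fragment_start}-{self.fragment_end}"

    @property
    def end_id(self) -> str:
        return f"{self.chrom}:{self.primary_cut}:{self.side}"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.end_start + self.end_end)


@dataclass
class FragmentEndMap:
    """Ordered fragment ends from a two-cutter digestion of one genome."""

    ends: list[FragmentEnd]
    build_label: str = ""
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ends = sorted(self.ends, key=lambda e: (e.chrom, e.end_start, e.side))
        self._by_id = {e.end_id: e for e in self.ends}

    def __len__(self) -> int:
        return len(self.ends)

    def __getitem__(self, end_id: str) -> FragmentEnd:
        return self._by_id[end_id]

    def __contains__(self, end_id: str) -> bool:
        return end_id in self._by_id

    def non_blind(self) -> list[FragmentEnd]:
        return [e for e in self.ends if not e.blind]

    def retained(self) -> list[FragmentEnd]:
        """Non-blind ends in genomic order — the analysis universe."""
        return self.non_blind()

    def with_updates(self, ends: list[FragmentEnd]) -> "FragmentEndMap":
        return FragmentEndMap(ends, build_label=self.build_label, chrom_lengths=dict(self.chrom_lengths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.chrom, e.fragment_start, e.fragment_end, e.primary_cut,
                    e.end_start, e.end_end, e.side, e.blind, e.unique, e.fragment_id, e.end_id,
                )
                for e in self.ends
            ],
            columns=[
                "chrom", "fragment_start", "fragment_end", "primary_cut",
                "end_start", "end_end", "side", "blind", "unique", "fragment_id", "end_id",
            ],
        )


def _motif_cuts(seq: str, motif: str, offset: int) -> list[int]:
    """Cut coordinates from all (overlapping) occurrences of a motif on both
    strands.  A reverse-strand occurrence of a non-palindromic motif cuts at
    the mirrored offset."""
    motif = motif.upper()
    cuts: set[int] = set()
    i = seq.find(motif)
    while i != -1:
        cuts.add(i + offset)
        i = seq.find(motif, i + 1)
    rc = reverse_complement(motif)
    if rc != motif:
        i = seq.find(rc)
        while i != -1:
            cuts.add(i + len(motif) - offset)
            i = seq.find(rc, i + 1)
    return sorted(c for c in cuts if 0 <= c <= len(seq))


def digest(
    genome: Genome,
    first_motif: str = "GTAC",
    first_offset: int = 1,
    second_motif: str = "CATG",
    second_offset: int = 4,
    ) -> FragmentEndMap:
    """Two-cutter in-silico digestion into a fragment-end map.

    The first cutter partitions each chromosome into primary fragments.
    Within each primary fragment, the left end runs from the fragment start
    to the first secondary cut and the right end from the last secondary cut
    to the fragment end.  Fragments without a secondary cut yield two ends
    flagged blind (their region is the whole fragment); zero-length end
    regions (secondary cut coinciding with a primary cut) are also blind.

    Defaults correspond to Csp6I (G^TAC) as first cutter and NlaIII (CATG^)
    as second cutter.
    """
    for motif, offset, which in ((first_motif, first_offset, "first"), (second_motif, second_offset, "second")):
        if not motif:
            raise ValueError(f"{which} cutter motif is empty")
        if not 0 <= offset <= len(motif):
            raise ValueError(f"{which} cutter offset {offset} outside motif of length {len(motif)}")

    ends: list[FragmentEnd] = []
    for chrom, seq in genome.sequences.items():
        primary = _motif_cuts(seq, first_motif, first_offset)
        secondary = _motif_cuts(seq, second_motif, second_offset)
        boundaries = sorted({0, len(seq), *primary})
        for fs, fe in zip(boundaries[:-1], boundaries[1:]):
            inner = [c for c in secondary if fs <= c <= fe]
            if not inner:
                ends.append(FragmentEnd(chrom, fs, fe, fs, fs, fe, "left", blind=True))
                ends.append(FragmentEnd(chrom, fs, fe, fe, fs, fe, "right", blind=True))
                continue
            left_end = inner[0]
            right_start = inner[-1]
            ends.append(
                FragmentEnd(chrom, fs, fe, fs, fs, left_end, "left", blind=(left_end == fs))
            )
            ends.append(
                FragmentEnd(chrom, fs, fe, fe, right_start, fe, "right", blind=(right_start == fe))
            )
    return FragmentEndMap(
        ends,
        build_label=genome.build_label,
        chrom_lengths={c: len(s) for c, s in genome.sequences.items()},
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def flag_unique_ends(fragmap: FragmentEndMap, genome: Genome) -> FragmentEndMap:
    """Flag ends whose full-length region sequence (or its reverse
    complement) occurs more than once in the genome as non-unique.

    This is an exact-duplication criterion: multi-mapping end regions are
    the ones an aligner could not place unambiguously.  Zero-length end
    regions are flagged blind.
    """
    new_ends: list[FragmentEnd] = []
    for e in fragmap.ends:
        if e.end_end <= e.end_start:
            new_ends.append(replace(e, blind=True))
            continue
        if e.blind:
            new_ends.append(replace(e))
            continue
        region = genome.sequences[e.chrom][e.end_start:e.end_end]
        rc = reverse_complement(region)
        hits = 0
        for seq in genome.sequences.values():
            hits += _count_occurrences(seq, region)
            if rc != region:
                hits += _count_occurrences(seq, rc)
        new_ends.append(replace(e, unique=hits <= 1))
    return fragmap.with_updates(new_ends)


def match_common_ends(
    fragmap_a: FragmentEndMap,
    map_a: CoordinateMap,
    fragmap_b: FragmentEndMap,
    map_b: CoordinateMap,
) -> pd.DataFrame:
    """Pair fragment ends of two builds that descend from the same base-genome
    cut site.

    Two ends are *common* iff their primary cuts project to the same base
    coordinate with the same side and neither end region overlaps an insert
    block or a block junction of its own build.  All other ends are
    build-specific (``A_only`` / ``B_only``); ends whose region spans a
    junction are additionally marked ``junction_spanning``.

    Returns a table with one row per end-pairing or unmatched end, carrying
    the projected base coordinates used for cross-build alignment.
    """
    if map_a.base_label != map_b.base_label:
        raise ValueError(
            f"coordinate maps refer to different base builds: "
            f"{map_a.base_label!r} vs {map_b.base_label!r}"
        )

    def classify(fragmap: FragmentEndMap, cmap: CoordinateMap):
        keyed: dict[tuple, dict] = {}
        unmatched: list[dict] = []
        for e in fragmap.ends:
            collinear = cmap.region_is_collinear(e.chrom, e.end_start, e.end_end)
            base_cut = cmap.project(e.chrom, e.primary_cut, "modified_to_base")
            if base_cut is None or not collinear:
                unmatched.append(
                    {"end_id": e.end_id, "junction_spanning": base_cut is not None and not collinear}
                )
                continue
            base_mid = cmap.project(e.chrom, int(e.midpoint), "modified_to_base")
            keyed[(e.chrom, base_cut, e.side)] = {
                "end_id": e.end_id,
                "base_chrom": e.chrom,
                "base_cut": base_cut,
                "base_mid": base_mid,
                "side": e.side,
            }
        return keyed, unmatched

    keyed_a, unmatched_a = classify(fragmap_a, map_a)
    keyed_b, unmatched_b = classify(fragmap_b, map_b)

    rows: list[dict] = []
    for key, rec_a in keyed_a.items():
        rec_b = keyed_b.get(key)
        if rec_b is not None:
            rows.append(
                {
                    "status": "common",
                    "end_id_a": rec_a["end_id"],
                    "end_id_b": rec_b["end_id"],
                    "base_chrom": rec_a["base_chrom"],
                    "base_cut": rec_a["base_cut"],
                    "base_mid": rec_a["base_mid"],
                    "side": rec_a["side"],
                    "junction_spanning": False,
                }
            )
        else:
            rows.append(
                {
                    "status": "A_only",
                    "end_id_a": rec_a["end_id"],
                    "end_id_b": None,
                    "base_chrom": rec_a["base_chrom"],
                    "base_cut": rec_a["base_cut"],
                    "base_mid": rec_a["base_mid"],
                    "side": rec_a["side"],
                    "junction_spanning": False,
                }
            )
    for key, rec_b in keyed_b.items():
        if key not in keyed_a:
            rows.append(
                {
                    "status": "B_only",
                    "end_id_a": None,
                    "end_id_b": rec_b["end_id"],
                    "base_chrom": rec_b["base_chrom"],
                    "base_cut": rec_b["base_cut"],
                    "base_mid": rec_b["base_mid"],
                    "side": rec_b["side"],
                    "junction_spanning": False,
                }
            )
    for rec in unmatched_a:
        rows.append(
            {
                "status": "A_only",
                "end_id_a": rec["end_id"],
                "end_id_b": None,
                "base_chrom": None,
                "base_cut": None,
                "base_mid": None,
                "side": None,
                "junction_spanning": rec["junction_spanning"],
            }
        )
    for rec in unmatched_b:
        rows.append(
            {
                "status": "B_only",
                "end_id_a": None,
                "end_id_b": rec["end_id"],
                "base_chrom": None,
                "base_cut": None,
                "base_mid": None,
                "side": None,
                "junction_spanning": rec["junction_spanning"],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "status", "end_id_a", "end_id_b", "base_chrom", "base_cut",
            "base_mid", "side", "junction_spanning",
        ],
    )
    return df.sort_values(
        ["base_chrom", "base_cut", "side"], na_position="last", kind="stable"
    ).reset_index(drop=True)
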