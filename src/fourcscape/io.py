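"""Readers and writers for the formats the pipeline touches.

FASTA genomes, insertion manifests (TSV), fragment-end maps (BED6),
coordinate maps (chain-style TSV), count/profile tables (TSV), bedGraph
tracks and BED9 color tracks.  All genomic intervals are 0-based half-open,
matching BED/bedGraph conventions.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_builder import (
    Block,
    CoordinateMap,
    FragmentEnd,
    FragmentEndMap,
    Genome,
    InsertionEvent,
)
from .overlay_compare import DifferentialTrack
from .profile_norm import ContactProfile, NormalizedProfile, Viewpoint

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_insertion_manifest",
    "write_insertion_manifest",
    "read_fragmap_bed",
    "write_fragmap_bed",
    "read_coordinate_map",
    "write_coordinate_map",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_profile_bedgraph",
    "read_profile_bedgraph",
    "write_differential_bedgraph",
    "write_differential_bed9",
    "read_facs_csv",
    "read_qpcr_tsv",
]


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path, build_label: str = "") -> Genome:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return Genome(records, build_label=build_label or Path(path).stem)


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- insertion manifests -----------------------------------------------------

def read_insertion_manifest(path: str | Path) -> list[InsertionEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
    required = {"chrom", "position", "insert_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"insertion manifest missing columns: {sorted(missing)}")
    return [
        InsertionEvent(
            chrom=row.chrom,
            position=int(row.position),
            insert_seq=str(row.insert_seq),
            label=str(getattr(row, "label", "")),
        )
        for row in df.itertuples(index=False)
    ]


def write_insertion_manifest(events: list[InsertionEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.chrom, e.position, e.insert_seq, e.label) for e in events],
        columns=["chrom", "position", "insert_seq", "label"],
    ).to_csv(path, sep="\t", index=False)


# -- fragment-end maps (BED6) ------------------------------------------------
# name: fragment_start;fragment_end;side;primary_cut  score: 2*blind + (not unique)
# strand: '+' for left ends, '-' for right ends.

def write_fragmap_bed(fragmap: FragmentEndMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        if fragmap.build_label or fragmap.chrom_lengths:
            lengths = ",".join(f"{c}:{l}" for c, l in fragmap.chrom_lengths.items())
            fh.write(f"# build={fragmap.build_label} chrom_lengths={lengths}\n")
        for e in fragmap.ends:
            name = f"{e.fragment_start};{e.fragment_end};{e.side};{e.primary_cut}"
            score = 2 * int(e.blind) + int(not e.unique)
            strand = "+" if e.side == "left" else "-"
            fh.write(
                f"{e.chrom}\t{e.end_start}\t{e.end_end}\t{name}\t{score}\t{strand}\n"
            )


def read_fragmap_bed(path: str | Path) -> FragmentEndMap:
    ends: list[FragmentEnd] = []
    build_label = ""
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    if token.startswith("build="):
                        build_label = token[len("build="):]
                    elif token.startswith("chrom_lengths=") and token != "chrom_lengths=":
                        for pair in token[len("chrom_lengths="):].split(","):
                            c, l = pair.rsplit(":", 1)
                            chrom_lengths[c] = int(l)
                continue
            chrom, start, end, name, score, _strand = line.split("\t")
            fs, fe, side, cut = name.split(";")
            score = int(score)
            ends.append(
                FragmentEnd(
                    chrom=chrom,
                    fragment_start=int(fs),
                    fragment_end=int(fe),
                    primary_cut=int(cut),
                    end_start=int(start),
                    end_end=int(end),
                    side=side,  # type: ignore[arg-type]
                    blind=bool(score & 2),
                    unique=not bool(score & 1),
                )
            )
    return FragmentEndMap(ends, build_label=build_label, chrom_lengths=chrom_lengths)


# -- coordinate maps ---------------------------------------------------------

def write_coordinate_map(cmap: CoordinateMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# base={cmap.base_label} modified={cmap.modified_label}\n")
        fh.write("chrom\tbase_start\tbase_end\tmod_start\tmod_end\tkind\n")
        for chrom, blocks in cmap.blocks.items():
            for b in blocks:
                fh.write(
                    f"{chrom}\t{b.base_start}\t{b.base_end}\t{b.mod_start}\t{b.mod_end}\t{b.kind}\n"
                )


def read_coordinate_map(path: str | Path) -> CoordinateMap:
    base_label = modified_label = ""
    blocks: dict[str, list[Block]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.startswith("#"):
            for token in header.lstrip("# ").split():
                if token.startswith("base="):
                    base_label = token[len("base="):]
                elif token.startswith("modified="):
                    modified_label = token[len("modified="):]
            fh.readline()  # column header
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row:
                continue
            chrom, bs, be, ms, me, kind = row
            blocks.setdefault(chrom, []).append(
                Block(int(bs), int(be), int(ms), int(me), kind)  # type: ignore[arg-type]
            )
    return CoordinateMap(blocks, base_label=base_label, modified_label=modified_label)


# -- count tables and profiles -----------------------------------------------

def write_counts_tsv(
    profile: ContactProfile, fragmap: FragmentEndMap, path: str | Path
) -> None:
    vp = profile.viewpoint
    with open(path, "w") as fh:
        fh.write(f"# viewpoint={vp.chrom}:{vp.position} label={vp.label} build={profile.genome_build}\n")
        fh.write("fragment_end_id\tchrom\tend_start\tend_end\tcount\n")
        for e in fragmap.ends:
            if e.end_id in profile.counts:
                fh.write(
                    f"{e.end_id}\t{e.chrom}\t{e.end_start}\t{e.end_end}\t{profile.counts[e.end_id]}\n"
                )


def read_counts_tsv(path: str | Path) -> ContactProfile:
    viewpoint = Viewpoint("", 0)
    build = ""
    counts: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#"):
            label = "VP"
            for token in first.lstrip("# ").split():
                if token.startswith("viewpoint="):
                    loc = token[len("viewpoint="):]
                    chrom, pos = loc.rsplit(":", 1)
                    viewpoint = Viewpoint(chrom, int(pos))
                elif token.startswith("label="):
                    label = token[len("label="):]
                elif token.startswith("build="):
                    build = token[len("build="):]
            viewpoint = Viewpoint(viewpoint.chrom, viewpoint.position, label)
            fh.readline()  # column header
        for line in fh:
            if not line.strip():
                continue
            end_id, _chrom, _s, _e, count = line.rstrip("\n").split("\t")
            counts[end_id] = int(count)
    return ContactProfile(viewpoint=viewpoint, counts=counts, genome_build=build)


def write_profile_bedgraph(
    norm: NormalizedProfile,
    fragmap: FragmentEndMap,
    path: str | Path,
    smoothed: bool = False,
) -> None:
    """Normalized (or smoothed) coverage as a sorted bedGraph over end regions."""
    source = norm.smoothed if smoothed else norm.values
    rows = []
    for e in fragmap.ends:
        if e.end_id in source and e.end_end > e.end_start:
            rows.append((e.chrom, e.end_start, e.end_end, source[e.end_id]))
    rows.sort()
    with open(path, "w") as fh:
        name = "smoothed" if smoothed else "normalized"
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, s, e_, v in rows:
            fh.write(f"{chrom}\t{s}\t{e_}\t{v:.6g}\n")


def read_profile_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.rstrip("\n").split("\t")
            rows.append((chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# -- differential tracks -----------------------------------------------------

def write_differential_bedgraph(track: DifferentialTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.label}"\n')
        for row in track.bins.itertuples(index=False):
            if not np.isnan(row.difference):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.difference:.6g}\n")


def _color_rgb(row) -> str:
    # gained: green ramp; lost: grey ramp; white/blank: white
    if row.color_class in ("white", "blank"):
        return "255,255,255"
    level = int(round(255 * (1.0 - row.intensity)))
    if row.direction == "gained":
        return f"{level},200,{level}"
    return f"{level},{level},{level}"


def write_differential_bed9(track: DifferentialTrack, path: str | Path) -> None:
    """Color-classified differential track as a 9-column BED with itemRgb."""
    if "color_class" not in track.bins.columns:
        raise ValueError("track has no color classification; run classify_colors first")
    with open(path, "w") as fh:
        fh.write(f'track name="{track.label}" itemRgb="On"\n')
        for row in track.bins.itertuples(index=False):
            if np.isnan(row.difference):
                continue
            name = f"{row.direction}:{row.color_class}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t.\t"
                f"{row.start}\t{row.end}\t{_color_rgb(row)}\n"
            )


# -- assay inputs ------------------------------------------------------------

def read_facs_csv(path: str | Path, label: str = "", channel: str = "GFP"):
    """One fluorescence intensity per row (optional header)."""
    from .assay_quant import FACSSample

    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                continue  # header line
    return FACSSample(np.array(values), label=label or Path(path).stem, channel=channel)  # type: ignore[arg-type]


def read_qpcr_tsv(path: str | Path):
    """qPCR table with columns site_label, ct_ip, ct_input, input_dilution_factor."""
    from .assay_quant import QPCRMeasurement

    df = pd.read_csv(path, sep="\t")
    return [
        QPCRMeasurement(
            site_label=str(row.site_label),
            ct_ip=float(row.ct_ip),
            ct_input=float(row.ct_input),
            input_dilution_factor=float(getattr(row, "input_dilution_factor", 1.0)),
        )
        for row in df.itertuples(index=False)
    ]
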