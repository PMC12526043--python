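"""Strand-specific CPD lesion tracks from aligned damage-seq reads.

CPD-seq reads start immediately downstream of the lesion: the enzymatic
cleavage leaves the read 5' end just past the dipyrimidine on the *opposite*
strand.  For a plus-strand read with 5' end at 0-based coordinate x the
candidate lesion is the minus-strand dinucleotide over genomic bases x-2 and
x-1; for a minus-strand read whose 5' end is its rightmost genomic base y the
candidate lesion is the plus-strand dinucleotide over y+1 and y+2.  A lesion
is recorded at the half-integer position midway between its two bases
(bases p and p+1 -> p + 0.5) and kept only when the dinucleotide read 5'->3'
on the lesion strand is one of TT/TC/CT/CC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import (
    DIPYRIMIDINES,
    GenomeSequence,
    GenomicInterval,
    reverse_complement,
)

logger = logging.getLogger(__name__)

TrackKey = tuple[str, str, float]  # (chrom, strand, half_position)


@dataclass
class LesionTrack:
    """Counts of CPD lesions keyed by (chrom, strand, half_position)."""

    counts: dict[TrackKey, float] = field(default_factory=dict)
    sample_id: str = ""

    @property
    def total_dipy_reads(self) -> float:
        return sum(self.counts.values())

    def add(self, chrom: str, strand: str, half_position: float, n: float = 1) -> None:
        key = (chrom, strand, half_position)
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, chrom: str, strand: str, half_position: float) -> float:
        return self.counts.get((chrom, strand, half_position), 0)


@dataclass
class NormalizedPair:
    """A cellular track and its naked-DNA control scaled to the same total."""

    cellular: LesionTrack
    naked_scaled: LesionTrack
    scale_factor: float


def lesion_strand_dinucleotide(genome: GenomeSequence, chrom: str, strand: str, p: int) -> str:
    """Dinucleotide covering plus-strand bases p, p+1, read 5'->3' on `strand`."""
    duplex = genome.fetch(chrom, p, p + 2)
    return duplex if strand == "+" else reverse_complement(duplex)


def is_dipyrimidine_site(genome: GenomeSequence, chrom: str, strand: str, half_position: float) -> bool:
    p = int(half_position - 0.5)
    if p < 0 or p + 2 > genome.length(chrom):
        return False
    return lesion_strand_dinucleotide(genome, chrom, strand, p) in DIPYRIMIDINES


def load_bed6_reads(path) -> list[GenomicInterval]:
    """Aligned reads as stranded BED6 intervals."""
    from .genome_io import load_intervals

    reads = load_intervals(path, kind="generic")
    for iv in reads:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"read without strand: {iv}")
    return reads


def reads_to_lesions(
    reads: list[GenomicInterval],
    genome: GenomeSequence,
    sample_id: str = "",
) -> LesionTrack:
    """Assign each read's candidate lesion; keep only dipyrimidine sites.

    Reads implicating a dinucleotide off the chromosome end are dropped and
    counted; reads naming an unknown chromosome are errors.
    """
    track = LesionTrack(sample_id=sample_id)
    retained = discarded_nondipy = discarded_edge = 0
    for read in reads:
        if read.chrom not in genome.chromosomes:
            raise KeyError(f"read on unknown chromosome {read.chrom!r}")
        if read.strand == "+":
            # lesion on minus strand, bases x-2 .. x-1
            p = read.start - 2
            strand = "-"
        else:
            # 5' end of a minus-strand read = its rightmost genomic base
            y = read.end - 1
            p = y + 1
            strand = "+"
        if p < 0 or p + 2 > genome.length(read.chrom):
            discarded_edge += 1
            continue
        dinuc = lesion_strand_dinucleotide(genome, read.chrom, strand, p)
        if dinuc not in DIPYRIMIDINES:
            discarded_nondipy += 1
            continue
        track.add(read.chrom, strand, p + 0.5)
        retained += 1
    logger.info(
        "%s: retained %d reads, discarded %d non-dipyrimidine, %d off-end",
        sample_id, retained, discarded_nondipy, discarded_edge,
    )
    return track


def merge_tracks(tracks: list[LesionTrack], sample_id: str = "merged") -> LesionTrack:
    """Keywise sum of replicate lesion tracks (raw counts, pre-normalization)."""
    if not tracks:
        raise ValueError("no tracks to merge")
    merged = LesionTrack(sample_id=sample_id)
    for track in tracks:
        for key, n in track.counts.items():
            merged.counts[key] = merged.counts.get(key, 0) + n
    return merged


def normalize_pair(cellular: LesionTrack, naked: LesionTrack) -> NormalizedPair:
    """Scale the naked-DNA control to the cellular dipyrimidine read total."""
    cell_total = cellular.total_dipy_reads
    naked_total = naked.total_dipy_reads
    if cell_total <= 0 or naked_total <= 0:
        raise ValueError("cannot normalize a zero-total track")
    scale = cell_total / naked_total
    scaled = LesionTrack(
        counts={k: v * scale for k, v in naked.counts.items()},
        sample_id=f"{naked.sample_id}_scaled",
    )
    return NormalizedPair(cellular=cellular, naked_scaled=scaled, scale_factor=scale)


def export_track_wig(values: dict[TrackKey, float], path_prefix: str) -> tuple[str, str]:
    """Write one variableStep wiggle per strand, 1-based positions.

    A half-integer position h is exported at 1-based coordinate floor(h) + 1,
    i.e. the left (smaller) base of the dipyrimidine.  Returns the two paths.
    """
    paths = []
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        per_chrom: dict[str, list[tuple[int, float]]] = {}
        for (chrom, s, half), v in values.items():
            if s != strand:
                continue
            per_chrom.setdefault(chrom, []).append((int(half) + 1, v))
        out = f"{path_prefix}.{suffix}.wig"
        with open(out, "w") as fh:
            fh.write(f'track type=wiggle_0 name="{path_prefix} ({strand})"\n')
            for chrom in sorted(per_chrom):
                fh.write(f"variableStep chrom={chrom}\n")
                for pos, v in sorted(per_chrom[chrom]):
                    fh.write(f"{pos}\t{v:g}\n")
        paths.append(out)
    return tuple(paths)


def read_track_wig(plus_path, minus_path) -> dict[TrackKey, float]:
    """Read back a wiggle pair written by :func:`export_track_wig`.

    Values come back keyed at the exported (floored) left-base half position.
    """
    values: dict[TrackKey, float] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        chrom = None
        with open(str(path)) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("track") or not line:
                    continue
                if line.startswith("variableStep"):
                    chrom = dict(
                        kv.split("=") for kv in line.split()[1:]
                    )["chrom"]
                    continue
                pos_s, val_s = line.split("\t")
                values[(chrom, strand, (int(pos_s) - 1) + 0.5)] = float(val_s)
    return values
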