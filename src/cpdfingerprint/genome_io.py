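"""Genome and interval I/O plus IUPAC motif enumeration.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based happens only at wiggle/report boundaries.  Motif occurrences are
reported on both strands with a strand-aware *anchor* base that defines
offset 0 of the motif-relative coordinate frame (e.g. the central adenine of
CCAAT, or the first cytosine of the terminal CC in CTTCC).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PYRIMIDINES = frozenset("CT")
DIPYRIMIDINES = frozenset({"TT", "TC", "CT", "CC"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    chromosomes: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[start:end) on the plus strand; bounds are checked."""
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"{chrom}:{start}-{end} outside [0, {len(seq)})"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifOccurrence:
    """A strand-aware motif match.

    ``match_start`` is the 0-based genomic coordinate of the match's leftmost
    genomic base (for minus-strand matches this is the *rightmost* base of the
    motif read 5'->3').  ``anchor`` is the genomic coordinate of the motif
    base designated offset 0.
    """

    chrom: str
    strand: str
    match_start: int
    anchor: int
    motif_id: str

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.anchor}:{self.strand}"


def load_genome(path) -> GenomeSequence:
    """Load a (multi-)FASTA into memory, uppercased.

    Raises on duplicate record names or empty sequences.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        chromosomes[record.id] = str(record.seq).upper()
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    genome = GenomeSequence(chromosomes)
    logger.info(
        "loaded %d chromosome(s), %d bp total",
        len(chromosomes), sum(len(s) for s in chromosomes.values()),
    )
    return genome


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for letter in pattern.upper():
        try:
            bases = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so that overlapping matches are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def _interval_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def scan_motif(
    genome: GenomeSequence,
    pattern: str,
    anchor_index: int,
    include: Iterable[GenomicInterval] | None = None,
    exclude: Iterable[GenomicInterval] | None = None,
    motif_id: str | None = None,
) -> list[MotifOccurrence]:
    """Enumerate all occurrences of an IUPAC pattern on both strands.

    Minus-strand occurrences are matches of the reverse complement of
    ``pattern`` on the plus-strand text; their anchor is mapped through the
    strand flip (anchor = leftmost base + pattern length - 1 - anchor_index).
    Overlapping occurrences are each reported.  An occurrence is dropped if
    any base of its match span intersects an ``exclude`` interval, or (when
    ``include`` is given) if its span is not fully inside an include interval.
    """
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty motif pattern")
    if not (0 <= anchor_index < len(pattern)):
        raise ValueError(
            f"anchor_index {anchor_index} outside pattern of length {len(pattern)}"
        )
    motif_id = motif_id or pattern
    m = len(pattern)
    fwd = _iupac_regex(pattern)
    rev = _iupac_regex(reverse_complement(pattern))

    exclude_trees = _interval_trees(exclude) if exclude else {}
    include_trees = _interval_trees(include) if include is not None else None

    occurrences: list[MotifOccurrence] = []
    for chrom, seq in genome.chromosomes.items():
        excl = exclude_trees.get(chrom)
        incl = include_trees.get(chrom) if include_trees is not None else None
        hits: list[tuple[int, str, int]] = []  # (start, strand, anchor)
        for match in fwd.finditer(seq):
            s = match.start()
            hits.append((s, "+", s + anchor_index))
        for match in rev.finditer(seq):
            s = match.start()
            hits.append((s, "-", s + (m - 1 - anchor_index)))
        for s, strand, anchor in hits:
            if excl is not None and excl.overlap(s, s + m):
                continue
            if include_trees is not None:
                if incl is None or not any(
                    iv.begin <= s and s + m <= iv.end for iv in incl.overlap(s, s + m)
                ):
                    continue
            occurrences.append(
                MotifOccurrence(chrom, strand, s, anchor, motif_id)
            )
    occurrences.sort(key=lambda o: (o.chrom, o.match_start, o.strand))
    return occurrences


def occurrence_sequence(genome: GenomeSequence, occ: MotifOccurrence, length: int) -> str:
    """Motif sequence read 5'->3' on the occurrence's strand."""
    raw = genome.fetch(occ.chrom, occ.match_start, occ.match_start + length)
    return raw if occ.strand == "+" else reverse_complement(raw)


def load_intervals(path, kind: str = "generic") -> list[GenomicInterval]:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    The format is chosen by extension (.gff/.gff3 vs anything else = BED).
    Malformed lines raise with their line number.
    """
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3"))
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ValueError("GFF line has fewer than 9 fields")
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in ("+", "-") else "."
                    label = fields[8]
                else:
                    if len(fields) < 3:
                        raise ValueError("BED line has fewer than 3 fields")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    strand = (
                        fields[5] if len(fields) > 5 and fields[5] in ("+", "-")
                        else "."
                    )
                if end <= start:
                    raise ValueError(f"end ({end}) <= start ({start})")
                intervals.append(GenomicInterval(chrom, start, end, strand, label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {kind} line: {exc}")
    return intervals
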