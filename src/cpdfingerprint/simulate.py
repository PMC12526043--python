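"""Ground-truth simulator: genomes, planted fingerprints, counts, and reads.

The generator emulates the damage structure seen around bound TF motifs:
sequence-intrinsic (naked DNA) damage rates that depend on the dipyrimidine
identity, multiplicative induction/suppression of the cellular rate at fixed
motif-frame offsets of *bound* sites only, Poisson count noise, and the
damage-seq 5'-end read convention.  Decoy motifs are planted deep inside
ORFs and receive no modulation, giving every downstream stage a labeled
truth set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    IUPAC_CODES,
    GenomeSequence,
    GenomicInterval,
    MotifOccurrence,
    reverse_complement,
)
from .lesion_map import LesionTrack

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

# dinucleotide ids (first*4 + second) of the four lesion-forming dipyrimidines
_DIPY_IDS = {
    _CODE["T"] * 4 + _CODE["T"]: "TT",
    _CODE["T"] * 4 + _CODE["C"]: "TC",
    _CODE["C"] * 4 + _CODE["T"]: "CT",
    _CODE["C"] * 4 + _CODE["C"]: "CC",
}

DEFAULT_DINUCLEOTIDE_WEIGHTS = {"TT": 1.0, "TC": 0.5, "CT": 0.15, "CC": 0.1}
DEFAULT_MODULATION = {-1.5: 0.3, 0.5: 3.0, 2.5: 0.5, 3.5: 0.5, 4.5: 0.5}


@dataclass
class SimConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.40
    n_orfs: int = 20
    orf_length: int = 4_000
    n_bound_sites: int = 40
    n_decoy_sites: int = 5_000
    motif: str = "CCAAT"
    anchor_index: int = 2
    depth: float | None = None  # expected total naked lesions; None = derive
    target_median_naked: float = 20.0
    dinucleotide_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DINUCLEOTIDE_WEIGHTS)
    )
    modulation: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MODULATION)
    )
    decoy_margin: int = 100
    read_length: int = 50
    chrom_name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.dinucleotide_weights.values()) and all(
            w == 0 for w in self.dinucleotide_weights.values()
        ):
            raise ValueError("all dinucleotide weights are zero")
        if any(w < 0 for w in self.dinucleotide_weights.values()):
            raise ValueError("dinucleotide weights must be >= 0")
        if any(m < 0 for m in self.modulation.values()):
            raise ValueError("modulation factors must be >= 0")


@dataclass
class SimTruth:
    genome: GenomeSequence
    orfs: list[GenomicInterval]
    bound_sites: list[MotifOccurrence]
    decoy_sites: list[MotifOccurrence]
    cellular: LesionTrack
    naked: LesionTrack
    config: SimConfig


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        b if len(IUPAC_CODES[b]) == 1 else rng.choice(list(IUPAC_CODES[b]))
        for b in pattern.upper()
    )


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[GenomeSequence, list[GenomicInterval], list[MotifOccurrence], list[MotifOccurrence]]:
    """Random genome with non-overlapping ORFs and planted motif instances.

    Bound sites go into inter-ORF "promoter" gaps (minimum 30 bp apart so
    their fingerprint windows never collide); decoys go inside ORFs at least
    ``decoy_margin`` bp from either end.  Motifs are written verbatim on a
    random strand.
    """
    m = len(cfg.motif)
    gap = (cfg.genome_length - cfg.n_orfs * cfg.orf_length) // (cfg.n_orfs + 1)
    if gap < 2 * 12 + m:
        raise ValueError("genome too small for the requested ORF layout")

    p_gc = cfg.gc_fraction / 2
    p_at = (1 - cfg.gc_fraction) / 2
    codes = rng.choice(4, size=cfg.genome_length, p=[p_at, p_gc, p_gc, p_at])
    seq = np.array(list(_BASES), dtype="U1")[codes]

    orfs = []
    for i in range(cfg.n_orfs):
        start = gap + i * (cfg.orf_length + gap)
        orfs.append(
            GenomicInterval(
                cfg.chrom_name, start, start + cfg.orf_length,
                "+" if i % 2 == 0 else "-", f"orf_{i + 1}",
            )
        )

    # candidate slots for bound sites: inter-ORF gaps, 12 bp clearance,
    # 30 bp pitch so neighboring fingerprints stay independent
    gap_regions = [
        (end_prev, start_next)
        for end_prev, start_next in zip(
            [0] + [o.end for o in orfs], [o.start for o in orfs] + [cfg.genome_length]
        )
        if start_next - end_prev > 0
    ]
    promoter_slots = [
        s
        for lo, hi in gap_regions
        for s in range(lo + 12, hi - 12 - m + 1, 30)
    ]
    if len(promoter_slots) < cfg.n_bound_sites:
        raise ValueError("not enough promoter slots for requested bound sites")
    decoy_slots = [
        s
        for o in orfs
        for s in range(o.start + cfg.decoy_margin, o.end - cfg.decoy_margin - m + 1, m + 7)
    ]
    if len(decoy_slots) < cfg.n_decoy_sites:
        raise ValueError("not enough intragenic slots for requested decoy sites")

    def plant(slots: list[int], n: int, motif_id: str) -> list[MotifOccurrence]:
        chosen = sorted(rng.choice(len(slots), size=n, replace=False))
        sites = []
        for idx in chosen:
            s = slots[idx]
            instance = _concrete_motif(cfg.motif, rng)
            strand = rng.choice(["+", "-"])
            written = instance if strand == "+" else reverse_complement(instance)
            seq[s:s + m] = list(written)
            anchor = (
                s + cfg.anchor_index if strand == "+"
                else s + (m - 1 - cfg.anchor_index)
            )
            sites.append(MotifOccurrence(cfg.chrom_name, strand, s, anchor, motif_id))
        return sites

    bound = plant(promoter_slots, cfg.n_bound_sites, cfg.motif)
    decoys = plant(decoy_slots, cfg.n_decoy_sites, cfg.motif)
    genome = GenomeSequence({cfg.chrom_name: "".join(seq)})
    return genome, orfs, bound, decoys


def _dipy_rates(seq: str, weights: dict[str, float]):
    """Per-position base rates (unnormalized weights) for both strands.

    Returns (plus_w, minus_w): arrays of length len(seq) - 1 where entry p is
    the damage weight of the dinucleotide over plus-strand bases p, p+1 on
    that strand (0 where the strand carries no dipyrimidine there).
    """
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    c = lut[codes]
    wtab = np.zeros(16)
    for dinuc_id, name in _DIPY_IDS.items():
        wtab[dinuc_id] = weights.get(name, 0.0)
    plus_id = c[:-1] * 4 + c[1:]
    comp = 3 - c
    minus_id = comp[1:] * 4 + comp[:-1]  # read 5'->3' on the minus strand
    return wtab[plus_id], wtab[minus_id]


def simulate_lesion_counts(
    genome: GenomeSequence,
    bound_sites: list[MotifOccurrence],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[LesionTrack, LesionTrack]:
    """Poisson lesion counts for the naked control and the cellular sample.

    Every dipyrimidine (both strands) gets naked rate lambda = depth * w / Z;
    the cellular rate is multiplied by the configured modulation factor where
    the position coincides with a bound-site motif-frame offset.  Decoys and
    chance motifs get no modulation.
    """
    cellular = LesionTrack(sample_id="sim_cellular")
    naked = LesionTrack(sample_id="sim_naked")
    for chrom, seq in genome.chromosomes.items():
        plus_w, minus_w = _dipy_rates(seq, cfg.dinucleotide_weights)
        all_w = np.concatenate([plus_w[plus_w > 0], minus_w[minus_w > 0]])
        if all_w.size == 0:
            continue
        Z = all_w.sum()
        depth = cfg.depth
        if depth is None:
            depth = cfg.target_median_naked * Z / np.median(all_w)
        lam_plus = depth * plus_w / Z
        lam_minus = depth * minus_w / Z

        mod_plus = np.ones_like(lam_plus)
        mod_minus = np.ones_like(lam_minus)
        for site in bound_sites:
            if site.chrom != chrom:
                continue
            for offset, factor in cfg.modulation.items():
                h = site.anchor + offset if site.strand == "+" else site.anchor - offset
                p = int(h - 0.5)
                if 0 <= p < len(lam_plus):
                    mod_plus[p] *= factor
                    mod_minus[p] *= factor

        naked_counts = rng.poisson(lam_plus), rng.poisson(lam_minus)
        cell_counts = rng.poisson(lam_plus * mod_plus), rng.poisson(lam_minus * mod_minus)
        for strand, nk, cl in (
            ("+", naked_counts[0], cell_counts[0]),
            ("-", naked_counts[1], cell_counts[1]),
        ):
            for p in np.nonzero(nk)[0]:
                naked.counts[(chrom, strand, p + 0.5)] = int(nk[p])
            for p in np.nonzero(cl)[0]:
                cellular.counts[(chrom, strand, p + 0.5)] = int(cl[p])
    return cellular, naked


def emit_reads(
    track: LesionTrack, genome: GenomeSequence, read_length: int = 50
) -> list[GenomicInterval]:
    """BED6-style reads applying the exact inverse of the 5'-end convention.

    A minus-strand lesion over bases p, p+1 produces a plus-strand read with
    5' end at p+2; a plus-strand lesion there produces a minus-strand read
    whose 5' end (rightmost base) is p-1.  One read per count unit; reads
    that would run off the chromosome are dropped (counted in the log).
    """
    reads: list[GenomicInterval] = []
    dropped = 0
    for (chrom, strand, half), n in sorted(track.counts.items()):
        p = int(half - 0.5)
        length = genome.length(chrom)
        if strand == "-":
            x = p + 2
            start, end, read_strand = x, x + read_length, "+"
        else:
            y = p - 1
            start, end, read_strand = y - read_length + 1, y + 1, "-"
        if start < 0 or end > length:
            dropped += int(n)
            continue
        for i in range(int(round(n))):
            reads.append(GenomicInterval(chrom, start, end, read_strand, "read"))
    if dropped:
        logger.info("emit_reads: dropped %d edge reads", dropped)
    return reads


def simulate(cfg: SimConfig) -> SimTruth:
    """Full simulation under one seed: genome, annotations, and count tracks."""
    rng = np.random.default_rng(cfg.seed)
    genome, orfs, bound, decoys = simulate_genome(cfg, rng)
    cellular, naked = simulate_lesion_counts(genome, bound, cfg, rng)
    return SimTruth(genome, orfs, bound, decoys, cellular, naked, cfg)


def write_fasta(genome: GenomeSequence, path) -> None:
    with open(str(path), "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(str(path), "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def write_sites_tsv(sites: list[MotifOccurrence], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("chrom\tstrand\tmatch_start\tanchor\tmotif_id\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.strand}\t{s.match_start}\t{s.anchor}\t{s.motif_id}\n")


def read_sites_tsv(path) -> list[MotifOccurrence]:
    import pandas as pd

    df = pd.read_csv(str(path), sep="\t", comment="#")
    return [
        MotifOccurrence(r.chrom, r.strand, int(r.match_start), int(r.anchor), r.motif_id)
        for r in df.itertuples()
    ]
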