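"""Damage-induction tracks and motif-frame CPD fingerprint profiles.

Induction at a half-integer position is the difference between the cellular
count and the scaled naked-DNA count; the companion channel is the log2 ratio
of the two after clamping both to a minimum count (default 10), which tames
ratios at low coverage.  Profiles project these values into a motif-relative
frame: offset o covers motif-frame bases o-0.5 and o+0.5, and minus-strand
sites are mirrored through the anchor so that a site and its reverse
complement yield identical profiles.  At any duplex position at most one
strand can carry a lesion-forming dipyrimidine, so the per-offset value sums
the two genomic strands, which in effect selects the lesion-bearing one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeSequence, MotifOccurrence
from .lesion_map import LesionTrack, NormalizedPair, TrackKey, is_dipyrimidine_site

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 10


@dataclass
class InductionTrack:
    """Per-position induction (cellular - scaled naked) and floored log2 ratio."""

    induction: dict[TrackKey, float]
    log2_floored: dict[TrackKey, float]
    floor: int = DEFAULT_FLOOR


@dataclass
class SiteProfile:
    site: MotifOccurrence
    offsets: list[float]
    induction_values: list[float]
    logratio_values: list[float]
    has_dipy: list[bool]
    partial: bool = False


@dataclass
class AggregateProfile:
    offsets: list[float]
    total_induction: list[float]
    n_sites: int
    n_dipy_sites: list[int]
    average_induction: list[float]
    denominator_mode: str


def window_offsets(window: float) -> list[float]:
    """Half-integer offsets -window .. +window in steps of 1."""
    if window <= 0 or (window * 2) % 2 != 1:
        raise ValueError(f"window must be a positive half-integer, got {window}")
    n = int(window + 0.5)
    return [i + 0.5 for i in range(-n, n)]


def build_induction_track(pair: NormalizedPair, floor: int = DEFAULT_FLOOR) -> InductionTrack:
    """Compute both channels over the union of keys of the two tracks.

    A key absent from one track is treated as count 0 there (then floored for
    the ratio channel).  Flooring clamps *both* cellular and scaled-naked
    values, bounding the ratio in both directions.
    """
    if floor < 1:
        raise ValueError("floor must be >= 1")
    cell = pair.cellular.counts
    naked = pair.naked_scaled.counts
    induction: dict[TrackKey, float] = {}
    logratio: dict[TrackKey, float] = {}
    for key in cell.keys() | naked.keys():
        c = cell.get(key, 0)
        n = naked.get(key, 0)
        induction[key] = c - n
        logratio[key] = math.log2(max(c, floor) / max(n, floor))
    return InductionTrack(induction=induction, log2_floored=logratio, floor=floor)


def _offset_position(site: MotifOccurrence, offset: float) -> float:
    """Genomic half position read by motif-frame `offset` at `site`."""
    return site.anchor + offset if site.strand == "+" else site.anchor - offset


def site_profile(
    track: InductionTrack,
    genome: GenomeSequence,
    site: MotifOccurrence,
    window: float,
) -> SiteProfile:
    """Project induction and log-ratio values into the site's motif frame."""
    offsets = window_offsets(window)
    ind_vals: list[float] = []
    log_vals: list[float] = []
    dipy: list[bool] = []
    partial = False
    chrom_len = genome.length(site.chrom)
    for o in offsets:
        h = _offset_position(site, o)
        p = int(h - 0.5)
        if p < 0 or p + 2 > chrom_len:
            partial = True
            ind_vals.append(0.0)
            log_vals.append(0.0)
            dipy.append(False)
            continue
        ind = 0.0
        logr = 0.0
        has = False
        for strand in ("+", "-"):
            key = (site.chrom, strand, h)
            ind += track.induction.get(key, 0.0)
            logr += track.log2_floored.get(key, 0.0)
            has = has or is_dipyrimidine_site(genome, site.chrom, strand, h)
        ind_vals.append(ind if has else 0.0)
        log_vals.append(logr if has else 0.0)
        dipy.append(has)
    return SiteProfile(site, offsets, ind_vals, log_vals, dipy, partial)


def aggregate_profile(
    track: InductionTrack,
    genome: GenomeSequence,
    sites: list[MotifOccurrence],
    window: float,
    denominator_mode: str = "per_dipy_site",
) -> AggregateProfile:
    """Per-offset average induction across sites.

    ``per_site`` divides each offset's total by the number of sites analyzed;
    ``per_dipy_site`` divides by the number of sites carrying a lesion-forming
    dipyrimidine at that offset.  Sites whose window runs off the chromosome
    are excluded (counted in the log).
    """
    if not sites:
        raise ValueError("no sites to aggregate")
    if denominator_mode not in ("per_site", "per_dipy_site"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    offsets = window_offsets(window)
    total = np.zeros(len(offsets))
    n_dipy = np.zeros(len(offsets), dtype=int)
    n_used = 0
    n_skipped = 0
    for site in sites:
        prof = site_profile(track, genome, site, window)
        if prof.partial:
            n_skipped += 1
            continue
        total += np.asarray(prof.induction_values)
        n_dipy += np.asarray(prof.has_dipy, dtype=int)
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites fell too close to a chromosome edge")
    if n_skipped:
        logger.info("aggregate_profile: skipped %d edge-partial sites", n_skipped)
    if denominator_mode == "per_site":
        avg = total / n_used
    else:
        with np.errstate(invalid="ignore"):
            avg = np.where(n_dipy > 0, total / np.maximum(n_dipy, 1), 0.0)
    return AggregateProfile(
        offsets=offsets,
        total_induction=total.tolist(),
        n_sites=n_used,
        n_dipy_sites=n_dipy.tolist(),
        average_induction=avg.tolist(),
        denominator_mode=denominator_mode,
    )


def site_matrix(
    track: InductionTrack,
    genome: GenomeSequence,
    sites: list[MotifOccurrence],
    window: float,
) -> np.ndarray:
    """Per-site induction rows (site order preserved), one column per offset."""
    if not sites:
        raise ValueError("no sites")
    rows = [
        site_profile(track, genome, site, window).induction_values
        for site in sites
    ]
    return np.asarray(rows)


def dipyrimidine_content(
    genome: GenomeSequence,
    sites: list[MotifOccurrence],
    window: float,
) -> dict:
    """Per-offset fraction of sites with a lesion-forming dipyrimidine.

    Also reports how many offsets have fraction 1.0 and >= 0.75, the summary
    used to judge whether a motif class is amenable to damage fingerprinting.
    """
    if not sites:
        raise ValueError("no sites")
    offsets = window_offsets(window)
    counts = np.zeros(len(offsets), dtype=int)
    for site in sites:
        for i, o in enumerate(offsets):
            h = _offset_position(site, o)
            p = int(h - 0.5)
            if p < 0 or p + 2 > genome.length(site.chrom):
                continue
            if is_dipyrimidine_site(genome, site.chrom, "+", h) or is_dipyrimidine_site(
                genome, site.chrom, "-", h
            ):
                counts[i] += 1
    fractions = counts / len(sites)
    return {
        "offsets": offsets,
        "fractions": fractions.tolist(),
        "n_offsets_full": int(np.sum(fractions == 1.0)),
        "n_offsets_75": int(np.sum(fractions >= 0.75)),
    }
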