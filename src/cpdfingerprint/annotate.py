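"""Downstream annotation of predicted binding sites.

Compares calls with orthogonal peak sets (e.g. ChIP-exo), assigns the nearest
transcription start site, summarizes TSS-distance distributions, filters
differential-expression tables, and tests gene-set overlap with the exact
hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .classify import PredictionSet
from .genome_io import GenomicInterval, MotifOccurrence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    condition: str
    log2_ratio: float
    p_value: float


def load_tss_table(path) -> list[GeneAnnotation]:
    """Tab-separated (gene_id, chrom, tss_1based, strand) -> 0-based annotations."""
    df = pd.read_csv(
        str(path), sep="\t", comment="#",
        names=["gene_id", "chrom", "tss_1based", "strand"], header=None,
    )
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in TSS table")
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.tss_1based) - 1, r.strand)
        for r in df.itertuples()
    ]


def load_expression_table(path) -> list[ExpressionRecord]:
    """Tab-separated (gene_id, condition, log2_ratio, p_value)."""
    df = pd.read_csv(
        str(path), sep="\t", comment="#",
        names=["gene_id", "condition", "log2_ratio", "p_value"], header=None,
    )
    return [
        ExpressionRecord(r.gene_id, r.condition, float(r.log2_ratio), float(r.p_value))
        for r in df.itertuples()
    ]


def _peak_distance(anchor: int, peak: GenomicInterval) -> int:
    if peak.start <= anchor < peak.end:
        return 0
    if anchor < peak.start:
        return peak.start - anchor
    return anchor - (peak.end - 1)


def categorize_by_peaks(
    predictions: PredictionSet,
    training_ids: set[str],
    peaks: list[GenomicInterval],
    max_distance: int = 50,
) -> dict[str, str]:
    """Per-site category: training > peak_discovered (within max_distance bp) > new."""
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    categories: dict[str, str] = {}
    for site, _, label in predictions.calls:
        if label != "bound":
            continue
        if site.site_id in training_ids:
            categories[site.site_id] = "training"
            continue
        near = any(
            _peak_distance(site.anchor, p) <= max_distance
            for p in peaks_by_chrom.get(site.chrom, [])
        )
        categories[site.site_id] = "peak_discovered" if near else "new"
    n_with_peak = sum(1 for c in categories.values() if c != "new")
    logger.info(
        "categorize_by_peaks: %d/%d bound sites within %d bp of a peak",
        n_with_peak, len(categories), max_distance,
    )
    return categories


def assign_target_genes(
    predictions: PredictionSet,
    genes: list[GeneAnnotation],
    max_distance: int | None = None,
) -> dict[str, str | None]:
    """Nearest-TSS gene per bound site; ties break to the smaller gene_id."""
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assignment: dict[str, str | None] = {}
    for site, _, label in predictions.calls:
        if label != "bound":
            continue
        chrom_genes = by_chrom.get(site.chrom)
        if not chrom_genes:
            logger.warning("no genes on %s; site %s unassigned", site.chrom, site.site_id)
            assignment[site.site_id] = None
            continue
        best = min(chrom_genes, key=lambda g: (abs(g.tss - site.anchor), g.gene_id))
        dist = abs(best.tss - site.anchor)
        if max_distance is not None and dist > max_distance:
            assignment[site.site_id] = None
        else:
            assignment[site.site_id] = best.gene_id
    return assignment


def signed_tss_distance(site: MotifOccurrence, gene: GeneAnnotation) -> int:
    """Distance from the TSS, negative upstream of the gene, positive downstream."""
    return site.anchor - gene.tss if gene.strand == "+" else gene.tss - site.anchor


def tss_distance_histogram(
    predictions: PredictionSet,
    genes: list[GeneAnnotation],
    bins: list[float],
    categories: dict[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Binned fractions of signed site-to-nearest-TSS distances per category.

    ``bins`` are ordered breakpoints; distances below the first or at/above
    the last breakpoint fall in explicit underflow/overflow bins.  Fractions
    per category sum to 1.
    """
    if not bins or sorted(bins) != list(bins):
        raise ValueError("bins must be ordered breakpoints")
    gene_index = {g.gene_id: g for g in genes}
    nearest = assign_target_genes(predictions, genes)
    labels = (
        [f"<{bins[0]:g}"]
        + [f"[{a:g},{b:g})" for a, b in zip(bins, bins[1:])]
        + [f">={bins[-1]:g}"]
    )
    counts: dict[str, dict[str, int]] = {}
    for site, _, label in predictions.calls:
        if label != "bound":
            continue
        gene_id = nearest.get(site.site_id)
        if gene_id is None:
            continue
        d = signed_tss_distance(site, gene_index[gene_id])
        cat = categories.get(site.site_id, "all") if categories else "all"
        idx = 0 if d < bins[0] else next(
            (i + 1 for i, (a, b) in enumerate(zip(bins, bins[1:])) if a <= d < b),
            len(labels) - 1,
        )
        counts.setdefault(cat, {lab: 0 for lab in labels})[labels[idx]] += 1
    result: dict[str, dict[str, float]] = {}
    for cat, binned in counts.items():
        total = sum(binned.values())
        result[cat] = {lab: n / total for lab, n in binned.items()}
    return result


def filter_de_genes(
    expr: list[ExpressionRecord],
    p_max: float = 1e-6,
    lfc_threshold: float = 0.5,
    direction: str = "down",
    conditions: list[str] | None = None,
) -> set[str]:
    """Genes significant in ANY of the requested conditions (strict p < p_max).

    ``down`` requires log2 ratio <= -lfc_threshold, ``up`` >= +lfc_threshold.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    selected: set[str] = set()
    for rec in expr:
        if conditions is not None and rec.condition not in conditions:
            continue
        if not rec.p_value < p_max:
            continue
        if direction == "down" and rec.log2_ratio <= -lfc_threshold:
            selected.add(rec.gene_id)
        elif direction == "up" and rec.log2_ratio >= lfc_threshold:
            selected.add(rec.gene_id)
    return selected


def hypergeometric_overlap(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float, float, float]:
    """Exact upper-tail P(overlap >= observed) drawing |A| from the universe.

    Returns (overlap, overlap/|A|, overlap/|B|, p_value).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    overlap = len(set_a & set_b)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(set_b), len(set_a)))
    frac_a = overlap / len(set_a) if set_a else 0.0
    frac_b = overlap / len(set_b) if set_b else 0.0
    return overlap, frac_a, frac_b, p
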