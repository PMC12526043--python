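"""Cross-TF atlas of average damage-induction profiles and 2-D embedding.

Each transcription factor contributes one row: the average CPD induction at
the 12 half-integer offsets -5.5 .. +5.5 around its motif anchor.  Rows are
embedded with UMAP so that factors inducing similar damage fingerprints land
near each other; an external profile (e.g. a human NF-Y row computed from
capture-seq data) can be appended and embedded jointly with the native rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import InductionTrack, aggregate_profile
from .genome_io import GenomeSequence, MotifOccurrence

ATLAS_WINDOW = 5.5
N_ATLAS_OFFSETS = 12


@dataclass
class TFProfileMatrix:
    tf_ids: list[str]
    rows: np.ndarray  # shape (n_tfs, 12)
    denominator_mode: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != N_ATLAS_OFFSETS:
            raise ValueError(
                f"profile matrix must have {N_ATLAS_OFFSETS} columns"
            )
        if len(self.tf_ids) != self.rows.shape[0]:
            raise ValueError("tf_ids must match row count")


def _dedupe_sites(sites: list[MotifOccurrence]) -> list[MotifOccurrence]:
    """Keep the first instance of each (chrom, anchor, strand) position."""
    seen: set[str] = set()
    uniq = []
    for site in sites:
        if site.site_id not in seen:
            seen.add(site.site_id)
            uniq.append(site)
    return uniq


def build_profile_matrix(
    track: InductionTrack,
    genome: GenomeSequence,
    site_sets: dict[str, list[MotifOccurrence]],
    denominator_mode: str = "per_site",
) -> TFProfileMatrix:
    """One averaged-induction row per TF over offsets -5.5 .. +5.5."""
    tf_ids = []
    rows = []
    for tf_id, sites in site_sets.items():
        uniq = _dedupe_sites(sites)
        if not uniq:
            raise ValueError(f"TF {tf_id!r} has no sites after deduplication")
        prof = aggregate_profile(
            track, genome, uniq, ATLAS_WINDOW, denominator_mode=denominator_mode
        )
        tf_ids.append(tf_id)
        rows.append(prof.average_induction)
    return TFProfileMatrix(tf_ids, np.asarray(rows), denominator_mode)


def embed_profiles(
    matrix: TFProfileMatrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> dict[str, tuple[float, float]]:
    """Seed-deterministic UMAP embedding of the profile rows."""
    if matrix.rows.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, "
            f"got {matrix.rows.shape[0]}"
        )
    import umap  # deferred: numba compilation makes this import heavy

    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        random_state=seed,
    )
    coords = reducer.fit_transform(matrix.rows)
    return {
        tf_id: (float(x), float(y))
        for tf_id, (x, y) in zip(matrix.tf_ids, coords)
    }


def append_external_profile(
    matrix: TFProfileMatrix, profile_row, tf_id: str
) -> TFProfileMatrix:
    """Extend the matrix with an externally computed 12-value profile row."""
    row = np.asarray(profile_row, dtype=float).ravel()
    if row.shape != (N_ATLAS_OFFSETS,):
        raise ValueError(f"external profile must have {N_ATLAS_OFFSETS} values")
    if tf_id in matrix.tf_ids:
        raise ValueError(f"tf_id {tf_id!r} already present")
    return TFProfileMatrix(
        matrix.tf_ids + [tf_id],
        np.vstack([matrix.rows, row]),
        matrix.denominator_mode,
    )


def remove_profile(matrix: TFProfileMatrix, tf_id: str) -> TFProfileMatrix:
    if tf_id not in matrix.tf_ids:
        raise ValueError(f"tf_id {tf_id!r} not present")
    keep = [i for i, t in enumerate(matrix.tf_ids) if t != tf_id]
    return TFProfileMatrix(
        [matrix.tf_ids[i] for i in keep],
        matrix.rows[keep],
        matrix.denominator_mode,
    )
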