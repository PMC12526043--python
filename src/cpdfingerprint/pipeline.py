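"""End-to-end glue: simulation through classification with known truth.

These helpers run the whole analysis on simulator output so that recovery of
planted binding sites can be measured against ground truth: simulate counts,
(optionally) round-trip them through read emission and lesion assignment,
normalize, build the induction track, extract fingerprint features for the
planted bound and decoy sites, and cross-validate a classifier.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import classify, fingerprint, lesion_map, simulate
from .classify import FeatureSchema, TrainingSet


def induction_from_truth(
    truth: simulate.SimTruth, via_reads: bool = False, floor: int = 10
) -> fingerprint.InductionTrack:
    """Induction track from simulated counts.

    With ``via_reads`` the counts are first converted to damage-seq reads and
    re-assigned to lesions (an exact round trip away from chromosome edges),
    exercising the read convention end to end.
    """
    cellular, naked = truth.cellular, truth.naked
    if via_reads:
        rl = truth.config.read_length
        cellular = lesion_map.reads_to_lesions(
            simulate.emit_reads(cellular, truth.genome, rl), truth.genome, "cellular"
        )
        naked = lesion_map.reads_to_lesions(
            simulate.emit_reads(naked, truth.genome, rl), truth.genome, "naked"
        )
    pair = lesion_map.normalize_pair(cellular, naked)
    return fingerprint.build_induction_track(pair, floor=floor)


def schema_from_config(cfg: simulate.SimConfig) -> FeatureSchema:
    """Feature schema reading both channels at the modulated offsets."""
    return FeatureSchema(cfg.motif, tuple(sorted(cfg.modulation)))


def truth_training_set(
    truth: simulate.SimTruth,
    track: fingerprint.InductionTrack,
    schema: FeatureSchema | None = None,
) -> TrainingSet:
    """Planted bound sites as positives, planted decoys as negatives."""
    schema = schema or schema_from_config(truth.config)
    sites = truth.bound_sites + truth.decoy_sites
    X = np.vstack([
        classify.extract_features(track, truth.genome, s, schema) for s in sites
    ])
    y = np.array([1] * len(truth.bound_sites) + [0] * len(truth.decoy_sites))
    return TrainingSet(schema, X, y, [s.site_id for s in sites], seed=truth.config.seed)


def recovery_metrics(
    cfg: simulate.SimConfig,
    algorithm: str = "random_forest",
    k: int = 5,
    threshold: float = 0.5,
    via_reads: bool = False,
) -> dict:
    """Out-of-fold recovery of planted sites vs decoys for one seed.

    Sensitivity is the fraction of planted bound sites called bound from the
    pooled out-of-fold probabilities; false positives are decoys called bound.
    """
    truth = simulate.simulate(cfg)
    track = induction_from_truth(truth, via_reads=via_reads)
    ts = truth_training_set(truth, track)
    report = classify.cross_validate(
        ts, algorithm=algorithm, k=k, seed=cfg.seed, threshold=threshold
    )
    tn, fp = report.confusion[0]
    fn, tp = report.confusion[1]
    return {
        "sensitivity": tp / (tp + fn),
        "false_positives": int(fp),
        "false_positive_rate": fp / (tn + fp),
        "auc": report.auc,
        "n_bound": int(tp + fn),
        "n_decoys": int(tn + fp),
    }


def null_auc(cfg: simulate.SimConfig, algorithm: str = "random_forest", k: int = 5) -> float:
    """Cross-validated AUC when modulation is flat (no binding effect)."""
    flat = replace(cfg, modulation={o: 1.0 for o in cfg.modulation})
    return recovery_metrics(flat, algorithm=algorithm, k=k)["auc"]
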