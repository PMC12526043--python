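import numpy as np
import pytest

from cpdfingerprint import pipeline
from cpdfingerprint.genome_io import GenomeSequence
from cpdfingerprint.simulate import SimConfig, simulate


@pytest.fixture
def tiny_genome():
    # CCAAT at 1..6 (plus) and an ATTGG (minus-strand CCAAT) further right
    return GenomeSequence({"chr1": "ACCAATGGCATTGGAT"})


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated data set for structural (exactness) tests."""
    cfg = SimConfig(
        genome_length=20_000,
        n_orfs=4,
        orf_length=3_000,
        n_bound_sites=10,
        n_decoy_sites=100,
        target_median_naked=2.0,
        seed=5,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """One realization of the default study-scale simulation."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_induction(default_truth):
    return pipeline.induction_from_truth(default_truth)


@pytest.fixture(scope="session")
def default_training_set(default_truth, default_induction):
    return pipeline.truth_training_set(default_truth, default_induction)


N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def multiseed_recovery():
    """Planted-site recovery and null-model metrics across 20 seeds.

    Computed once per session; shared by the classifier-invariant tests and
    the simulation-property acceptance tests.
    """
    from cpdfingerprint import classify

    rf, mlp, null = [], [], []
    for seed in range(N_RECOVERY_SEEDS):
        cfg = SimConfig(seed=seed)
        truth = simulate(cfg)
        track = pipeline.induction_from_truth(truth)
        ts = pipeline.truth_training_set(truth, track)
        for algorithm, sink in (("random_forest", rf), ("multilayer_perceptron", mlp)):
            report = classify.cross_validate(ts, algorithm, k=5, seed=seed)
            tn, fp = report.confusion[0]
            fn, tp = report.confusion[1]
            sink.append({
                "sensitivity": tp / (tp + fn),
                "false_positives": int(fp),
                "false_positive_rate": fp / (tn + fp),
                "auc": report.auc,
            })
        null.append(pipeline.null_auc(cfg))
    return {"random_forest": rf, "multilayer_perceptron": mlp, "null_auc": null}
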