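import numpy as np
import pandas as pd
import pytest

import sigevolve as sv


@pytest.fixture(scope="session")
def small_dataset():
    """50+50 samples, 100 genes, 5+5 planted at effect 2 (log2 units)."""
    design = sv.SimulationDesign(
        n_pos=50, n_neg=50, n_genes=100, n_up=5, n_down=5,
        effect_size=2.0, noise_sd=1.0, seed=42,
    )
    return sv.gen_two_class_expression(design)


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    matrix, labels, _ = small_dataset
    ranked = sv.rank_genes(sv.signal_to_noise(matrix, labels))
    return sv.screen_candidates(ranked, None, n_per_tail=50, restrict_to_sets=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_confusions(rng, n, high=200):
    """Random non-degenerate confusion tables."""
    tables = []
    while len(tables) < n:
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, high, size=4))
        if tp + tn + fp + fn >= 1:
            tables.append(sv.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return tables


def confusion_to_vectors(cc):
    """Binary truth/prediction vectors realizing a confusion table."""
    truth = np.concatenate(
        [np.ones(cc.tp), np.ones(cc.fn), np.zeros(cc.tn), np.zeros(cc.fp)]
    )
    pred = np.concatenate(
        [np.ones(cc.tp), np.zeros(cc.fn), np.zeros(cc.tn), np.ones(cc.fp)]
    )
    return truth, pred
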