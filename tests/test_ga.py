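"""GA operators and the cross-validated SVM fitness."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

import sigevolve as sv
from sigevolve import metrics
from sigevolve.datatypes import ConfusionCounts, SolutionRecord
from sigevolve.ga import (
    FitnessEvaluator,
    GAConfig,
    GAState,
    SVMFitnessConfig,
    crossover,
    evaluate_fitness,
    init_population,
    mutate,
    run_ga,
    run_selection_procedure,
    select_elites,
)

FAST = SVMFitnessConfig(exp_step=4)


def _tiny_dataset(seed=0, n=30, genes=12, informative=4, effect=2.0):
    design = sv.SimulationDesign(
        n_pos=n // 2, n_neg=n - n // 2, n_genes=genes,
        n_up=informative // 2, n_down=informative - informative // 2,
        effect_size=effect, seed=seed,
    )
    m, y, truth = sv.gen_two_class_expression(design)
    return m.data, y, truth


# -- configs -----------------------------------------------------------------

def test_config_validation():
    with pytest.raises(sv.ValidationError):
        GAConfig(population_size=7)
    with pytest.raises(sv.ValidationError):
        GAConfig(mutation_threshold=1.5)
    with pytest.raises(sv.ValidationError):
        SVMFitnessConfig(folds=1)
    with pytest.raises(sv.ValidationError):
        SVMFitnessConfig(fitness_measure="auc")
    assert len(SVMFitnessConfig().exponents) == 31
    assert len(FAST.exponents) == 8


# -- population operators ----------------------------------------------------

def test_init_population_shape_and_density(rng):
    cfg = GAConfig()
    pop = init_population(cfg, rng, n_bits=100)
    assert pop.shape == (80, 100)
    assert pop.any(axis=1).all()  # no all-zero chromosome
    mean_bits = pop.sum(axis=1).mean()
    # Binomial(100, .5) mean over 80 chromosomes: generous 4-sigma band
    assert abs(mean_bits - 50) < 4 * 5 / np.sqrt(80)


def _state(pop):
    return GAState(population=pop)


def test_select_elites_tie_takes_lowest_index():
    pop = np.array([[1, 0], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
    fits = np.array([0.5, 0.5, 0.5, 0.5])
    state = select_elites(_state(pop), fits)
    assert np.array_equal(state.alpha.bits, [1, 0])
    assert np.array_equal(state.beta.bits, [1, 1])
    # population repopulated alternating alpha/beta (1-based odd/even)
    assert np.array_equal(state.population, [[1, 0], [1, 1], [1, 0], [1, 1]])


def test_select_elites_keeps_better_previous_elite():
    pop = np.array([[1, 0], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
    prev = GAState(
        population=pop,
        alpha=SolutionRecord(np.array([1, 1], dtype=np.int8), 0.9),
        beta=SolutionRecord(np.array([0, 1], dtype=np.int8), 0.1),
    )
    state = select_elites(prev, np.array([0.5, 0.2, 0.6, 0.3]))
    assert state.alpha.fitness == 0.9  # previous alpha survives
    assert state.beta.fitness == 0.6   # current second half wins
    assert state.omega.fitness == 0.9


def test_omega_fitness_monotone_over_updates(rng):
    state = _state((rng.random((8, 10)) < 0.5).astype(np.int8))
    best = -np.inf
    for _ in range(20):
        fits = rng.random(8)
        state = select_elites(state, fits)
        assert state.omega.fitness >= best
        best = state.omega.fitness
        state.population = (rng.random((8, 10)) < 0.5).astype(np.int8)


def test_mutate_thresholds_zero_and_one(rng):
    cfg0 = GAConfig(population_size=8, mutation_threshold=0.0)
    pop = (rng.random((8, 20)) < 0.5).astype(np.int8)
    out = mutate(pop, cfg0, rng)
    assert np.array_equal(out[:4], pop[:4])  # first half untouched
    for i in range(4, 8):  # second half: exactly one flip each
        assert (out[i] != pop[i]).sum() == 1
    cfg1 = GAConfig(population_size=8, mutation_threshold=1.0)
    out = mutate(pop, cfg1, rng)
    assert np.array_equal(out[:4], 1 - pop[:4])  # fully complemented


def test_mutate_first_half_flip_rate(rng):
    cfg = GAConfig(population_size=80, mutation_threshold=0.1)
    pop = np.zeros((80, 100), dtype=np.int8)
    flips = []
    for _ in range(25):
        out = mutate(pop, cfg, rng)
        flips.append(out[:40].sum(axis=1))
    mean = np.concatenate(flips).mean()  # 1,000 chromosomes
    assert abs(mean - 10.0) < 4 * 3.0 / np.sqrt(1000)


def test_crossover_rate_zero_is_identity(rng):
    cfg = GAConfig(population_size=8, crossover_threshold=0.0)
    pop = (rng.random((8, 20)) < 0.5).astype(np.int8)
    assert np.array_equal(crossover(pop, cfg, rng), pop)


def test_crossover_swaps_tails_and_conserves_bits(rng):
    cfg = GAConfig(population_size=40, crossover_threshold=1.0)
    pop = (rng.random((40, 30)) < 0.5).astype(np.int8)
    out = crossover(pop, cfg, rng)
    for k in range(0, 40, 2):
        a0, b0, a1, b1 = pop[k], pop[k + 1], out[k], out[k + 1]
        # per-position multiset conserved within the pair
        assert np.array_equal(a0 + b0, a1 + b1)
        # one-point structure: prefix kept, suffix swapped at some cut
        diff = np.flatnonzero(a0 != a1)
        if diff.size:
            lam = diff[0]
            assert np.array_equal(a1[lam:], b0[lam:])
            assert np.array_equal(b1[lam:], a0[lam:])
            assert np.array_equal(a1[:lam], a0[:lam])


# -- fitness -----------------------------------------------------------------

def test_separable_data_gives_perfect_mcc():
    X, y, truth = _tiny_dataset(seed=1, n=40, genes=10, informative=4, effect=5.0)
    informative_bits = np.array(
        [g in truth.planted for g in X.index], dtype=np.int8
    )
    fit = evaluate_fitness(informative_bits, X, y, SVMFitnessConfig(exp_step=4, fitness_measure="mcc"), seed=3)
    assert fit == pytest.approx(1.0)


def test_fitness_deterministic_for_same_seed():
    X, y, _ = _tiny_dataset(seed=2)
    bits = np.ones(len(X), dtype=np.int8)
    cfg = SVMFitnessConfig(exp_step=8, fitness_measure="f1")
    assert evaluate_fitness(bits, X, y, cfg, seed=5) == evaluate_fitness(bits, X, y, cfg, seed=5)


def test_permuted_labels_give_near_zero_mcc():
    X, y, _ = _tiny_dataset(seed=3, n=100, genes=20, informative=6, effect=2.0)
    rng = np.random.default_rng(7)
    cfg = SVMFitnessConfig(exp_step=8, fitness_measure="mcc")
    bits = np.ones(len(X), dtype=np.int8)
    fits = []
    for _ in range(20):
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        fits.append(evaluate_fitness(bits, X, perm, cfg, seed=1))
    assert abs(np.median(fits)) < 0.3


def test_all_zero_chromosome_sentinels():
    X, y, _ = _tiny_dataset(seed=4)
    zero = np.zeros(len(X), dtype=np.int8)
    assert evaluate_fitness(zero, X, y, SVMFitnessConfig(fitness_measure="mcc")) == -1.0
    assert evaluate_fitness(zero, X, y, SVMFitnessConfig(fitness_measure="acc")) == 0.0


def _reference_fitness(bits, X, y, cfg, fold_seed, measure):
    """Independent oracle: public sklearn SVC over the same folds and grid."""
    Xs = X.to_numpy().T[:, bits.astype(bool)]
    yv = y.to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(Xs, yv))
    balance = sv.ClassBalance(int(yv.sum()), int((1 - yv).sum()))
    best = -np.inf
    for ge in cfg.exponents:
        for ce in cfg.exponents:
            pred = np.empty_like(yv)
            for tr, te in folds:
                model = SVC(C=2.0 ** ce, gamma=2.0 ** ge, kernel="rbf")
                model.fit(Xs[tr], yv[tr])
                pred[te] = model.predict(Xs[te])
            cc = ConfusionCounts(
                tp=int(((pred == 1) & (yv == 1)).sum()),
                tn=int(((pred == 0) & (yv == 0)).sum()),
                fp=int(((pred == 1) & (yv == 0)).sum()),
                fn=int(((pred == 0) & (yv == 1)).sum()),
            )
            value = (
                metrics.hybrid(cc, balance)
                if measure == "hybrid"
                else getattr(metrics, {"acc": "accuracy"}.get(measure, measure))(cc)
            )
            best = max(best, value)
    return best


@pytest.mark.parametrize("measure", ["acc", "mcc", "f1", "hybrid"])
def test_fast_fitness_agrees_with_public_svc_oracle(measure):
    """Precomputed-kernel libsvm path equals sklearn.svm.SVC grid search."""
    X, y, _ = _tiny_dataset(seed=5, n=30, genes=10, informative=4, effect=1.0)
    cfg = SVMFitnessConfig(exp_min=-11, exp_max=9, exp_step=5, fitness_measure=measure)
    rng = np.random.default_rng(1)
    ev = FitnessEvaluator(X, y, cfg, fold_seed=9)
    for _ in range(4):
        bits = (rng.random(len(X)) < 0.6).astype(np.int8)
        if not bits.any():
            continue
        got = ev.evaluate(bits, measure)
        want = _reference_fitness(bits, X, y, cfg, fold_seed=9, measure=measure)
        assert got == pytest.approx(want, abs=1e-9)


# -- GA runs -----------------------------------------------------------------

def test_run_ga_record_count_and_monotonicity():
    X, y, _ = _tiny_dataset(seed=6, n=30, genes=10, informative=4)
    ga_cfg = GAConfig(population_size=8, generations=12, seed=3)
    records = run_ga(X, y, "acc", ga_cfg, SVMFitnessConfig(exp_step=8))
    assert len(records) == 12
    fits = [r.fitness for r in records]
    assert fits == sorted(fits)


def test_run_ga_improves_over_initial_best():
    """On improvable data the GA beats the initial population's best."""
    wins = 0
    for seed in range(10):
        X, y, _ = _tiny_dataset(seed=100 + seed, n=60, genes=24, informative=4, effect=1.0)
        ga_cfg = GAConfig(population_size=20, generations=20, seed=seed)
        records = run_ga(X, y, "mcc", ga_cfg, SVMFitnessConfig(exp_step=4, fitness_measure="mcc"))
        if records[-1].fitness > records[0].fitness:
            wins += 1
    assert wins >= 9


def test_selection_procedure_counts_dedup_and_determinism():
    X, y, _ = _tiny_dataset(seed=7, n=30, genes=10, informative=4)
    ga_cfg = GAConfig(population_size=8, generations=5, repeats=3, seed=11)
    svm_cfg = SVMFitnessConfig(exp_step=8)
    archive = run_selection_procedure(X, y, ga_cfg, svm_cfg, measures=("acc", "mcc"))
    for measure in ("acc", "mcc"):
        assert len(archive.records[measure]) == 15  # repeats x generations
        top = archive.ranked(measure, 10)
        keys = {tuple(r.bits) for r in top}
        assert len(keys) == len(top)  # dedup
        fits = [r.fitness for r in top]
        assert fits == sorted(fits, reverse=True)
    again = run_selection_procedure(X, y, ga_cfg, svm_cfg, measures=("acc", "mcc"))
    for measure in ("acc", "mcc"):
        assert len(again.records[measure]) == len(archive.records[measure])
        for a, b in zip(archive.records[measure], again.records[measure]):
            assert a.fitness == b.fitness and np.array_equal(a.bits, b.bits)
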