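"""Synthetic generators: reproducibility, truth recovery, model invariants."""

import random

import numpy as np
import pytest

from karyoevo import (
    classify_morphology,
    recovery_experiment,
    simulate_character,
    simulate_karyotype,
)
from karyoevo.errors import ConfigError
from karyoevo.parsimony import reconstruct
from karyoevo.synthetic import history_to_matrix, measurements_to_karyotype

from conftest import random_tree


def test_simulate_karyotype_reproducible_under_seed():
    m1, t1 = simulate_karyotype(seed=11)
    m2, t2 = simulate_karyotype(seed=11)
    assert m1.equals(m2)
    assert t1 == t2
    m3, _ = simulate_karyotype(seed=12)
    assert not m1.equals(m3)


def test_noise_free_measurements_classify_perfectly():
    for seed in range(20):
        measurements, truth = simulate_karyotype(noise_sd=0.0, seed=seed)
        k = measurements_to_karyotype(measurements)
        assert tuple(p.morphology for p in k.pairs) == truth.morphology


def test_misclassification_concentrates_near_thresholds():
    """With mild noise, errors happen essentially only when the true CI is
    within ~2 noise-sd of a class boundary."""
    noise = 0.05
    boundaries = (0.125, 0.25, 0.37)
    far_errors = near_total = far_total = 0
    for seed in range(300):
        measurements, truth = simulate_karyotype(
            n_pairs=12, noise_sd=noise, seed=seed
        )
        k = measurements_to_karyotype(measurements)
        for pair, true_ci, true_m in zip(k.pairs, truth.ci, truth.morphology):
            # delta-method sd of the measured CI under per-arm log-normal noise
            ci_sd = noise * np.sqrt(2.0) * true_ci * (1.0 - true_ci)
            near = min(abs(true_ci - b) for b in boundaries) < 2 * ci_sd
            if near:
                near_total += 1
            else:
                far_total += 1
                far_errors += pair.morphology is not true_m
    assert far_total > 1000  # plenty of unambiguous pairs simulated
    assert far_errors / far_total < 0.01


def test_simulate_karyotype_rejects_bad_params():
    with pytest.raises(ConfigError):
        simulate_karyotype(n_pairs=0)
    with pytest.raises(ConfigError):
        simulate_karyotype(noise_sd=-0.1)


def test_simulate_character_reproducible_and_consistent():
    rng = random.Random(0)
    tree = random_tree(rng, 16)
    h1 = simulate_character(tree, 0.3, seed=5)
    h2 = simulate_character(tree, 0.3, seed=5)
    assert h1 == h2
    # tip states follow from the change list applied down the tree
    keys = tree.node_keys()
    state = {keys[id(tree.root)]: h1.root_state}
    changes = {(p, c): t for p, c, _, t in h1.changes}
    for node in tree.preorder():
        for child in node.children:
            pk, ck = keys[id(node)], keys[id(child)]
            state[ck] = changes.get((pk, ck), state[pk])
    for leaf in tree.leaves():
        assert h1.tip_states[leaf.label] == state[keys[id(leaf)]]


def test_change_prob_zero_uniform_tips_zero_length():
    rng = random.Random(1)
    tree = random_tree(rng, 12)
    history = simulate_character(tree, 0.0, seed=3)
    assert set(history.tip_states.values()) == {history.root_state}
    matrix = history_to_matrix(history, ("0", "1", "2", "3"))
    assert reconstruct(tree, matrix, "sim").length == 0


def test_parsimony_length_bounded_by_realized_changes():
    rng = random.Random(2)
    tree = random_tree(rng, 16)
    for seed in range(50):
        history = simulate_character(tree, 0.15, seed=seed)
        matrix = history_to_matrix(history, ("0", "1", "2", "3"))
        assert reconstruct(tree, matrix, "sim").length <= history.n_changes


def test_recovery_experiment_summary_properties():
    rng = random.Random(3)
    tree = random_tree(rng, 16)
    table = recovery_experiment(
        tree, change_probs=(0.0, 0.05, 0.15, 0.3), replicates=60, seed=9
    )
    first = table.iloc[0]
    assert first.change_prob == 0.0
    assert first.root_recovery_freq == 1.0
    assert first.mean_length == 0.0
    # mean parsimony length grows with the change probability
    assert (np.diff(table.mean_length) >= 0).all()
    # parsimony length is a lower bound on realized changes, also in the mean
    assert (table.mean_length <= table.mean_realized_changes + 1e-12).all()
    # with little change the true root state is almost always recovered
    assert table.iloc[1].root_recovery_freq > 0.9
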