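"""Synthetic data generators with known ground truth.

Two generators mirror the statistical structure the analysis pipeline
assumes, so every stage can be exercised against a known answer:

* :func:`simulate_karyotype` emulates per-pair arm-length measurement.
  True total lengths are drawn from a right-skewed log-normal (chromosome
  size distributions are positive and long-tailed), a true centromere
  position (CI) is drawn per pair, and each arm measurement gets
  independent multiplicative log-normal noise — measurement error on a
  length scales with the length.  Pairs are ranked by measured size, as a
  cytogeneticist orders a karyogram.

* :func:`simulate_character` evolves an unordered character down a tree
  under a per-branch jump model: with probability ``change_prob`` the state
  changes to a uniformly chosen different state on each branch.  A
  per-branch probability (rather than rate x branch length) is used because
  condensed cladograms carry no meaningful branch lengths.  The full change
  history is recorded, so parsimony estimates can be compared with the
  realized number of changes (parsimony length is a lower bound on it).

* :func:`recovery_experiment` sweeps ``change_prob`` and reports how often
  the true root state is recovered in the root MPR set, alongside mean
  parsimony length vs mean realized changes and root-ambiguity frequency.

All generators are deterministic under their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import CharacterMatrix
from .errors import ConfigError, DegenerateInputError
from .karyotype import (
    CIThresholds,
    DEFAULT_THRESHOLDS,
    ChromosomePair,
    Karyotype,
    Morphology,
    centromeric_index,
    classify_morphology,
)
from .parsimony import reconstruct
from .trees import Phylogeny

__all__ = [
    "SimKaryotypeTruth",
    "SimCharacterHistory",
    "simulate_karyotype",
    "simulate_character",
    "recovery_experiment",
    "measurements_to_karyotype",
]


@dataclass(frozen=True)
class SimKaryotypeTruth:
    """Ground truth behind one simulated karyotype measurement."""

    p_len: tuple[float, ...]
    q_len: tuple[float, ...]
    ci: tuple[float, ...]
    morphology: tuple[Morphology, ...]
    noise_sd: float
    seed: int


def simulate_karyotype(
    n_pairs: int = 12,
    mean_length: float = 5.0,
    length_sigma: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    thresholds: CIThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, SimKaryotypeTruth]:
    """Simulate noisy arm-length measurements of one haploid complement.

    Returns ``(measurements, truth)``: a DataFrame with columns
    ``pair_index, p_len, q_len`` (oriented p <= q, ranked by measured total
    length, largest first) and the matching truth record.  True CI is drawn
    uniformly on [0, 0.5], covering every morphology class.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if mean_length <= 0 or length_sigma < 0:
        raise ConfigError("length distribution parameters must be positive")
    rng = np.random.default_rng(seed)
    totals = np.sort(
        rng.lognormal(mean=np.log(mean_length), sigma=length_sigma, size=n_pairs)
    )[::-1]
    true_ci = rng.uniform(0.0, 0.5, size=n_pairs)
    true_p = totals * true_ci
    true_q = totals - true_p
    meas_p = true_p * np.exp(rng.normal(0.0, noise_sd, size=n_pairs))
    meas_q = true_q * np.exp(rng.normal(0.0, noise_sd, size=n_pairs))
    lo = np.minimum(meas_p, meas_q)  # orient so p is the short arm
    hi = np.maximum(meas_p, meas_q)
    order = np.argsort(-(lo + hi), kind="stable")  # rank by measured size
    truth = SimKaryotypeTruth(
        p_len=tuple(true_p[order]),
        q_len=tuple(true_q[order]),
        ci=tuple(true_ci[order]),
        morphology=tuple(
            classify_morphology(c, thresholds) for c in true_ci[order]
        ),
        noise_sd=noise_sd,
        seed=seed,
    )
    measurements = pd.DataFrame(
        {
            "pair_index": np.arange(1, n_pairs + 1),
            "p_len": lo[order],
            "q_len": hi[order],
        }
    )
    return measurements, truth


def measurements_to_karyotype(
    measurements: pd.DataFrame,
    species: str = "simulated",
    thresholds: CIThresholds = DEFAULT_THRESHOLDS,
) -> Karyotype:
    """Build a fully derived karyotype (CI, morphology, rel_length) from
    simulated or real arm-length measurements."""
    total = float((measurements["p_len"] + measurements["q_len"]).sum())
    if total <= 0:
        raise DegenerateInputError("zero-length complement")
    pairs = []
    for row in measurements.itertuples(index=False):
        ci = centromeric_index(row.p_len, row.q_len)
        pairs.append(
            ChromosomePair(
                pair_index=int(row.pair_index),
                p_len=float(row.p_len),
                q_len=float(row.q_len),
                ci=ci,
                morphology=classify_morphology(ci, thresholds),
                rel_length=100.0 * (row.p_len + row.q_len) / total,
            )
        )
    return Karyotype(species=species, pairs=pairs, source="simulated")


@dataclass(frozen=True)
class SimCharacterHistory:
    """One realized character history on a tree."""

    root_state: str
    tip_states: dict[str, str]
    changes: tuple[tuple[str, str, str, str], ...]  # (parent, child, from, to)
    change_prob: float
    seed: int

    @property
    def n_changes(self) -> int:
        return len(self.changes)


def simulate_character(
    tree: Phylogeny,
    change_prob: float,
    alphabet: tuple[str, ...] = ("0", "1", "2", "3"),
    seed: int = 0,
) -> SimCharacterHistory:
    """Evolve an unordered character down ``tree`` by per-branch jumps.

    The root state is uniform on the alphabet; along every branch the state
    jumps, with probability ``change_prob``, to a uniformly chosen
    *different* state.  Tip states are consistent with the recorded change
    list by construction.
    """
    if not 0.0 <= change_prob < 1.0:
        raise ConfigError("change_prob must be in [0, 1)")
    if len(alphabet) < 2:
        raise ConfigError("alphabet needs at least 2 states")
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise DegenerateInputError("tree must have at least 2 leaves")
    rng = np.random.default_rng(seed)
    keys = tree.node_keys()
    root_state = alphabet[rng.integers(len(alphabet))]
    states = {id(tree.root): root_state}
    changes = []
    for node in tree.preorder():
        for child in node.children:
            s = states[id(node)]
            if rng.random() < change_prob:
                others = [a for a in alphabet if a != s]
                t = others[rng.integers(len(others))]
                changes.append((keys[id(node)], keys[id(child)], s, t))
                states[id(child)] = t
            else:
                states[id(child)] = s
    return SimCharacterHistory(
        root_state=root_state,
        tip_states={leaf.label: states[id(leaf)] for leaf in leaves},
        changes=tuple(changes),
        change_prob=change_prob,
        seed=seed,
    )


def history_to_matrix(
    history: SimCharacterHistory,
    alphabet: tuple[str, ...],
    character: str = "sim",
) -> CharacterMatrix:
    """Wrap simulated tip states as a one-character matrix."""
    taxa = tuple(history.tip_states)
    return CharacterMatrix(
        taxa=taxa,
        characters=(character,),
        alphabets={character: tuple(alphabet)},
        cells={
            character: {t: frozenset({history.tip_states[t]}) for t in taxa}
        },
    )


def recovery_experiment(
    tree: Phylogeny,
    change_probs=(0.0, 0.02, 0.05, 0.1, 0.2),
    replicates: int = 100,
    alphabet: tuple[str, ...] = ("0", "1", "2", "3"),
    seed: int = 0,
) -> pd.DataFrame:
    """Parsimony root-recovery under the per-branch jump model.

    For each ``change_prob``, ``replicates`` histories are simulated and
    reconstructed; the summary row reports mean parsimony length, mean
    realized changes, the frequency with which the true root state lies in
    the root MPR set, and the frequency of an ambiguous (|MPR| > 1) root.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    root_key = tree.node_keys()[id(tree.root)]
    rng = np.random.default_rng(seed)
    rows = []
    for p in change_probs:
        lengths, realized, recovered, ambiguous = [], [], 0, 0
        for _ in range(replicates):
            rep_seed = int(rng.integers(2**31 - 1))
            history = simulate_character(tree, p, alphabet, seed=rep_seed)
            matrix = history_to_matrix(history, alphabet)
            result = reconstruct(tree, matrix, "sim")
            lengths.append(result.length)
            realized.append(history.n_changes)
            root_mpr = result.mpr[root_key]
            recovered += history.root_state in root_mpr
            ambiguous += len(root_mpr) > 1
            if result.length > history.n_changes:
                raise AssertionError(
                    "parsimony length exceeded realized changes "
                    f"(length={result.length}, realized={history.n_changes})"
                )
        rows.append(
            {
                "change_prob": p,
                "mean_length": float(np.mean(lengths)),
                "mean_realized_changes": float(np.mean(realized)),
                "root_recovery_freq": recovered / replicates,
                "root_ambiguity_freq": ambiguous / replicates,
            }
        )
    return pd.DataFrame(rows)
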