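"""Genetic-algorithm refinement of a scoring card.

The card's 400 scores are optimized directly as a real-valued genome under
the composite fitness

    Fit = w1 * AUC_cv + w2 * R,     (defaults w1 = 0.9, w2 = 0.1)

where AUC_cv is the mean held-out-fold AUC of the candidate's protein scores
over a seeded stratified fold plan, and R is the Pearson correlation between
the candidate's 400 scores and the initial (statistical) card.  The R term
regularizes the search toward the statistical estimate and guards against
overfitting the AUC.

The GA is a standard elitist continuous one: the seed population is the
initial card plus Gaussian-perturbed copies, selection is size-2 tournament,
crossover is uniform per-gene, mutation adds per-gene Gaussian noise, and all
scores are clipped to [0, 1000].  Every run is a deterministic function of
its inputs and seed.

The decision threshold is not part of the genome (the AUC fitness is
threshold-free); it is chosen after optimization as the training-accuracy-
maximizing midpoint between consecutive distinct scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .evaluation import compute_metrics, confusion, stratified_fold_plan
from .features import gdc_matrix
from .io import POSITIVE, NEGATIVE, LabeledDataset
from .scm import OPTIMIZED, SCORE_MAX, SCORE_MIN, PropensityTable


@dataclass(frozen=True)
class GaConfig:
    """Knobs of the genetic search; defaults suit desk-scale experiments."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_step: float = 50.0
    elite_count: int = 2
    w1: float = 0.9
    w2: float = 0.1
    folds: int = 10
    runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9 or self.w1 < 0 or self.w2 < 0:
            raise ValueError("fitness weights must be non-negative and sum to 1")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("rates must be probabilities")


def _fold_auc(scores: np.ndarray, is_pos: np.ndarray) -> np.ndarray:
    """Rank-based AUC (ties credited 0.5) per candidate column."""
    ranks = rankdata(scores, axis=0)
    n_pos = int(is_pos.sum())
    n_neg = len(is_pos) - n_pos
    return (ranks[is_pos].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class _FitnessEngine:
    """Precomputed feature matrix + fold plan for fast population scoring."""

    def __init__(self, train: LabeledDataset, g: int, config: GaConfig):
        self.F = gdc_matrix(train.sequences, g)
        self.y = np.asarray(train.labels) == POSITIVE
        self.plan = stratified_fold_plan(train.labels, config.folds, config.seed)
        self.w1, self.w2 = config.w1, config.w2

    def auc_cv(self, population: np.ndarray) -> np.ndarray:
        scores = self.F @ population.T  # (n, pop)
        aucs = np.zeros(population.shape[0])
        for _, test_idx in self.plan:
            aucs += _fold_auc(scores[test_idx], self.y[test_idx])
        return aucs / len(self.plan)

    def pearson(self, population: np.ndarray, initial: np.ndarray) -> np.ndarray:
        a = population - population.mean(axis=1, keepdims=True)
        b = initial - initial.mean()
        norm_a = np.linalg.norm(a, axis=1)
        norm_b = np.linalg.norm(b)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a @ b) / (norm_a * norm_b)
        r[~np.isfinite(r)] = 0.0  # zero-variance candidates correlate as 0
        return r

    def __call__(self, population: np.ndarray, initial: np.ndarray) -> np.ndarray:
        return self.w1 * self.auc_cv(population) + self.w2 * self.pearson(population, initial)


def fitness(
    candidate: PropensityTable,
    initial: PropensityTable,
    train: LabeledDataset,
    config: GaConfig,
) -> float:
    """Composite fitness w1 * AUC_cv + w2 * R of one candidate card."""
    if candidate.g != initial.g:
        raise ValueError("candidate and initial tables must share the same gap size")
    engine = _FitnessEngine(train, candidate.g, config)
    return float(engine(candidate.values[None, :], initial.values)[0])


def pearson_to_initial(candidate: PropensityTable, initial: PropensityTable) -> float:
    """Pearson correlation between a card and its initial card (R of the fitness)."""
    a, b = candidate.values, initial.values
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def choose_threshold(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Training-accuracy-maximizing midpoint between consecutive distinct scores.

    Classification is positive at score >= threshold; among equally accurate
    midpoints the smallest is returned.  A degenerate all-equal score vector
    returns that score.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == POSITIVE
    if y.all() or not y.any():
        raise ValueError("threshold selection requires both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:  # ascending, so ties keep the smallest midpoint
        acc = float(((scores >= t) == y).mean())
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)


def optimize(
    initial: PropensityTable, train: LabeledDataset, config: GaConfig
) -> PropensityTable:
    """Run the elitist GA and return the fittest card, thresholded and clipped.

    With ``generations=0`` the result is the best member of the seed
    population, which contains the unmodified initial card, so the returned
    fitness never falls below the initial card's.
    """
    if config.population_size < 2:
        raise ValueError("population_size must be >= 2")
    rng = np.random.default_rng(config.seed)
    engine = _FitnessEngine(train, initial.g, config)
    pop_size, n_genes = config.population_size, initial.values.size

    population = np.empty((pop_size, n_genes))
    population[0] = initial.values
    population[1:] = initial.values + rng.normal(
        0.0, config.mutation_step, size=(pop_size - 1, n_genes)
    )
    np.clip(population, SCORE_MIN, SCORE_MAX, out=population)
    fit = engine(population, initial.values)
    trace = [float(fit.max())]

    n_children = pop_size - config.elite_count
    for _ in range(config.generations):
        elite_idx = np.argsort(-fit, kind="stable")[: config.elite_count]
        children = np.empty((n_children, n_genes))
        filled = 0
        while filled < n_children:
            contenders = rng.integers(0, pop_size, size=4)
            p1 = contenders[0] if fit[contenders[0]] >= fit[contenders[1]] else contenders[1]
            p2 = contenders[2] if fit[contenders[2]] >= fit[contenders[3]] else contenders[3]
            c1, c2 = population[p1].copy(), population[p2].copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(n_genes) < 0.5
                c1[mask], c2[mask] = population[p2][mask], population[p1][mask]
            children[filled] = c1
            filled += 1
            if filled < n_children:
                children[filled] = c2
                filled += 1
        mutate = rng.random(children.shape) < config.mutation_rate
        children += mutate * rng.normal(0.0, config.mutation_step, size=children.shape)
        np.clip(children, SCORE_MIN, SCORE_MAX, out=children)
        population = np.vstack([population[elite_idx], children])
        fit = engine(population, initial.values)
        trace.append(float(fit.max()))

    best = int(np.argmax(fit))
    values = population[best]
    table = PropensityTable(
        g=initial.g,
        values=values,
        provenance=OPTIMIZED,
        metadata={
            "seed": config.seed,
            "fitness": float(fit[best]),
            "generations": config.generations,
            "fitness_trace": trace,
        },
    )
    train_scores = engine.F @ values
    table.threshold = choose_threshold(train_scores, train.labels)
    return table


def cross_validated_mcc(
    table: PropensityTable, dataset: LabeledDataset, folds: int, seed: int
) -> float:
    """Fold-averaged held-out MCC of a fixed card.

    Per fold the threshold is re-chosen on the in-fold scores, so the
    held-out MCC measures the card, not one lucky cutoff.
    """
    from .scm import score_dataset

    all_scores = score_dataset(dataset.sequences, table)
    labels = np.asarray(dataset.labels)
    mccs = []
    for train_idx, test_idx in stratified_fold_plan(dataset.labels, folds, seed):
        thr = choose_threshold(all_scores[train_idx], labels[train_idx])
        predicted = np.where(all_scores[test_idx] >= thr, POSITIVE, NEGATIVE)
        mccs.append(compute_metrics(confusion(labels[test_idx], predicted)).mcc)
    return float(np.mean(mccs))


def run_repeated(
    initial: PropensityTable, train: LabeledDataset, config: GaConfig
) -> PropensityTable:
    """Repeat the GA ``config.runs`` times and keep the best card by CV MCC.

    Run ``r`` uses seed ``config.seed + r``; ties in cross-validated MCC are
    broken in favour of the earlier run.
    """
    best_table, best_mcc, history = None, -np.inf, []
    for run in range(config.runs):
        table = optimize(initial, train, replace(config, seed=config.seed + run))
        mcc = cross_validated_mcc(table, train, folds=config.folds, seed=config.seed)
        history.append(mcc)
        if mcc > best_mcc:
            best_table, best_mcc = table, mcc
    assert best_table is not None
    best_table.metadata.update(
        {"selected_run": int(np.argmax(history)), "cv_mcc": best_mcc, "run_cv_mcc": history}
    )
    return best_table
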