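"""Generalized multifactor dimensionality reduction (GMDR) marker screening.

A score-based GMDR reimplementation for quantitative traits: each subject's
score is its phenotype residual after removing the null model (grand and
environment means).  For a 1- to 3-locus combination, subjects fall into
3^d genotype cells; a cell is "high" when its training-fold mean score is
positive.  Testing accuracy is the balanced accuracy of the cell labels
against the sign of the score on the held-out fold, averaged over k folds.
Cross-validation consistency of a combination is the number of folds in which
it has the best training accuracy among the combinations of its dimension.

An exhaustive 3-locus scan over a genome-wide panel is combinatorial; the
scanner therefore supports exhaustive mode for small panels and a staged
mode (default) where the top-m one-locus survivors seed the 2- and 3-locus
scans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class ScoreVector:
    """Per-subject score: mean deviation from the environment means."""

    scores: pd.Series  # index = subject ids

    @property
    def subjects(self) -> list:
        return list(self.scores.index)


@dataclass
class GMDRResult:
    loci: tuple
    testing_accuracy: float
    cv_consistency: int
    k_folds: int
    selected: bool = False


def compute_scores(p: PhenotypeTable, trait: str) -> ScoreVector:
    """Score of a subject: mean over its records of (value - environment mean)."""
    sub = p.trait_records(trait).dropna(subset=["value"])
    if sub.empty:
        raise KeyError(f"trait {trait!r} has no phenotype records")
    env_mean = sub.groupby("environment")["value"].transform("mean")
    dev = sub["value"] - env_mean
    scores = dev.groupby(sub["subject"]).mean().sort_index()
    return ScoreVector(scores=scores)


def _cell_ids(g: GenotypeMatrix, loci, subjects) -> np.ndarray:
    """Genotype-cell index per subject (base-3 over the loci); -1 where any
    call is missing."""
    calls = g.calls.loc[subjects, list(loci)].to_numpy()
    cells = np.zeros(len(subjects), dtype=np.int64)
    for k in range(calls.shape[1]):
        cells = cells * 3 + np.where(calls[:, k] == MISSING, 0, calls[:, k])
    cells[(calls == MISSING).any(axis=1)] = -1
    return cells


def _fold_assignment(n: int, k_folds: int, rng) -> np.ndarray:
    folds = np.arange(n) % k_folds
    rng.shuffle(folds)
    return folds


def _balanced_accuracy(truth_high: np.ndarray, pred_high: np.ndarray) -> float:
    """Mean of per-class accuracies over the classes present."""
    accs = []
    for cls in (True, False):
        m = truth_high == cls
        if m.any():
            accs.append(float((pred_high[m] == cls).mean()))
    return float(np.mean(accs)) if accs else 0.5


def _fold_accuracies(scores: np.ndarray, cells: np.ndarray, folds: np.ndarray,
                     k_folds: int, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Training and testing balanced accuracy per fold for one combination."""
    truth = scores > 0
    train_acc = np.zeros(k_folds)
    test_acc = np.zeros(k_folds)
    for f in range(k_folds):
        test = folds == f
        train = ~test
        cell_sum = np.bincount(cells[train], weights=scores[train],
                               minlength=n_cells)
        cell_n = np.bincount(cells[train], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            cell_mean = np.where(cell_n > 0, cell_sum / np.maximum(cell_n, 1),
                                 0.0)
        high = cell_mean > 0  # empty training cell -> low (prior)
        train_acc[f] = _balanced_accuracy(truth[train], high[cells[train]])
        test_acc[f] = _balanced_accuracy(truth[test], high[cells[test]])
    return train_acc, test_acc


def _prepare(s: ScoreVector, g: GenotypeMatrix) -> tuple[np.ndarray, list]:
    subjects = [x for x in s.subjects if x in set(g.calls.index)]
    return s.scores.loc[subjects].to_numpy(dtype=float), subjects


def evaluate_combination(s: ScoreVector, g: GenotypeMatrix, loci,
                         k_folds: int = 10, seed: int = 0,
                         competitors=None) -> GMDRResult:
    """Cross-validated GMDR evaluation of one 1- to 3-locus combination.

    ``competitors`` (same-dimension locus sets) define the field against
    which cross-validation consistency is counted; with none given the model
    competes only against itself, so cv_consistency = k_folds.
    """
    loci = tuple(loci)
    if len(set(loci)) != len(loci):
        raise ValueError("loci must be distinct")
    if not 1 <= len(loci) <= 3:
        raise ValueError("GMDR supports 1 to 3 loci")
    scores, subjects = _prepare(s, g)
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(len(subjects), k_folds, rng)
    n_cells = 3 ** len(loci)

    cells = _cell_ids(g, loci, subjects)
    ok = cells >= 0
    train_acc, test_acc = _fold_accuracies(scores[ok], cells[ok], folds[ok],
                                           k_folds, n_cells)
    field = [loci] + [tuple(c) for c in (competitors or [])
                      if tuple(c) != loci]
    if len(field) == 1:
        cvc = k_folds
    else:
        best = np.tile(-np.inf, k_folds)
        winner = [None] * k_folds
        for cand in sorted(field):
            c_cells = _cell_ids(g, cand, subjects)
            c_ok = c_cells >= 0
            c_train, _ = _fold_accuracies(scores[c_ok], c_cells[c_ok],
                                          folds[c_ok], k_folds, n_cells)
            for f in range(k_folds):
                if c_train[f] > best[f]:
                    best[f] = c_train[f]
                    winner[f] = cand
        cvc = sum(1 for w in winner if w == loci)
    return GMDRResult(loci=loci, testing_accuracy=float(test_acc.mean()),
                      cv_consistency=int(cvc), k_folds=k_folds)


def _scan_dimension(scores, cells_by_combo, folds, k_folds) -> dict:
    """Evaluate every combination of one dimension sharing a fold split."""
    train = {}
    test = {}
    for combo, cells in cells_by_combo.items():
        n_cells = 3 ** len(combo)
        ok = cells >= 0
        tr, te = _fold_accuracies(scores[ok], cells[ok], folds[ok],
                                  k_folds, n_cells)
        train[combo] = tr
        test[combo] = te
    # per-fold winner by training accuracy (ties -> lexicographically first)
    winners = []
    for f in range(k_folds):
        best_combo, best_acc = None, -np.inf
        for combo in sorted(train):
            if train[combo][f] > best_acc:
                best_acc = train[combo][f]
                best_combo = combo
        winners.append(best_combo)
    results = {}
    for combo in cells_by_combo:
        cvc = sum(1 for w in winners if w == combo)
        results[combo] = GMDRResult(loci=combo,
                                    testing_accuracy=float(test[combo].mean()),
                                    cv_consistency=cvc, k_folds=k_folds)
    return results


def scan(s: ScoreVector, g: GenotypeMatrix, max_dim: int = 3,
         k_folds: int = 10, accuracy_min: float = 0.55, seed: int = 0,
         mode: str = "staged", top_m: int = 20,
         cv_consistency_min: int = None) -> set:
    """Screen the panel for candidate loci by 1- to ``max_dim``-locus GMDR.

    A combination is selected when its testing accuracy reaches
    ``accuracy_min`` and its cross-validation consistency reaches
    ``cv_consistency_min`` (default k_folds // 2); the returned candidate set
    is the union of loci over selected combinations of every dimension.

    ``mode="exhaustive"`` scans all combinations (small panels only);
    ``mode="staged"`` (default) feeds the ``top_m`` one-locus survivors by
    testing accuracy into the 2- and 3-locus scans.  Deterministic given
    ``seed``; invariant to subject order and locus relabeling.
    """
    if not 1 <= max_dim <= 3:
        raise ValueError("max_dim must be 1, 2 or 3")
    if mode not in ("staged", "exhaustive"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if cv_consistency_min is None:
        cv_consistency_min = k_folds // 2

    scores, subjects = _prepare(s, g)
    order = np.argsort(np.array(subjects, dtype=object))
    scores = scores[order]
    subjects = [subjects[i] for i in order]
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(len(subjects), k_folds, rng)

    all_loci = sorted(g.calls.columns)
    selected = set()

    dim1 = {(l,): _cell_ids(g, (l,), subjects) for l in all_loci}
    results1 = _scan_dimension(scores, dim1, folds, k_folds)
    for combo, res in results1.items():
        res.selected = (res.testing_accuracy >= accuracy_min
                        and res.cv_consistency >= cv_consistency_min)
        if res.selected:
            selected.update(combo)

    if mode == "staged":
        ranked = sorted(results1.values(),
                        key=lambda r: (-r.testing_accuracy, r.loci))
        pool = sorted({l for r in ranked[:top_m] for l in r.loci})
    else:
        pool = all_loci

    for dim in range(2, max_dim + 1):
        combos = {c: _cell_ids(g, c, subjects)
                  for c in itertools.combinations(pool, dim)}
        if not combos:
            continue
        results = _scan_dimension(scores, combos, folds, k_folds)
        for combo, res in results.items():
            if (res.testing_accuracy >= accuracy_min
                    and res.cv_consistency >= cv_consistency_min):
                selected.update(combo)
    return selected
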