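"""Nested cross-model validation (2CV) and permutation significance.

The outer loop repeatedly splits the data into stratified 75%/25%
training/testing sets; the inner loop selects the PLS component count on
the training set by leave-10-out cross-validation, minimizing the number of
misclassifications (NMC, ties broken toward the smallest count).  The
optimized model is refit on the full training set and scored on the held-out
test set; NMC mean +- sd and the pooled confusion-matrix accuracy are
aggregated over the outer repeats, and models with accuracy >= 80% pass the
gate.  Model significance comes from randomly permuting the class labels
(default 1000 iterations) and recomputing the same cross-validated NMC; the
permutation p-value uses the add-one rule so its minimum is 1/(n_perm+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .plsda import decision_path, fit_plsda, predict

log = logging.getLogger(__name__)

_PERM_STREAM = 7919


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CVConfig:
    """Nested-CV parameters.

    ``inner_leave_out`` is the inner fold size (leave-10-out read as folds
    of 10 consecutive samples of a seeded shuffle; the last fold may be
    smaller).  ``a_max`` caps the component search, defaulting to
    min(n_train - 1, p, 10).  ``perm_repeats`` is the reduced outer repeat
    count used inside each permutation iteration for tractability; the
    observed statistic is computed with the same reduced count so the
    permutation comparison is exchangeable.
    """

    outer_train_fraction: float = 0.75
    inner_leave_out: int = 10
    a_max: int | None = None
    n_outer_repeats: int = 100
    accuracy_gate: float = 0.80
    n_perm: int = 1000
    perm_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.outer_train_fraction < 1.0:
            raise ValidationError("outer_train_fraction must be in (0, 1)")
        if self.inner_leave_out < 1:
            raise ValidationError("inner_leave_out must be >= 1")
        if self.n_outer_repeats < 1 or self.perm_repeats < 1:
            raise ValidationError("repeat counts must be >= 1")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")


@dataclass
class CVDiagnostics:
    """Aggregate diagnostics for one compartment x contrast."""

    r2y: float
    nmc_mean: float
    nmc_sd: float
    confusion: np.ndarray        # rows = true class, cols = predicted
    classes: tuple[str, str]
    classification_accuracy: float  # percent
    selected_a: list[int]
    a_final: int
    gate_passed: bool
    n_test_total: int


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int


def _effective_a_max(cfg: CVConfig, n_train: int, p: int) -> int:
    cap = min(n_train - 1, p, 10 if cfg.a_max is None else cfg.a_max)
    return max(1, cap)


def inner_cv_select_A(X: np.ndarray, y: np.ndarray, cfg: CVConfig,
                      rng: np.random.Generator) -> int:
    """Leave-``inner_leave_out``-out NMC-optimal component count.

    Partitions a seeded shuffle of the training set into consecutive folds,
    scores held-out NMC for every candidate component count from a single
    multi-component fit per fold, and returns the count with the smallest
    total NMC (smallest count on ties).  A fold whose training remainder is
    single-class is skipped with a warning; if every fold is skipped the
    parsimonious default of 1 component is returned.
    """
    y = np.asarray(y)
    n = len(y)
    if n <= cfg.inner_leave_out:
        raise ValidationError("training set not larger than the inner fold size")
    a_hi = _effective_a_max(cfg, n - cfg.inner_leave_out, X.shape[1])
    idx = rng.permutation(n)
    nmc = np.zeros(a_hi)
    scored_any = False
    for start in range(0, n, cfg.inner_leave_out):
        held = idx[start:start + cfg.inner_leave_out]
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        y_tr = y[mask]
        if len(set(y_tr.tolist())) < 2:
            warnings.warn("inner fold skipped: remaining training data is single-class")
            continue
        model = fit_plsda(X[mask], y_tr, min(a_hi, mask.sum() - 1),
                          clip=True)
        preds = decision_path(model, X[held])           # (m, A_used)
        truth = np.where(y[held] == model.classes[0], 1.0, -1.0)
        miss = (np.where(preds >= 0, 1.0, -1.0) != truth[:, None]).sum(axis=0)
        a_used = preds.shape[1]
        nmc[:a_used] += miss
        if a_used < a_hi:
            nmc[a_used:] += miss[-1]                    # cap at the deepest model
        scored_any = True
    if not scored_any:
        return 1
    return int(np.argmin(nmc)) + 1  # argmin takes the first (smallest A) on ties


def _stratified_split(y: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in sorted(set(y.tolist()), key=str):
        members = np.flatnonzero(y == cls)
        perm = rng.permutation(members)
        n_tr = int(round(fraction * len(members)))
        n_tr = min(max(n_tr, 1), len(members) - 1)
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def outer_cv(X: np.ndarray, y: Sequence, cfg: CVConfig,
             rng: np.random.Generator | None = None) -> CVDiagnostics:
    """Repeated stratified 75/25 2CV with inner NMC-optimized component choice."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist()), key=str))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {len(classes)}")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 members")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    nmc_list: list[int] = []
    selected: list[int] = []
    confusion = np.zeros((2, 2), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for _ in range(cfg.n_outer_repeats):
        tr, te = _stratified_split(y, cfg.outer_train_fraction, rng)
        a_sel = inner_cv_select_A(X[tr], y[tr], cfg, rng)
        model = fit_plsda(X[tr], y[tr], a_sel, clip=True)
        labels_hat = predict(model, X[te])
        nmc_list.append(int((labels_hat != y[te]).sum()))
        selected.append(model.n_components)
        for yt, yp in zip(y[te], labels_hat):
            confusion[cls_index[yt], cls_index[yp]] += 1

    nmc_arr = np.asarray(nmc_list, dtype=float)
    n_test_total = int(confusion.sum())
    accuracy = 100.0 * confusion.trace() / n_test_total
    # final model: refit the full data at the modal selected component count
    vals, counts = np.unique(selected, return_counts=True)
    a_final = int(vals[np.argmax(counts)])
    full = fit_plsda(X, y, a_final, clip=True)
    return CVDiagnostics(
        r2y=full.r2y,
        nmc_mean=float(nmc_arr.mean()),
        nmc_sd=float(nmc_arr.std(ddof=1)) if len(nmc_arr) > 1 else 0.0,
        confusion=confusion, classes=classes,
        classification_accuracy=float(accuracy),
        selected_a=selected, a_final=full.n_components,
        gate_passed=bool(accuracy >= 100.0 * cfg.accuracy_gate),
        n_test_total=n_test_total)


def permutation_test(X: np.ndarray, y: Sequence, cfg: CVConfig,
                     n_perm: int | None = None) -> PermutationResult:
    """Class-label permutation test on the cross-validated test NMC.

    The observed statistic and every permuted replicate use an identical
    reduced outer-repeat count (``cfg.perm_repeats``), so under the null the
    observed value is exchangeable with the permuted ones.  p-value:
    ``(1 + #{null <= observed}) / (1 + n_perm)`` — smaller NMC is better,
    and the add-one rule keeps the minimum p at 1/(n_perm + 1).
    """
    if n_perm is None:
        n_perm = cfg.n_perm
    y = np.asarray(y)
    ss = np.random.SeedSequence([cfg.seed, _PERM_STREAM])
    children = ss.spawn(n_perm + 2)

    def _seeded_cfg(child) -> CVConfig:
        s = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        return replace(cfg, n_outer_repeats=cfg.perm_repeats, seed=s)

    observed = outer_cv(X, y, _seeded_cfg(children[0])).nmc_mean
    rng_perm = np.random.default_rng(children[1])
    null = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng_perm.permutation(y)
        null[k] = outer_cv(X, y_perm, _seeded_cfg(children[k + 2])).nmc_mean
    p = (1.0 + float((null <= observed + 1e-12).sum())) / (1.0 + n_perm)
    return PermutationResult(observed=float(observed), null=null,
                             p_value=float(p), n_perm=int(n_perm))
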