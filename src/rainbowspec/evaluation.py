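"""Evaluation protocol: DUPLEX 2:1 splitting, leave-one-out
cross-validated grid search, and overall / per-class accuracy reporting.

Everything here is deterministic: DUPLEX uses no randomness, all five
classifiers are deterministic, and grid ties resolve by a documented
parsimony rule (fewest latent variables first, then the smallest value of
the secondary parameter).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .classifiers import make_classifier
from .classifiers.dummy import decode, dummy_code
from .classifiers.kpls import kpls_fit
from .classifiers.lwpls import _weighted_pls_score_path, similarity_weights
from .classifiers.pls import pls_fit
from .errors import InvalidParameterError, LabelError

# ---------------------------------------------------------------------------
# parameter grids


def default_grids() -> dict:
    """The default hyperparameter search grids.

    k odd in 1..49; latent variables capped at 10; C integer in 1..8;
    sigma over seven decades on a log scale; phi from 0.1 to 25.
    """
    return {
        "knn": {"k": list(range(1, 50, 2))},
        "svm": {"C": [float(c) for c in range(1, 9)]},
        "plsda": {"n_lv": list(range(1, 11))},
        "kplsda": {
            "n_lv": list(range(1, 11)),
            "sigma": [10.0**e for e in range(-3, 4)],
        },
        "lwplsc": {
            "n_lv": list(range(1, 11)),
            "phi": [0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0],
        },
    }


# ---------------------------------------------------------------------------
# DUPLEX splitting


@dataclass(frozen=True)
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray


def duplex_split(X, ratio: tuple = (2, 1)) -> SplitResult:
    """Deterministic DUPLEX partition at the given train:test ratio.

    The two mutually most-distant samples seed the training set, the next
    most-distant remaining pair seeds the test set; thereafter single
    points join the set with the largest relative deficit (ties toward
    training), each time choosing the remaining point farthest — in
    max-min distance — from that set's current members.  Test-set size is
    ``round(n * ratio_test / (ratio_train + ratio_test))``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    r_train, r_test = ratio
    if r_train < 1 or r_test < 1:
        raise InvalidParameterError(f"split ratio parts must be >= 1, got {ratio}")
    n_test = int(round(n * r_test / (r_train + r_test)))
    n_train = n - n_test
    if n < 4 or n_test < 2 or n_train < 2:
        raise InvalidParameterError(
            f"need at least two samples per subset; n={n} with ratio {ratio} gives "
            f"{n_train}:{n_test}"
        )
    D = cdist(X, X)
    remaining = np.ones(n, dtype=bool)
    train: list[int] = []
    test: list[int] = []

    def pop_farthest_pair(dest):
        masked = np.where(np.outer(remaining, remaining), D, -1.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        i, j = min(i, j), max(i, j)
        dest.extend([i, j])
        remaining[[i, j]] = False

    def pop_farthest_point(dest):
        cand = np.flatnonzero(remaining)
        min_d = D[np.ix_(cand, dest)].min(axis=1)
        pick = int(cand[int(np.argmax(min_d))])
        dest.append(pick)
        remaining[pick] = False

    pop_farthest_pair(train)
    pop_farthest_pair(test)
    while remaining.any():
        train_def = n_train - len(train)
        test_def = n_test - len(test)
        if test_def <= 0:
            target = train
        elif train_def <= 0:
            target = test
        else:
            target = train if train_def * r_test >= test_def * r_train else test
        pop_farthest_point(target)
    return SplitResult(np.array(sorted(train)), np.array(sorted(test)))


# ---------------------------------------------------------------------------
# leave-one-out cross validation


def loocv_accuracy(X, y, algorithm: str, params: dict) -> float:
    """LOOCV accuracy (percent) of one algorithm at one parameter setting.

    A classifier failure on a fold is recorded as a misclassification and
    warned about, so a fragile parameter point cannot crash a grid search.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = X.shape[0]
    if n < 2:
        raise InvalidParameterError("LOOCV needs at least two samples")
    correct = 0
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n_lv clamping on tiny folds
        for i in range(n):
            mask[i] = False
            try:
                clf = make_classifier(algorithm, params)
                clf.fit(X[mask], y[mask])
                pred = clf.predict(X[i][None, :])[0]
                correct += pred == y[i]
            except Exception as exc:  # noqa: BLE001 - fold failure is data-dependent
                warnings.warn(
                    f"{algorithm} failed on fold {i} with {params}: {exc}",
                    stacklevel=2,
                )
            mask[i] = True
    return 100.0 * correct / n


# ---------------------------------------------------------------------------
# grid search


@dataclass
class GridSearchResult:
    algorithm: str
    best_params: dict
    best_accuracy: float
    surface: pd.DataFrame = field(repr=False)

    def surface_to_csv(self, path) -> None:
        self.surface.to_csv(path, index=False)


def _combo_order(algorithm, grid):
    """Canonical evaluation order implementing the parsimony tie-break."""
    if algorithm == "knn":
        return [{"k": k} for k in sorted(grid["k"])]
    if algorithm == "svm":
        return [{"C": c} for c in sorted(grid["C"])]
    if algorithm == "plsda":
        return [{"n_lv": a} for a in sorted(grid["n_lv"])]
    if algorithm == "kplsda":
        return [
            {"n_lv": a, "sigma": s}
            for a in sorted(grid["n_lv"])
            for s in sorted(grid["sigma"])
        ]
    if algorithm == "lwplsc":
        return [
            {"n_lv": a, "phi": p}
            for a in sorted(grid["n_lv"])
            for p in sorted(grid["phi"])
        ]
    raise KeyError(f"unknown algorithm {algorithm!r}")


def _loocv_knn_all_k(X, y, ks):
    n = len(y)
    D = cdist(X, X)
    _, class_order = dummy_code(y)
    correct = dict.fromkeys(ks, 0)
    for i in range(n):
        others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = others[np.argsort(D[i, others], kind="stable")]
        votes = y[order]
        for k in ks:
            counts = [np.sum(votes[:k] == c) for c in class_order]
            pred = class_order[int(np.argmax(counts))]
            correct[k] += pred == y[i]
    return {k: 100.0 * c / n for k, c in correct.items()}


def _loocv_plsda_all_lv(X, y, lvs):
    n = len(y)
    max_lv = max(lvs)
    correct = dict.fromkeys(lvs, 0)
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask[i] = False
            Y, class_order = dummy_code(y[mask])
            model = pls_fit(X[mask], Y, max_lv, class_order)
            for a in lvs:
                pred = model.predict(X[i][None, :], n_lv=a)[0]
                correct[a] += pred == y[i]
            mask[i] = True
    return {a: 100.0 * c / n for a, c in correct.items()}


def _loocv_kplsda(X, y, lvs, sigmas):
    n = len(y)
    max_lv = max(lvs)
    correct = {(a, s): 0 for a in lvs for s in sigmas}
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in sigmas:
            for i in range(n):
                mask[i] = False
                Y, class_order = dummy_code(y[mask])
                model = kpls_fit(X[mask], Y, max_lv, sigma=s, class_order=class_order)
                for a in lvs:
                    pred = model.predict(X[i][None, :], n_lv=a)[0]
                    correct[(a, s)] += pred == y[i]
                mask[i] = True
    return {key: 100.0 * c / n for key, c in correct.items()}


def _loocv_lwplsc(X, y, lvs, phis):
    n = len(y)
    max_lv = max(lvs)
    correct = {(a, p): 0 for a in lvs for p in phis}
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for phi in phis:
            for i in range(n):
                mask[i] = False
                Xt, yt = X[mask], y[mask]
                Y, class_order = dummy_code(yt)
                d = np.linalg.norm(Xt - X[i], axis=1)
                w = similarity_weights(d, phi)
                path = _weighted_pls_score_path(Xt, Y, X[i], w, max_lv)
                for a in lvs:
                    row = path[min(a, path.shape[0]) - 1]
                    pred = decode(row[None, :], class_order)[0]
                    correct[(a, phi)] += pred == y[i]
                mask[i] = True
    return {key: 100.0 * c / n for key, c in correct.items()}


def grid_search(X, y, algorithm: str, grid: dict | None = None) -> GridSearchResult:
    """Exhaustive LOOCV over the parameter grid.

    Shares per-fold model fits across grid points where mathematically
    exact (all LV counts from one NIPALS run; one distance matrix for all
    k), so results are identical to calling :func:`loocv_accuracy` per
    point.  Ties resolve to the earliest point in the canonical order
    (fewest LVs first, then the smallest secondary parameter).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    grid = grid or default_grids()[algorithm]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise InvalidParameterError("parameter grid must be non-empty")
    combos = _combo_order(algorithm, grid)

    if algorithm == "knn":
        acc = _loocv_knn_all_k(X, y, sorted(grid["k"]))
        rows = [{**c, "accuracy": acc[c["k"]]} for c in combos]
    elif algorithm == "plsda":
        acc = _loocv_plsda_all_lv(X, y, sorted(grid["n_lv"]))
        rows = [{**c, "accuracy": acc[c["n_lv"]]} for c in combos]
    elif algorithm == "kplsda":
        acc = _loocv_kplsda(X, y, sorted(grid["n_lv"]), sorted(grid["sigma"]))
        rows = [{**c, "accuracy": acc[(c["n_lv"], c["sigma"])]} for c in combos]
    elif algorithm == "lwplsc":
        acc = _loocv_lwplsc(X, y, sorted(grid["n_lv"]), sorted(grid["phi"]))
        rows = [{**c, "accuracy": acc[(c["n_lv"], c["phi"])]} for c in combos]
    else:  # svm: plain per-point loop
        rows = [
            {**c, "accuracy": loocv_accuracy(X, y, algorithm, c)} for c in combos
        ]

    surface = pd.DataFrame(rows)
    best_i = int(np.argmax(surface["accuracy"].to_numpy()))
    best = rows[best_i]
    best_params = {k: v for k, v in best.items() if k != "accuracy"}
    return GridSearchResult(algorithm, best_params, float(best["accuracy"]), surface)


# ---------------------------------------------------------------------------
# accuracy reporting


@dataclass
class EvaluationReport:
    """Test-set performance of one algorithm, Table-style."""

    overall: float
    per_class: dict
    confusion: np.ndarray
    class_order: list
    n: int
    algorithm: str | None = None
    selected_params: dict | None = None
    validation_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n": self.n,
            "overall": self.overall,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "selected_params": self.selected_params,
            "validation_accuracy": self.validation_accuracy,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        parts = [f"overall {self.overall:.1f}%"]
        parts += [f"{c} {v:.1f}%" for c, v in self.per_class.items()]
        if self.selected_params:
            params = ", ".join(f"{k}={v}" for k, v in self.selected_params.items())
            parts.append(f"[{params}]")
        name = self.algorithm or "classifier"
        return f"{name}: " + "  ".join(parts)


def evaluate_predictions(y_true, y_pred, class_order=None) -> EvaluationReport:
    """Overall and per-class accuracy plus the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise InvalidParameterError("prediction and truth lengths differ")
    if class_order is None:
        class_order = sorted(set(y_true.tolist()))
    unknown = set(y_pred.tolist()) - set(class_order)
    if unknown:
        raise LabelError(f"predictions contain labels outside the class set: {unknown}")
    index = {c: j for j, c in enumerate(class_order)}
    C = len(class_order)
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    overall = 100.0 * np.trace(confusion) / len(y_true)
    per_class = {}
    for c in class_order:
        row = confusion[index[c]]
        total = row.sum()
        per_class[c] = 100.0 * row[index[c]] / total if total else float("nan")
    return EvaluationReport(
        overall=float(overall),
        per_class=per_class,
        confusion=confusion,
        class_order=list(class_order),
        n=len(y_true),
    )
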