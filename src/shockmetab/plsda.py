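"""Two-class PLS-DA by single-response NIPALS, with VIP variable ranking.

The class labels are coded as a single response y in {+1, -1} (the
alphabetically first class is +1); with two roughly balanced classes this is
equivalent to two-column indicator coding up to scaling.  For a single
response the NIPALS component extraction is exact in one pass:

    w_a = X_a' y / ||X_a' y||        (unit-norm weights)
    t_a = X_a w_a                    (scores)
    q_a = t_a' y / t_a' t_a          (response loading)
    p_a = X_a' t_a / t_a' t_a        (X loadings)
    X_{a+1} = X_a - t_a p_a'         (deflation)

Scores are mutually orthogonal; predictions use the regression vector
b = W (P'W)^{-1} q on the training-scaled space.  R2Y on the training fit is
the headline fit diagnostic; R2X is computed but secondary.

VIP (variable importance in projection, Wold's formulation):

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),   SSY_a = q_a^2 t_a't_a

normalized so that sum_j VIP_j^2 = p (the retained variable count).
Metabolites with VIP >= 1.0, capped at the 10 largest, are reported as the
primary drivers of the discrimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DataValidationError
from .preprocess import autoscale

#: selection rule defaults: VIP threshold and report cap
VIP_THRESHOLD = 1.0
VIP_CAP = 10


class ModelError(ValueError):
    """Invalid model inputs (single class, too many components, ...)."""


@dataclass
class PLSDAModel:
    """Fitted two-class PLS-DA model.

    ``classes[0]`` is coded +1; a continuous prediction of exactly 0 is
    assigned to ``classes[0]`` (documented tie-break).  ``coef_path[:, a-1]``
    is the regression vector using the first ``a`` components, so the full
    component path can be evaluated from one fit.
    """

    classes: tuple[str, str]
    center: np.ndarray
    scale: np.ndarray
    kept: np.ndarray
    names: list[str]
    W: np.ndarray          # p_kept x A, unit-norm columns
    P: np.ndarray          # p_kept x A
    T: np.ndarray          # n x A training scores
    q: np.ndarray          # A response loadings
    t_ss: np.ndarray       # A score sums of squares t_a' t_a
    y_mean: float
    coef_path: np.ndarray  # p_kept x A
    r2y: float
    r2x: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[:, -1]

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        payload = {
            "classes": list(self.classes),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "kept": self.kept.tolist(),
            "names": self.names,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "t_ss": self.t_ss.tolist(),
            "y_mean": self.y_mean,
            "coef_path": self.coef_path.tolist(),
            "r2y": self.r2y,
            "r2x": self.r2x,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSDAModel":
        d = json.loads(Path(path).read_text())
        W = np.asarray(d["W"], dtype=float)
        return cls(classes=tuple(d["classes"]), center=np.asarray(d["center"]),
                   scale=np.asarray(d["scale"]), kept=np.asarray(d["kept"], dtype=int),
                   names=list(d["names"]), W=W, P=np.asarray(d["P"]),
                   T=np.empty((0, W.shape[1])), q=np.asarray(d["q"]),
                   t_ss=np.asarray(d["t_ss"]), y_mean=float(d["y_mean"]),
                   coef_path=np.asarray(d["coef_path"]),
                   r2y=float(d["r2y"]), r2x=float(d["r2x"]))


def _encode_labels(y: Sequence) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(y)
    classes = sorted(set(labels.tolist()), key=str)
    if len(classes) != 2:
        raise ModelError(f"need exactly 2 classes, got {len(classes)}")
    coded = np.where(labels == classes[0], 1.0, -1.0)
    return coded, (classes[0], classes[1])


def fit_plsda(X: np.ndarray, y: Sequence, n_components: int,
              names: Sequence[str] | None = None, clip: bool = False) -> PLSDAModel:
    """Fit a two-class PLS-DA model with ``n_components`` latent variables.

    ``X`` is the raw (unscaled) analysis matrix; autoscaling is performed
    internally and the centering/scaling vectors are stored so new data is
    always scaled with the TRAINING parameters.  Component extraction stops
    early if the response-covariance direction degenerates (X orthogonal to
    y), in which case the model carries fewer components than requested.
    """
    X = np.asarray(X, dtype=float)
    coded, classes = _encode_labels(y)
    n, p = X.shape
    if len(coded) != n:
        raise ModelError("X and y lengths differ")
    scaled = autoscale(X, names=names)
    p_kept = scaled.n_features
    a_cap = min(n - 1, p_kept)
    if clip:
        n_components = max(1, min(n_components, a_cap))
    if not 1 <= n_components <= a_cap:
        raise ModelError(
            f"n_components must be in [1, {a_cap}] for n={n}, p={p_kept}")

    y_mean = coded.mean()
    yc = coded - y_mean
    Xd = scaled.values.copy()
    x_ss_total = float((Xd ** 2).sum())

    Ws, Ps, Ts, qs, tss = [], [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(yc)):
            break  # X residual orthogonal to the response
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        q_a = float(t @ yc) / tt
        p_a = (Xd.T @ t) / tt
        Xd -= np.outer(t, p_a)
        Ws.append(w); Ps.append(p_a); Ts.append(t); qs.append(q_a); tss.append(tt)

    if not Ws:
        # fully degenerate: constant-zero predictor
        W = np.zeros((p_kept, 1)); P = np.zeros((p_kept, 1))
        T = np.zeros((n, 1)); q = np.zeros(1); t_ss = np.ones(1)
        coef_path = np.zeros((p_kept, 1))
        r2y = 0.0
        r2x = 0.0
    else:
        W = np.column_stack(Ws); P = np.column_stack(Ps)
        T = np.column_stack(Ts); q = np.asarray(qs); t_ss = np.asarray(tss)
        A = W.shape[1]
        M = P.T @ W  # A x A; invertible for extracted components
        coef_path = np.empty((p_kept, A))
        for a in range(1, A + 1):
            coef_path[:, a - 1] = W[:, :a] @ np.linalg.solve(M[:a, :a], q[:a])
        fitted = T @ q
        ss_res = float(((yc - fitted) ** 2).sum())
        ss_tot = float((yc ** 2).sum())
        r2y = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        r2x = 1.0 - float((Xd ** 2).sum()) / x_ss_total if x_ss_total > 0 else 0.0

    return PLSDAModel(classes=classes, center=scaled.means, scale=scaled.sds,
                      kept=scaled.kept, names=scaled.names, W=W, P=P, T=T,
                      q=q, t_ss=t_ss, y_mean=float(y_mean),
                      coef_path=coef_path, r2y=float(r2y), r2x=float(r2x))


def _scale_new(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < int(model.kept.max(initial=-1)) + 1:
        raise ModelError("new data has fewer columns than the training matrix")
    return (X[:, model.kept] - model.center) / model.scale


def decision_scores(model: PLSDAModel, X: np.ndarray,
                    n_components: int | None = None) -> np.ndarray:
    """Continuous predictions; >= 0 means the first (coded +1) class."""
    Xs = _scale_new(model, X)
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ModelError(f"n_components must be in [1, {model.n_components}]")
    return Xs @ model.coef_path[:, a - 1] + model.y_mean


def decision_path(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """``(n, A)`` continuous predictions for every component count 1..A."""
    Xs = _scale_new(model, X)
    return Xs @ model.coef_path + model.y_mean


def predict(model: PLSDAModel, X: np.ndarray,
            n_components: int | None = None) -> np.ndarray:
    """Predicted class labels; a score of exactly 0 goes to the first class."""
    yhat = decision_scores(model, X, n_components)
    return np.where(yhat >= 0, model.classes[0], model.classes[1])


# ---------------------------------------------------------------------------
# VIP

@dataclass
class VIPTable:
    """Per-metabolite VIP scores with ranks and the threshold/cap selection."""

    names: list[str]
    vip: np.ndarray
    threshold: float = VIP_THRESHOLD
    cap: int = VIP_CAP
    rank: np.ndarray = field(init=False)
    selected: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = self._order()
        self.rank = np.empty(len(self.vip), dtype=int)
        self.rank[order] = np.arange(1, len(self.vip) + 1)
        chosen = [i for i in order if self.vip[i] >= self.threshold][: self.cap]
        self.selected = np.zeros(len(self.vip), dtype=bool)
        self.selected[chosen] = True

    def _order(self) -> list[int]:
        # descending VIP; ties broken by metabolite name for reproducibility
        return sorted(range(len(self.vip)),
                      key=lambda i: (-self.vip[i], self.names[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"metabolite": self.names, "vip": self.vip,
                             "rank": self.rank, "selected": self.selected})


def vip_scores(model: PLSDAModel, threshold: float = VIP_THRESHOLD,
               cap: int = VIP_CAP) -> VIPTable:
    """Wold VIP scores for every retained metabolite of a fitted model."""
    ssy = model.q ** 2 * model.t_ss
    total = float(ssy.sum())
    p_kept = model.W.shape[0]
    if total <= 0:
        vip = np.zeros(p_kept)
    else:
        vip = np.sqrt(p_kept * (model.W ** 2 @ ssy) / total)
    return VIPTable(names=list(model.names), vip=vip, threshold=threshold, cap=cap)


def select_vip(table: VIPTable, threshold: float | None = None,
               cap: int | None = None) -> list[str]:
    """Metabolites with VIP >= threshold, the largest first, at most ``cap``."""
    thr = table.threshold if threshold is None else threshold
    c = table.cap if cap is None else cap
    order = sorted(range(len(table.vip)),
                   key=lambda i: (-table.vip[i], table.names[i]))
    return [table.names[i] for i in order if table.vip[i] >= thr][:c]
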