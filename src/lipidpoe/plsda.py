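"""PLS discriminant analysis with VIP scoring and cross-validated Q².

The screening step asks, per SNP and per parental transmission: does the
whole lipid profile separate carriers of the minor transmitted allele from
carriers of the major one?  PLS-DA answers this by regressing the (centred,
dummy-coded) class label on the centred lipid matrix via NIPALS partial
least squares.  A model is accepted when its cross-validated predictive
ability Q² = 1 − PRESS/TSS is positive; within accepted models, lipid
species with a variable-importance-in-projection (VIP) score above a
threshold (2.0 by default) become candidates for univariate follow-up.

The estimator follows the scikit-learn protocol (``fit`` / ``transform`` /
``predict``, ``get_params``, trailing-underscore fitted attributes) so it
composes with sklearn model selection; sklearn's own PLS code is used only
as an independent cross-check in the test-suite, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = ["PLSDA", "q2_cv", "vip_scores", "CandidateSet", "select_candidates"]


class PLSDA(BaseEstimator):
    """Two-class partial least squares discriminant analysis (NIPALS PLS1).

    Parameters
    ----------
    n_components : int
        Number of latent components A to extract.  Extraction stops early
        (with a note in ``stopped_early_``) if X is deflated to numerical
        zero first.

    Attributes
    ----------
    x_weights_ : (J, A) unit-norm weight vectors w_a
    x_scores_ : (n, A) scores t_a
    x_loadings_ : (J, A) loadings p_a
    y_loadings_ : (A,) loadings q_a
    ssy_ : (A,) explained sum of squares of centred y per component
    r2y_ : (A,) cumulative fraction of y variance explained
    vip_ : (J,) VIP scores over all extracted components
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("degenerate class label: only one class present")
        if classes.size > 2:
            raise ValueError("PLS-DA here is strictly two-class")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y01.mean()
        Xc = X - self.x_mean_
        yc = y01 - self.y_mean_
        n, J = Xc.shape
        A = min(self.n_components, J, n - 1)

        tss = float(yc @ yc)
        W, T, P, Q, ssy = [], [], [], [], []
        self.stopped_early_ = False
        eps = np.finfo(float).eps
        for _ in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw <= np.sqrt(eps) * max(1.0, np.abs(Xc).max()):
                self.stopped_early_ = True
                break
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt <= eps:
                self.stopped_early_ = True
                break
            p = Xc.T @ t / tt
            q = float(yc @ t / tt)
            Xc = Xc - np.outer(t, p)
            yc = yc - q * t
            W.append(w); T.append(t); P.append(p); Q.append(q)
            ssy.append(q * q * tt)
        if not W:
            raise ValueError("X carries no covariance with y; no components")
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.array(Q)
        self.ssy_ = np.array(ssy)
        self.tss_ = tss
        self.r2y_ = np.cumsum(self.ssy_) / tss
        self.n_components_ = len(W)
        self.n_features_in_ = J
        self.vip_ = vip_scores(self)
        return self

    def _rotations(self):
        # R = W (PᵀW)⁻¹ maps original (centred) X to scores
        return self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_)

    def transform(self, X):
        check_is_fitted(self, "x_weights_")
        X = check_array(X, dtype=float)
        return (X - self.x_mean_) @ self._rotations()

    def decision_function(self, X):
        """Continuous prediction of the centred class indicator."""
        check_is_fitted(self, "x_weights_")
        X = check_array(X, dtype=float)
        return self.transform(X) @ self.y_loadings_

    def predict(self, X):
        yhat = self.decision_function(X) + self.y_mean_
        return np.where(yhat >= 0.5, self.classes_[1], self.classes_[0])


def vip_scores(model: PLSDA, n_components: int | None = None) -> np.ndarray:
    """Variable importance in projection over the first ``n_components``.

    VIP_j = sqrt( J * sum_a SSY_a w_ja² / sum_a SSY_a ); the squared scores
    average exactly 1 over species, so sum_j VIP_j² = J.
    """
    check_is_fitted(model, "x_weights_")
    A = model.n_components_ if n_components is None else int(n_components)
    if not 1 <= A <= model.n_components_:
        raise ValueError(f"n_components must be in [1, {model.n_components_}]")
    ssy = model.ssy_[:A]
    total = ssy.sum()
    if total <= 0:
        raise ValueError("no explained Y variance; VIP undefined")
    W2 = model.x_weights_[:, :A] ** 2
    J = W2.shape[0]
    return np.sqrt(J * (W2 @ ssy) / total)


def q2_cv(X, y, a_max: int = 5, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Cross-validated Q² for component counts 1..a_max.

    Q²(A) = 1 − PRESS(A)/TSS, with PRESS the summed squared out-of-fold
    errors predicting the centred class indicator and TSS the total centred
    sum of squares.  Folds are stratified by class so every training fold
    retains both classes; deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("degenerate class label")
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few samples in the minority class to stratify")
    y01 = (y == classes[1]).astype(float)
    tss = float(((y01 - y01.mean()) ** 2).sum())
    if tss <= 0:
        raise ValueError("y has no variance")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = np.zeros(a_max)
    for train, test in skf.split(X, y01):
        model = PLSDA(n_components=a_max).fit(X[train], y01[train])
        Xt = X[test] - model.x_mean_
        R = model._rotations()
        scores = Xt @ R
        for a in range(a_max):
            A_eff = min(a + 1, model.n_components_)
            yhat = scores[:, :A_eff] @ model.y_loadings_[:A_eff] + model.y_mean_
            press[a] += float(((y01[test] - yhat) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class CandidateSet:
    """Screening outcome for one (SNP, transmission) contrast."""

    snp_id: str
    transmission: str  # "paternal" | "maternal"
    q2: np.ndarray  # Q² per component count 1..a_max
    best_a: int
    model_q2: float
    accepted: bool
    n_samples: int
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    # candidates columns: species, vip (cumulative over best_a components),
    # vip_single (component best_a alone)


def select_candidates(X: pd.DataFrame, labels: dict, vip_threshold: float = 2.0,
                      a_max: int = 5, folds: int = 10, seed: int = 0,
                      min_per_class: int = 5) -> list[CandidateSet]:
    """Screen every (SNP, transmission) contrast by PLS-DA.

    ``X`` is the normalized lipid matrix (samples x species); ``labels`` maps
    ``(snp_id, transmission)`` onto a per-sample binary coding aligned with
    ``X.index`` (NaN = uninformative, excluded).  A model is accepted iff its
    best Q² over 1..a_max components is positive; ties in Q² resolve to the
    smallest component count.  Accepted models emit the species with
    cumulative VIP above ``vip_threshold``.
    """
    out = []
    for (snp_id, transmission), coded in labels.items():
        coded = pd.Series(coded).reindex(X.index)
        mask = coded.notna()
        yv = coded[mask].to_numpy(float)
        classes, counts = (np.unique(yv, return_counts=True)
                           if mask.any() else (np.array([]), np.array([])))
        if classes.size < 2 or counts.min() < min_per_class:
            out.append(CandidateSet(snp_id, transmission,
                                    np.full(a_max, np.nan), 0, np.nan, False,
                                    int(mask.sum())))
            continue
        Xv = X.loc[mask].to_numpy(float)
        q2 = q2_cv(Xv, yv, a_max=a_max, folds=folds, seed=seed)
        best_a = int(np.argmax(np.round(q2, 12))) + 1
        model_q2 = float(q2[best_a - 1])
        accepted = model_q2 > 0
        cs = CandidateSet(snp_id, transmission, q2, best_a, model_q2,
                          accepted, int(mask.sum()))
        if accepted:
            model = PLSDA(n_components=best_a).fit(Xv, yv)
            A_eff = model.n_components_
            vip = vip_scores(model, A_eff)
            single = np.sqrt(X.shape[1]) * np.abs(model.x_weights_[:, A_eff - 1])
            hits = vip > vip_threshold
            cs.candidates = pd.DataFrame({
                "species": X.columns[hits],
                "vip": vip[hits],
                "vip_single": single[hits],
            }).sort_values("vip", ascending=False).reset_index(drop=True)
        out.append(cs)
    return out
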