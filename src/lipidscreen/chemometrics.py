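"""From-scratch PCA and single-response OPLS-DA chemometrics.

OPLS-DA follows the orthogonal-projections-to-latent-structures NIPALS
formulation for a single binary response: the predictive weight is the
(normalized) covariance direction X'y; each orthogonal component removes
from X the part of its loading uncorrelated with y before the final
predictive component is computed.  Model quality is summarized by R2X/R2Y
(explained variation) and Q2 (7-fold cross-validated prediction), variable
relevance by VIP and S-plot coordinates, and classification by the
predicted-response rule: cancer iff predicted Y > 0.5.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Y_CUTOFF = 0.5
DEFAULT_CV_FOLDS = 7
Q2_IMPROVEMENT = 0.01


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, n_components: int | None = None):
    """Principal component analysis of a centered/scaled matrix via SVD.

    Returns (scores, loadings, explained_variance_ratio).  Components are
    ordered by decreasing explained variance; each loading's sign is fixed
    so that its largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        logger.warning("requested %d components > rank %d; truncated", n_components, rank)
        n_components = rank
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-magnitude loading entry positive
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    total = np.sum(np.asarray(np.linalg.svd(X, compute_uv=False)) ** 2)
    evr = s**2 / total if total > 0 else np.zeros_like(s)
    return scores, vt.T, evr


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted single-response OPLS(-DA) parameters."""

    w: np.ndarray                 # predictive weight (unit norm)
    p: np.ndarray                 # predictive loading
    t: np.ndarray                 # predictive score (training)
    q: float                      # response loading
    w_ortho: np.ndarray           # (k, J) orthogonal weights
    p_ortho: np.ndarray           # (k, J) orthogonal loadings
    t_ortho: np.ndarray           # (k, n) orthogonal scores
    y_mean: float
    n_orthogonal: int
    R2X: float
    R2Y: float
    Q2: float = np.nan
    species: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "q": self.q,
            "w_ortho": self.w_ortho.tolist(),
            "p_ortho": self.p_ortho.tolist(),
            "y_mean": self.y_mean,
            "n_orthogonal": self.n_orthogonal,
            "R2X": self.R2X,
            "R2Y": self.R2Y,
            "Q2": None if np.isnan(self.Q2) else self.Q2,
            "species": self.species,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class/value")
    return X, y


def fit_opls_da(X, y, n_orthogonal: int = 0, species: list[str] | None = None) -> OplsModel:
    """Fit a single-response OPLS(-DA) model on transformed data.

    ``y`` is the 0/1 class code (0 non-cancer, 1 cancer).  With
    ``n_orthogonal=0`` the model coincides with one-component PLS1.  The
    predictive score is oriented so the case-class mean score is positive.
    """
    X, y = _as_xy(X, y)
    n, J = X.shape
    if n_orthogonal >= min(n, J):
        raise ValueError(f"n_orthogonal={n_orthogonal} >= rank bound {min(n, J)}")
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_x_total = float(np.sum(X**2))
    ss_y_total = float(np.sum(yc**2))

    # predictive weight from the covariance direction (fixed across deflation)
    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no covariance with y")
    w = w / norm

    Xf = X.copy()
    w_ortho, p_ortho, t_ortho = [], [], []
    for _ in range(n_orthogonal):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        wo = p - (w @ p) / (w @ w) * w
        wo_norm = np.linalg.norm(wo)
        if wo_norm < 1e-12:
            logger.warning("orthogonal variation exhausted; stopping early")
            break
        wo = wo / wo_norm
        to = Xf @ wo
        po = Xf.T @ to / (to @ to)
        Xf = Xf - np.outer(to, po)
        w_ortho.append(wo)
        p_ortho.append(po)
        t_ortho.append(to)

    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    q = float(t @ yc / (t @ t))

    # orient the predictive score so the case mean is positive
    if t[y == 1].mean() < t[y == 0].mean():
        w, t, p, q = -w, -t, -p, -q

    ss_pred = float(t @ t) * float(p @ p)
    ss_orth = sum(float(to @ to) * float(po @ po) for to, po in zip(t_ortho, p_ortho))
    resid_y = yc - t * q
    model = OplsModel(
        w=w,
        p=p,
        t=t,
        q=q,
        w_ortho=np.asarray(w_ortho).reshape(len(w_ortho), J),
        p_ortho=np.asarray(p_ortho).reshape(len(p_ortho), J),
        t_ortho=np.asarray(t_ortho).reshape(len(t_ortho), n),
        y_mean=y_mean,
        n_orthogonal=len(w_ortho),
        R2X=(ss_pred + ss_orth) / ss_x_total if ss_x_total else 0.0,
        R2Y=1.0 - float(resid_y @ resid_y) / ss_y_total,
        species=list(species) if species is not None else [],
    )
    return model


def predict(model: OplsModel, X_new, species: list[str] | None = None) -> np.ndarray:
    """Predicted continuous response for new (already transformed) samples.

    Orthogonal variation is stripped with the training weights/loadings,
    then the predictive score is projected onto the response loading.
    """
    X_new = np.asarray(X_new, dtype=float)
    if model.species and species is not None:
        missing = [s for s in model.species if s not in species]
        if missing:
            raise ValueError(f"missing species in prediction data: {missing}")
        idx = [species.index(s) for s in model.species]
        X_new = X_new[:, idx]
    if X_new.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.w.shape[0]}, data has {X_new.shape[1]}"
        )
    Xf = X_new.copy()
    for wo, po in zip(model.w_ortho, model.p_ortho):
        to = Xf @ wo
        Xf = Xf - np.outer(to, po)
    t = Xf @ model.w
    return t * model.q + model.y_mean


def classify(y_hat) -> np.ndarray:
    """Binary class from predicted response: cancer iff y_hat > 0.5."""
    return (np.asarray(y_hat, dtype=float) > Y_CUTOFF).astype(int)


def crossvalidate_q2(
    X,
    y,
    n_orthogonal: int = 0,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    scaling: str | None = None,
    log: bool = False,
) -> float:
    """Q2 = 1 - PRESS/SS via k-fold (venetian-blind) cross-validation.

    Folds are assigned round-robin over a seeded permutation.  When a
    scaling scheme is given, centering/scaling parameters are re-fit on
    each fold's training part and applied to the held-out part; otherwise
    X is used as passed.  A fold whose training part is single-class is
    re-drawn once, then raises.
    """
    X, y = _as_xy(X, y)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least {k} samples for {k}-fold CV")
    rng = np.random.default_rng(seed)

    for attempt in range(2):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k
        ok = all(len(np.unique(y[folds != f])) == 2 for f in range(k))
        if ok:
            break
    else:
        raise ValueError("could not build folds with both classes in every training part")

    press = 0.0
    for f in range(k):
        train, test = folds != f, folds == f
        Xtr, Xte = X[train], X[test]
        if scaling is not None:
            from .preprocess import transform_scale

            Xtr_df = pd.DataFrame(Xtr)
            Xtr_t, params = transform_scale(Xtr_df, log=log, scaling=scaling)
            Xtr = Xtr_t.to_numpy()
            Xte = params.apply(pd.DataFrame(Xte)).to_numpy()
        model = fit_opls_da(Xtr, y[train], n_orthogonal=n_orthogonal)
        y_hat = predict(model, Xte)
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def auto_select_orthogonal(
    X,
    y,
    max_k: int = 5,
    k_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    scaling: str | None = None,
) -> int:
    """Add orthogonal components while Q2 improves by more than 0.01."""
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    best_k = 0
    best_q2 = crossvalidate_q2(X, y, 0, k=k_folds, seed=seed, scaling=scaling)
    for kk in range(1, max_k + 1):
        try:
            q2 = crossvalidate_q2(X, y, kk, k=k_folds, seed=seed, scaling=scaling)
        except ValueError:
            break
        if q2 > best_q2 + Q2_IMPROVEMENT:
            best_k, best_q2 = kk, q2
        else:
            break
    return best_k


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Sensitivity/specificity/accuracy (in %) with confusion counts."""

    tp: int
    fn: int
    tn: int
    fp: int
    label: str = "training"

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / n if n else float("nan")

    def as_dict(self) -> dict:
        return dict(
            label=self.label,
            tp=self.tp,
            fn=self.fn,
            tn=self.tn,
            fp=self.fp,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
            accuracy=self.accuracy,
        )


def classification_metrics(truth, predicted, label: str = "training") -> ClassificationReport:
    """Confusion counts and diagnostic percentages for binary labels."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction differ in length")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp, label=label)


def roc_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep) and trapezoid AUC.

    Ties are handled so the AUC equals P(score_case > score_control)
    + 0.5 * P(tie), i.e. the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos, neg = scores[truth == 1], scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = [(pos >= th).mean() for th in thresholds]
    fpr = [(neg >= th).mean() for th in thresholds]
    tpr.append(1.0)
    fpr.append(1.0)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    return roc, auc


def vip(model: OplsModel) -> np.ndarray:
    """Variable influence on projection over all model components.

    ``VIP_j = sqrt(J * sum_a SSY_a (w_aj/|w_a|)^2 / sum_a SSY_a)`` where
    SSY_a is the response variation explained by component a.  Orthogonal
    components contribute (their explained-Y share is ~0 by construction),
    so the result is numerically close to predictive-only VIP.  The mean of
    VIP^2 over variables is exactly 1.
    """
    J = model.w.shape[0]
    weights = [model.w]
    # SSY explained by the predictive component
    ssy = [float(model.t @ model.t) * model.q**2]
    for wo, to in zip(model.w_ortho, model.t_ortho):
        weights.append(wo)
        # orthogonal scores are uncorrelated with y by construction; their
        # explained-Y share is the projection of centered y on the score
        ssy.append(0.0)
    total = sum(ssy)
    acc = np.zeros(J)
    for w_a, ssy_a in zip(weights, ssy):
        acc += ssy_a * (w_a / np.linalg.norm(w_a)) ** 2
    return np.sqrt(J * acc / total)


def splot(model: OplsModel, X) -> pd.DataFrame:
    """S-plot coordinates: covariance and correlation of each variable
    with the predictive score."""
    X = np.asarray(X, dtype=float)
    t = model.t
    n = len(t)
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sd_x = Xc.std(axis=0, ddof=1)
    sd_t = tc.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd_x * sd_t)
    corr = np.where(sd_x > 0, corr, np.nan)
    index = model.species if model.species else list(range(X.shape[1]))
    return pd.DataFrame({"p1": cov, "pcorr1": corr}, index=index)
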