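"""Per-cancer-type classifiers, the metastatic tracing cascade, and the
cfDNA combined model.

Each cancer type gets a one-vs-rest logistic regression over its
cancer-type-specific signatures (optionally plus mutation-marker
indicators), with bidirectional stepwise feature selection by AIC starting
from the intercept-only model.  Tracing the origin of a liver lesion is a
two-stage cascade: the liver model first separates primary liver tumors
from metastases of other organs; a small neural network then assigns
non-liver lesions to a candidate origin from their exposures plus the
per-type model scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

_COEF_BLOWUP = 30.0  # |coef| beyond this signals (quasi-)separation
_RIDGE_STRENGTH = 1e-4


class ConfigurationError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


@dataclass
class CancerModel:
    """A fitted one-vs-rest logistic model for one cancer type."""

    type_name: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "type_name": self.type_name,
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CancerModel":
        return cls(
            d["type_name"],
            list(d["feature_names"]),
            np.asarray(d["coefficients"], dtype=float),
            float(d["intercept"]),
            dict(d.get("training_meta", {})),
        )


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: bool) -> tuple[np.ndarray, float, float]:
    """Fit a logistic model, returning (coefs, intercept, log-likelihood).

    Effectively unpenalized MLE by default; under ``ridge`` an L2 penalty of
    strength 1e-4 stabilizes separated data.
    """
    if X.shape[1] == 0:
        pbar = y.mean()
        pbar = min(max(pbar, 1e-12), 1 - 1e-12)
        b0 = float(np.log(pbar / (1 - pbar)))
        return np.zeros(0), b0, _loglik(y, np.full(len(y), pbar))
    C = 1.0 / _RIDGE_STRENGTH if ridge else 1e8
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-9)
    clf.fit(X, y)
    coefs = clf.coef_[0]
    b0 = float(clf.intercept_[0])
    ll = _loglik(y, expit(X @ coefs + b0))
    return coefs, b0, ll


def _aic(ll: float, n_features: int) -> float:
    return 2 * (n_features + 1) - 2 * ll


def fit_one_vs_rest(
    features: pd.DataFrame,
    labels: np.ndarray,
    candidate_features: list[str],
    type_name: str = "",
    seed: int = 0,
) -> CancerModel:
    """Stepwise (bidirectional, AIC) logistic regression for one type.

    ``labels`` is binary (1 = this type).  Starting from the intercept-only
    model, each step evaluates every single-feature addition and removal
    and applies the move with the largest AIC decrease, stopping when no
    move improves.  On (quasi-)separation — runaway coefficients — the
    final fit falls back to a weak L2 ridge and flags it.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present")
    if not candidate_features:
        raise ConfigurationError("no candidate features supplied")
    missing = [f for f in candidate_features if f not in features.columns]
    if missing:
        raise ConfigurationError(f"candidate features missing from matrix: {missing}")

    selected: list[str] = []
    _, _, ll = _fit_logistic(features[selected].to_numpy(), y, ridge=False)
    current_aic = _aic(ll, 0)
    path: list[str] = []
    while True:
        best_move: tuple[str, str] | None = None
        best_aic = current_aic
        for f in candidate_features:
            if f in selected:
                trial = [s for s in selected if s != f]
                move = ("drop", f)
            else:
                trial = selected + [f]
                move = ("add", f)
            _, _, ll = _fit_logistic(features[trial].to_numpy(), y, ridge=False)
            a = _aic(ll, len(trial))
            if a < best_aic - 1e-9:
                best_aic, best_move = a, move
        if best_move is None:
            break
        action, f = best_move
        selected = [s for s in selected if s != f] if action == "drop" else selected + [f]
        current_aic = best_aic
        path.append(f"{action}:{f}")

    X = features[selected].to_numpy()
    coefs, b0, _ = _fit_logistic(X, y, ridge=False)
    ridge_flag = bool(coefs.size and np.abs(coefs).max() > _COEF_BLOWUP)
    if ridge_flag:
        logger.info("type %s: separation detected, refitting with ridge", type_name)
        coefs, b0, _ = _fit_logistic(X, y, ridge=True)
    return CancerModel(
        type_name=type_name,
        feature_names=selected,
        coefficients=coefs,
        intercept=b0,
        training_meta={
            "n_pos": int(y.sum()),
            "n_neg": int(len(y) - y.sum()),
            "seed": seed,
            "selection_path": path,
            "ridge_fallback": ridge_flag,
        },
    )


def score(model: CancerModel, features: pd.Series | dict | np.ndarray) -> float:
    """Logistic score of one sample; missing features are treated as 0."""
    if isinstance(features, np.ndarray):
        x = np.asarray(features, dtype=float)
        if x.shape != (len(model.feature_names),):
            raise ConfigurationError("feature vector length mismatch")
    else:
        getter = features.get if isinstance(features, dict) else features.get
        vals = []
        for f in model.feature_names:
            v = getter(f)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                logger.warning("feature %r missing for scoring; using 0", f)
                v = 0.0
            vals.append(float(v))
        x = np.array(vals)
    return float(expit(model.intercept + model.coefficients @ x))


def score_many(model: CancerModel, features: pd.DataFrame) -> np.ndarray:
    """Vectorized scores for a cohort; absent columns contribute 0."""
    X = np.zeros((len(features), len(model.feature_names)))
    for j, f in enumerate(model.feature_names):
        if f in features.columns:
            X[:, j] = features[f].to_numpy(dtype=float)
        else:
            logger.warning("feature %r missing for scoring; using 0", f)
    return expit(model.intercept + X @ model.coefficients)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form: P(s+ > s-) + P(tie)/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("AUC needs both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Origin model: a small fixed neural network


@dataclass
class OriginModel:
    """Single-hidden-layer softmax classifier over candidate origin types."""

    classes: list[str]
    feature_names: list[str]
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        H = expit(X @ self.W1 + self.b1)
        Z = H @ self.W2 + self.b2
        Z = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> list[str]:
        P = self.predict_proba(X)
        return [self.classes[i] for i in P.argmax(axis=1)]


def fit_origin_model(
    features: pd.DataFrame,
    labels: list[str],
    hidden_units: int = 8,
    seed: int = 0,
    max_iter: int = 5000,
    learning_rate: float = 0.5,
) -> OriginModel:
    """Train the multi-class origin network.

    Logistic hidden layer, softmax output, cross-entropy loss, full-batch
    gradient descent with a fixed iteration cap and seeded initialization —
    deterministic for a given seed.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ConfigurationError("origin model needs at least 2 classes")
    X = features.to_numpy(dtype=float)
    n, d = X.shape
    Y = np.zeros((n, len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, 0.5, size=(d, hidden_units))
    b1 = np.zeros(hidden_units)
    W2 = rng.normal(0, 0.5, size=(hidden_units, len(classes)))
    b2 = np.zeros(len(classes))
    losses: list[float] = []
    for _ in range(max_iter):
        H = expit(X @ W1 + b1)
        Z = H @ W2 + b2
        Z = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        losses.append(float(-np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n))
        dZ = (P - Y) / n
        dW2 = H.T @ dZ
        db2 = dZ.sum(axis=0)
        dH = dZ @ W2.T * H * (1 - H)
        dW1 = X.T @ dH
        db1 = dH.sum(axis=0)
        W2 -= learning_rate * dW2
        b2 -= learning_rate * db2
        W1 -= learning_rate * dW1
        b1 -= learning_rate * db1
    return OriginModel(
        classes=classes,
        feature_names=list(features.columns),
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        loss_history=losses,
    )


def build_origin_features(
    exposures: pd.DataFrame,
    type_models: dict[str, CancerModel],
    signature_features: list[str],
) -> pd.DataFrame:
    """Stage-2 input: CTS-MS exposures concatenated with per-type model scores."""
    out = exposures.reindex(columns=signature_features, fill_value=0.0).copy()
    for name in sorted(type_models):
        out[f"score_{name}"] = score_many(type_models[name], exposures)
    return out


@dataclass
class TraceResult:
    sample_id: str
    stage1_call: str  # "liver_primary" or "non_liver_origin"
    stage1_score: float
    origin: str | None = None
    origin_proba: dict[str, float] | None = None


def trace_metastasis(
    exposures: pd.DataFrame,
    liver_model: CancerModel,
    origin_model: OriginModel,
    type_models: dict[str, CancerModel],
    signature_features: list[str],
    threshold: float = 0.5,
) -> list[TraceResult]:
    """Two-stage origin tracing of liver lesions.

    Stage 1: the liver model score at or above ``threshold`` calls a
    primary liver tumor.  Stage 2: remaining lesions are assigned the
    argmax class of the origin network run on their exposures plus the
    candidate-type model scores.
    """
    feats = build_origin_features(exposures, type_models, signature_features)
    if list(feats.columns) != list(origin_model.feature_names):
        raise ConfigurationError(
            "origin model feature mismatch: "
            f"{list(origin_model.feature_names)} vs {list(feats.columns)}"
        )
    s1 = score_many(liver_model, exposures)
    results: list[TraceResult] = []
    for i, sid in enumerate(exposures.index):
        if s1[i] >= threshold:
            results.append(TraceResult(str(sid), "liver_primary", float(s1[i])))
            continue
        proba = origin_model.predict_proba(feats.iloc[[i]].to_numpy())[0]
        results.append(
            TraceResult(
                str(sid),
                "non_liver_origin",
                float(s1[i]),
                origin=origin_model.classes[int(proba.argmax())],
                origin_proba={c: float(p) for c, p in zip(origin_model.classes, proba)},
            )
        )
    return results


def classify_cfdna(
    sample_features: pd.Series | dict,
    model_a: CancerModel,
    model_b: CancerModel,
) -> str:
    """Assign a cfDNA sample to the type whose model scores it higher.

    Exact ties break toward ``model_a`` with a logged flag.
    """
    sa = score(model_a, sample_features)
    sb = score(model_b, sample_features)
    if sa == sb:
        logger.warning(
            "cfDNA tie between %s and %s; breaking toward %s",
            model_a.type_name,
            model_b.type_name,
            model_a.type_name,
        )
        return model_a.type_name
    return model_a.type_name if sa > sb else model_b.type_name


def confusion_stats(
    predictions: list, truth: list, positive_class
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with respect to one class.

    Accuracy is the overall multi-class hit rate; sensitivity and
    specificity binarize on ``positive_class``.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions/truth length mismatch")
    pred = np.asarray(predictions, dtype=object)
    tru = np.asarray(truth, dtype=object)
    accuracy = float((pred == tru).mean())
    pos = tru == positive_class
    neg = ~pos
    tp = float(((pred == positive_class) & pos).sum())
    tn = float(((pred != positive_class) & neg).sum())
    sensitivity = tp / pos.sum() if pos.sum() else float("nan")
    specificity = tn / neg.sum() if neg.sum() else float("nan")
    return accuracy, sensitivity, specificity
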