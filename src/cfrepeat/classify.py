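"""Elastic-net diagnostic classifiers with specificity-anchored thresholds.

Protocol: each disease cohort (cases vs healthy controls) is split into
stratified 80/20 training and testing subsets.  On the training split,
logistic-regression models with an elastic-net penalty are tuned by 10-fold
cross-validation: for each mixing value alpha on an 11-point grid in [0, 1]
(alpha = 1 is the lasso limit, alpha = 0 ridge), the regularization strength
lambda is chosen along a log-spaced path by minimum mean CV binomial
deviance.  Each alpha's winning (alpha, lambda) is refit on the full
training split; the reported model is the candidate with the highest
training sensitivity at 90% specificity, ties broken by training AUC.  The
probability threshold that achieves >= 90% specificity on training controls
is frozen into the model and reused verbatim on the held-out test split,
where sensitivity, specificity, AUC and an exact (Clopper-Pearson) 95%
binomial CI on sensitivity are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))
DEFAULT_TARGET_SPECIFICITY = 0.90


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0


def stratified_split(
    sample_ids: Sequence[str], labels: Sequence[int], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/test split.

    Within each class, floor(n * train_fraction + 0.5) samples are drawn
    without replacement into training (at least 1 in each side when n >= 2).
    """
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for cls in np.unique(labels):
        idx = [i for i, l in enumerate(labels) if l == cls]
        n_train = int(np.floor(len(idx) * spec.train_fraction + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) >= 2 else n_train
        perm = rng.permutation(len(idx))
        chosen = set(perm[:n_train])
        for j, i in enumerate(idx):
            (train if j in chosen else test).append(sample_ids[i])
    return train, test


# ---------------------------------------------------------------------------
# metrics


def auc(probabilities, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation (ties = 1/2)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval."""
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    a = 1.0 - level
    low = 0.0 if successes == 0 else float(beta_dist.ppf(a / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(beta_dist.ppf(1 - a / 2, successes + 1, n - successes))
    return low, high


def threshold_at_specificity(probabilities, labels, target: float = DEFAULT_TARGET_SPECIFICITY) -> float:
    """Smallest probability cutoff achieving specificity >= target.

    A sample is called positive when its probability >= t.  Candidate
    thresholds are the midpoints between adjacent distinct sorted control
    probabilities plus the sentinels 0 and 1; since specificity is
    non-decreasing in t, the smallest qualifying candidate maximizes
    sensitivity subject to the constraint.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    controls = np.sort(np.unique(p[y == 0]))
    if len(controls) == 0:
        raise ValueError("no controls; specificity undefined")
    n_controls = int((y == 0).sum())
    if n_controls < 10:
        logger.warning(
            "only %d controls: a %.0f%% specificity threshold is coarse-grained",
            n_controls,
            100 * target,
        )
    candidates = [0.0] + [(a + b) / 2.0 for a, b in zip(controls[:-1], controls[1:])] + [1.0]
    ctrl = p[y == 0]
    for t in candidates:
        spec = float((ctrl < t).mean())
        if spec >= target:
            return float(t)
    return 1.0


def sensitivity_specificity(probabilities, labels, threshold: float) -> tuple[float, float]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    return sens, spec


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ModelFit:
    """A frozen elastic-net logistic model with its training-derived threshold."""

    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    lam: float  # regularization strength
    beta: pd.Series  # per-feature coefficients (training-standardized scale)
    intercept: float
    feature_set: str
    threshold_90: float
    train_metrics: dict = field(default_factory=dict)
    # training standardization, applied unchanged to test data
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None

    def nonzero_features(self) -> pd.Series:
        return self.beta[self.beta != 0]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[self.beta.index]
        if self.feature_means is not None:
            Xs = (Xs - self.feature_means) / self.feature_sds
        eta = Xs.to_numpy(dtype=float) @ self.beta.to_numpy() + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "feature_set": self.feature_set,
            "threshold_90": self.threshold_90,
            "train_metrics": self.train_metrics,
            "features": list(self.beta.index),
            "beta": {f: float(b) for f, b in self.beta.items() if b != 0},
            "feature_means": None
            if self.feature_means is None
            else {f: float(v) for f, v in self.feature_means.items()},
            "feature_sds": None
            if self.feature_sds is None
            else {f: float(v) for f, v in self.feature_sds.items()},
        }

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelFit":
        with open(path) as fh:
            d = json.load(fh)
        feats = d["features"]
        beta = pd.Series({f: d["beta"].get(f, 0.0) for f in feats}, index=feats, dtype=float)
        return cls(
            alpha=d["alpha"],
            lam=d["lambda"],
            beta=beta,
            intercept=d["intercept"],
            feature_set=d["feature_set"],
            threshold_90=d["threshold_90"],
            train_metrics=d["train_metrics"],
            feature_means=None if d["feature_means"] is None else pd.Series(d["feature_means"]).reindex(feats),
            feature_sds=None if d["feature_sds"] is None else pd.Series(d["feature_sds"]).reindex(feats),
        )


@dataclass
class EvalResult:
    sensitivity: float
    specificity: float
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# training


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, eps: float = 1e-3) -> np.ndarray:
    """glmnet-style log-spaced lambda path from the data-derived lambda_max."""
    n = len(y)
    ybar = y.mean()
    resid = y - ybar
    grad = np.abs(X.T @ resid) / n
    a = max(alpha, 0.05)  # ridge has no finite lambda_max; use the glmnet convention
    lam_max = float(grad.max() / a)
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> LogisticRegression:
    n = len(y)
    # sklearn minimizes loss_sum + penalty/C; glmnet minimizes loss_mean + lam*penalty
    C = 1.0 / max(n * lam, 1e-12)
    if alpha == 0.0:
        model = LogisticRegression(l1_ratio=0.0, C=C, solver="lbfgs", max_iter=2000)
    elif alpha == 1.0:
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6, random_state=0
        )
    else:
        model = LogisticRegression(
            l1_ratio=alpha, C=C, solver="saga", max_iter=5000, tol=1e-5, random_state=0
        )
    model.fit(X, y)
    return model


def cv_train(
    train_matrix: pd.DataFrame,
    labels: pd.Series,
    feature_set_name: str = "features",
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    folds: int = 10,
    n_lambda: int = 20,
    seed: int = 0,
    target_specificity: float = DEFAULT_TARGET_SPECIFICITY,
) -> ModelFit:
    """Cross-validated elastic-net training on samples x features data.

    Features are standardized with training means/sds (zero-sd features are
    left centered only).  For each alpha, lambda minimizing mean CV binomial
    deviance is selected along a log-spaced path; each candidate is refit on
    the full training split and the winner maximizes training sensitivity at
    the target specificity, ties broken by training AUC.
    """
    y = labels.reindex(train_matrix.index).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class")
    mu = train_matrix.mean(axis=0)
    sd = train_matrix.std(axis=0, ddof=1).replace(0.0, 1.0)
    Xs = ((train_matrix - mu) / sd).to_numpy(dtype=float)

    n_splits = min(folds, int(np.bincount(y).min()))
    if n_splits < folds:
        logger.warning("reducing CV folds from %d to %d (small class)", folds, n_splits)
    if n_splits < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_pairs = list(skf.split(Xs, y))

    candidates = []
    for alpha in alpha_grid:
        path = _lambda_path(Xs, y, alpha, n_lambda)
        dev = np.zeros(len(path))
        for tr_idx, va_idx in fold_pairs:
            for k, lam in enumerate(path):
                try:
                    m = _fit_enet(Xs[tr_idx], y[tr_idx], alpha, lam)
                    pv = m.predict_proba(Xs[va_idx])[:, 1]
                    dev[k] += _binomial_deviance(y[va_idx], pv)
                except Exception:
                    dev[k] += np.inf
        best_lam = float(path[int(np.argmin(dev))])
        final = _fit_enet(Xs, y, alpha, best_lam)
        p_train = final.predict_proba(Xs)[:, 1]
        thr = threshold_at_specificity(p_train, y, target_specificity)
        sens, spec = sensitivity_specificity(p_train, y, thr)
        candidates.append(
            {
                "alpha": float(alpha),
                "lambda": best_lam,
                "model": final,
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc(p_train, y),
            }
        )

    candidates.sort(key=lambda c: (c["sensitivity"], c["auc"]), reverse=True)
    best = candidates[0]
    model = best["model"]
    beta = pd.Series(model.coef_.ravel(), index=train_matrix.columns)
    n_case = int((y == 1).sum())
    k_sens = int(round(best["sensitivity"] * n_case))
    lo, hi = binomial_ci(k_sens, n_case)
    return ModelFit(
        alpha=best["alpha"],
        lam=best["lambda"],
        beta=beta,
        intercept=float(model.intercept_[0]),
        feature_set=feature_set_name,
        threshold_90=best["threshold"],
        train_metrics={
            "sensitivity": best["sensitivity"],
            "specificity": best["specificity"],
            "auc": best["auc"],
            "ci_low": lo,
            "ci_high": hi,
            "n_case": n_case,
            "n_control": int((y == 0).sum()),
            "leaderboard": [
                {k: v for k, v in c.items() if k != "model"} for c in candidates
            ],
        },
        feature_means=mu,
        feature_sds=sd,
    )


def evaluate_test(model: ModelFit, test_matrix: pd.DataFrame, labels: pd.Series) -> EvalResult:
    """Evaluate a frozen model on held-out samples at its training threshold."""
    y = labels.reindex(test_matrix.index).to_numpy(dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("test set must contain both classes")
    p = model.predict_proba(test_matrix)
    sens, spec = sensitivity_specificity(p, y, model.threshold_90)
    n_case = int((y == 1).sum())
    lo, hi = binomial_ci(int(round(sens * n_case)), n_case)
    return EvalResult(
        sensitivity=sens,
        specificity=spec,
        auc=auc(p, y),
        ci_low=lo,
        ci_high=hi,
        n_case=n_case,
        n_control=int((y == 0).sum()),
    )


def coefficient_vs_lfc(model: ModelFit, de) -> pd.DataFrame:
    """Nonzero-beta repeat features joined with their DE log2 fold change."""
    from .annotation import REPEAT_PREFIX

    nz = model.nonzero_features()
    rows = []
    for f, b in nz.items():
        if not f.startswith(REPEAT_PREFIX):
            continue
        if f in de.table.index:
            lfc = float(de.table.loc[f, "log2FoldChange"])
        else:
            logger.warning("feature %s missing from DE table", f)
            lfc = np.nan
        rows.append({"feature": f, "beta": float(b), "log2FoldChange": lfc})
    out = pd.DataFrame(rows, columns=["feature", "beta", "log2FoldChange"])
    out.attrs["n_total_nonzero"] = int((nz != 0).sum())
    return out
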