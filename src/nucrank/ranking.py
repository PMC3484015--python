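"""Calibrated logistic ranking of candidate segmentations.

The model regresses the log-odds of a candidate being a well-segmented
nucleus on its features,

    ln p / (1 - p) = alpha + beta_1 x_1 + ... + beta_m x_m,

so the posterior p = sigmoid(alpha + beta . x) is directly a calibrated
probability and the ranked list follows by sorting on it.  Targets may
be *fractional* (mean reviewer labels in [0, 1]); the fit maximises the
Bernoulli-form log-likelihood

    mean_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ] - lambda ||beta||^2,

which for fractional y is equivalent to a two-row expansion weighted by
y and 1 - y.  The mean (not sum) likelihood makes the fit invariant to
duplicating the data.  Features are z-scored with training statistics
stored in the model; a small default ridge (lambda = 1e-4) keeps the
optimum finite on separable data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import rankdata

log = logging.getLogger("nucrank")

DEFAULT_LAMBDA = 1e-4
#: screening threshold for gene-localisation work: posteriors above 0.1
#: keep a candidate (the probability mass concentrates near zero, so a
#: low threshold already removes most bad objects)
DEFAULT_SELECT_TAU = 0.1
#: aggregate labels >= this count as a positive for ROC purposes
DEFAULT_POSITIVE_THRESHOLD = 0.5


@dataclass
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]          # per z-scored feature
    means: dict[str, float]
    scales: dict[str, float]
    feature_names: list[str]
    lambda_: float
    metadata: dict = field(default_factory=dict)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"feature columns missing from input: "
                             f"{missing}")
        Z = np.empty((len(X), len(self.feature_names)))
        for j, f in enumerate(self.feature_names):
            Z[:, j] = ((X[f].to_numpy(dtype=float) - self.means[f])
                       / self.scales[f])
        return Z

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[f] for f in self.feature_names])
        return self.intercept + self._design(X) @ beta

    def raw_coefficients(self) -> tuple[float, dict[str, float]]:
        """Intercept and coefficients on the original feature scale."""
        raw = {f: self.coefficients[f] / self.scales[f]
               for f in self.feature_names}
        alpha = self.intercept - sum(raw[f] * self.means[f]
                                     for f in self.feature_names)
        return alpha, raw

    def to_json(self) -> dict:
        return {"intercept": self.intercept,
                "coefficients": self.coefficients,
                "means": self.means, "scales": self.scales,
                "feature_names": self.feature_names,
                "lambda": self.lambda_, "metadata": self.metadata}

    @classmethod
    def from_json(cls, payload: dict) -> "LogisticModel":
        return cls(intercept=payload["intercept"],
                   coefficients=dict(payload["coefficients"]),
                   means=dict(payload["means"]),
                   scales=dict(payload["scales"]),
                   feature_names=list(payload["feature_names"]),
                   lambda_=payload.get("lambda", DEFAULT_LAMBDA),
                   metadata=dict(payload.get("metadata", {})))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def fit_logistic(X: pd.DataFrame, y: Sequence[float],
                 lambda_: float = DEFAULT_LAMBDA,
                 seed: int | None = None,
                 metadata: dict | None = None) -> LogisticModel:
    """Maximum-penalised-likelihood fit on fractional targets in [0, 1].

    Constant feature columns are dropped with a warning.  With
    ``lambda_ = 0`` on separable data the optimum diverges; the fit
    then raises and advises a positive ridge.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any((y < 0) | (y > 1)):
        raise ValueError("targets must be finite and in [0, 1]")
    if np.unique(y).size < 2:
        raise ValueError("need at least two distinct target values")
    Xv = X.to_numpy(dtype=float)
    if np.any(~np.isfinite(Xv)):
        raise ValueError("features must be finite after imputation")

    names = list(X.columns)
    scales_all = Xv.std(axis=0)
    keep = scales_all > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        log.warning("dropping constant features: %s", dropped)
    names = [n for n, k in zip(names, keep) if k]
    if not names:
        raise ValueError("all features are constant")
    Xv = Xv[:, keep]
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    Z = (Xv - mu) / sd
    n, m = Z.shape

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, beta = w[0], w[1:]
        eta = alpha + Z @ beta
        # mean negative log-likelihood, numerically stable
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        p = _sigmoid(eta)
        resid = p - y
        g_alpha = resid.mean()
        g_beta = Z.T @ resid / n + 2.0 * lambda_ * beta
        val = nll + lambda_ * beta @ beta
        return val, np.concatenate([[g_alpha], g_beta])

    w0 = np.zeros(m + 1)
    res = optimize.minimize(objective, w0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12,
                                     "gtol": 1e-9})
    beta_norm = float(np.linalg.norm(res.x[1:]))
    # on z-scored features a coefficient norm this large means the
    # optimiser is running off to infinity along a separating direction
    if lambda_ == 0 and (not res.success or beta_norm > 15.0):
        raise RuntimeError(
            "logistic fit did not converge (perfect separation?); "
            "use a positive regularisation strength lambda_")
    coef = {f: float(b) for f, b in zip(names, res.x[1:])}
    meta = {"n": int(n), "seed": seed}
    meta.update(metadata or {})
    return LogisticModel(intercept=float(res.x[0]), coefficients=coef,
                         means={f: float(v) for f, v in zip(names, mu)},
                         scales={f: float(v) for f, v in zip(names, sd)},
                         feature_names=names, lambda_=lambda_,
                         metadata=meta)


def predict_posterior(model: LogisticModel, X: pd.DataFrame) -> pd.Series:
    """Calibrated posterior probability of each candidate being a
    well-segmented nucleus."""
    p = _sigmoid(model.linear_predictor(X))
    return pd.Series(p, index=X.index, name="posterior")


def rank_candidates(posteriors: pd.Series) -> pd.DataFrame:
    """Stable descending sort on posterior; ties broken by object id for
    reproducibility.  Returns columns (object_id, posterior, rank)."""
    df = pd.DataFrame({"object_id": posteriors.index.astype(str),
                       "posterior": posteriors.to_numpy(dtype=float)})
    df = df.sort_values(["posterior", "object_id"],
                        ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass
class QualityScore:
    """Mean posterior over a core or subject: the area under the sorted,
    domain-normalised posterior curve, estimating the yield of usable
    nuclei in [0, 1]."""

    scope: str
    value: float
    n: int


def dataset_quality(posteriors: Sequence[float],
                    scope: str = "") -> QualityScore:
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise ValueError("cannot score an empty scope")
    # fsum gives the correctly-rounded sum, so the score is exactly
    # invariant to candidate ordering
    value = math.fsum(p) / p.size
    return QualityScore(scope=scope, value=float(value), n=int(p.size))


def roc_area(scores: Sequence[float], aggregate_labels: Sequence[float],
             positive_threshold: float = DEFAULT_POSITIVE_THRESHOLD,
             ) -> float:
    """ROC area by the tie-corrected rank (Mann-Whitney) formulation.

    Aggregate labels are binarised at ``positive_threshold`` (>= is
    positive, so "maybe"-leaning objects count as positives).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(aggregate_labels, dtype=float) >= positive_threshold
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: one class is empty")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class FoldResult:
    held_out: str          # core id
    subject: str
    roc: float | None
    n_test: int
    positive_fraction: float
    valid: bool = True


def loso_evaluate(X: pd.DataFrame, y: pd.Series, subjects: pd.Series,
                  cores: pd.Series, lambda_: float = DEFAULT_LAMBDA,
                  seed: int | None = None,
                  positive_threshold: float = DEFAULT_POSITIVE_THRESHOLD,
                  ) -> tuple[list[FoldResult], dict]:
    """Leave-one-subject-out evaluation reported per core.

    For each core, the model is trained on all candidates belonging to
    *other subjects* (never on the held-out subject's remaining cores)
    and the core's candidates are scored against their aggregate
    labels.  Folds whose test core contains a single class are flagged
    and excluded from the summary.
    """
    subjects = subjects.reindex(X.index)
    cores = cores.reindex(X.index)
    y = y.reindex(X.index)
    if subjects.nunique() < 2:
        raise ValueError("need at least two subjects")
    results: list[FoldResult] = []
    for core in sorted(cores.dropna().unique()):
        test = cores == core
        subj = subjects[test].iloc[0]
        train = subjects != subj
        model = fit_logistic(X[train], y[train], lambda_=lambda_, seed=seed,
                             metadata={"fold": str(core)})
        post = predict_posterior(model, X[test])
        yt = y[test].to_numpy()
        pos_frac = float((yt >= positive_threshold).mean())
        if pos_frac in (0.0, 1.0):
            log.warning("fold %s has a single class; excluded from the "
                        "summary", core)
            results.append(FoldResult(str(core), str(subj), None,
                                      int(test.sum()), pos_frac,
                                      valid=False))
            continue
        roc = roc_area(post.to_numpy(), yt, positive_threshold)
        results.append(FoldResult(str(core), str(subj), roc,
                                  int(test.sum()), pos_frac))
    valid = [r.roc for r in results if r.valid]
    summary = {"n_folds": len(results), "n_valid": len(valid),
               "mean_roc": float(np.mean(valid)) if valid else None,
               "min_roc": float(np.min(valid)) if valid else None,
               "max_roc": float(np.max(valid)) if valid else None}
    return results, summary


DEFAULT_TRAIN_SIZES = (8, 16, 32, 64, 128, 256, 512, 1024)


def training_size_curve(X: pd.DataFrame, y: pd.Series,
                        sizes: Sequence[int] = DEFAULT_TRAIN_SIZES,
                        reps: int = 500, seed: int = 0,
                        lambda_: float = DEFAULT_LAMBDA,
                        positive_threshold: float =
                        DEFAULT_POSITIVE_THRESHOLD,
                        max_retries: int = 20) -> pd.DataFrame:
    """ROC area vs training-set size: for each size, draw ``reps``
    random training subsets, fit, and score on the complement.

    Returns one row per size with the mean and variance of the ROC
    across repetitions.  Subsets with a single class are redrawn (a
    bounded number of times).
    """
    y = y.reindex(X.index)
    n = len(X)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size >= n:
            raise ValueError(f"training size {size} >= dataset size {n}")
        rocs = []
        for _ in range(reps):
            for _attempt in range(max_retries):
                idx = rng.choice(n, size=size, replace=False)
                train_mask = np.zeros(n, dtype=bool)
                train_mask[idx] = True
                ytr = y.iloc[idx].to_numpy()
                yte = y.iloc[~train_mask].to_numpy()
                pos_tr = (ytr >= positive_threshold)
                pos_te = (yte >= positive_threshold)
                if (np.unique(ytr).size >= 2 and 0 < pos_te.sum() < len(yte)
                        and 0 < pos_tr.sum() < len(ytr)):
                    break
            else:
                raise RuntimeError(
                    f"could not draw a two-class subset of size {size}")
            model = fit_logistic(X.iloc[idx], pd.Series(ytr),
                                 lambda_=lambda_)
            post = predict_posterior(model, X.iloc[~train_mask])
            rocs.append(roc_area(post.to_numpy(), yte, positive_threshold))
        rocs = np.asarray(rocs)
        rows.append({"size": size, "reps": reps,
                     "roc_mean": float(rocs.mean()),
                     "roc_var": float(rocs.var(ddof=1))
                     if reps > 1 else 0.0})
    return pd.DataFrame(rows)


def select_usable(ranked: pd.DataFrame, rule: tuple) -> list[str]:
    """Apply a selection rule to a ranked list.

    ``("threshold", tau)`` keeps posteriors > tau (default screen
    tau = 0.1); ``("top_n", N)`` keeps the first N of the ranked list;
    ``("weights",)`` returns all ids (use the posterior column as the
    per-object weight for a weighted position distribution).
    """
    kind = rule[0]
    if kind == "threshold":
        tau = rule[1] if len(rule) > 1 else DEFAULT_SELECT_TAU
        sel = ranked[ranked["posterior"] > tau]
        return list(sel["object_id"])
    if kind == "top_n":
        n = int(rule[1])
        if n > len(ranked):
            log.warning("top-N with N=%d exceeds list length %d; "
                        "returning all", n, len(ranked))
            n = len(ranked)
        return list(ranked.nsmallest(n, "rank")["object_id"])
    if kind == "weights":
        return list(ranked["object_id"])
    raise ValueError(f"unknown selection rule {kind!r}")
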