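"""Logistic risk models for ECMO-need prediction and their evaluation.

Covers maximum-likelihood logistic fitting with Wald statistics and odds
ratios, the three published fixed-coefficient models (imaging, clinical,
combined) loaded from a versioned constants file, Youden-index cutoff
selection, classification reports and AUROC with bootstrap or DeLong
confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "LogisticModel",
    "published_model",
    "load_published_models",
    "fit_logistic",
    "youden_cutoff",
    "classification_report",
    "roc_auc",
]


@dataclass
class LogisticModel:
    """Intercept + named coefficients + optional classification cutoff."""

    intercept: float
    coefficients: dict[str, float]
    cutoff: float | None = None
    provenance: str = "fitted"
    stats: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.cutoff is not None and not (0.0 < self.cutoff < 1.0):
            raise ValueError(f"cutoff must be in (0,1), got {self.cutoff}")
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("duplicate coefficient names")

    def linear_predictor(self, covariates: Mapping | pd.DataFrame) -> np.ndarray:
        eta = np.asarray(self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            try:
                x = covariates[name]
            except (KeyError, IndexError) as err:
                raise KeyError(f"missing covariate {name!r} required by the model") from err
            eta = eta + beta * np.asarray(x, dtype=float)
        return np.atleast_1d(eta)

    def predict_proba(self, covariates: Mapping | pd.DataFrame) -> np.ndarray:
        """Inverse-logit of the linear predictor."""
        eta = self.linear_predictor(covariates)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    def classify(self, covariates: Mapping | pd.DataFrame, cutoff: float | None = None) -> np.ndarray:
        c = cutoff if cutoff is not None else self.cutoff
        if c is None:
            raise ValueError("no classification cutoff set")
        return (self.predict_proba(covariates) >= c).astype(int)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            cutoff=d.get("cutoff"),
            provenance=d.get("provenance", "fitted"),
        )


def load_published_models() -> dict[str, LogisticModel]:
    """Load the three fixed-coefficient models from the constants file."""
    raw = resources.files("ecmolung").joinpath("data/published_models.json").read_text()
    spec = json.loads(raw)
    return {
        name: LogisticModel(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            cutoff=float(d["cutoff"]),
            provenance="published",
        )
        for name, d in spec.items()
    }


def published_model(name: str) -> LogisticModel:
    """Return one of the published models: 'imaging', 'clinical' or 'combined'."""
    models = load_published_models()
    if name not in models:
        raise KeyError(f"unknown published model {name!r}; choose from {sorted(models)}")
    return models[name]


def fit_logistic(features: pd.DataFrame, outcome, cutoff_from_youden: bool = True) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald inference.

    Returns a :class:`LogisticModel` whose ``stats`` table has one row
    per term with columns B, SE, Wald, p, OR and the 95% OR confidence
    interval (Wald = (B/SE)^2, OR = exp(B), CI = exp(B +/- 1.96 SE)).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    X = sm.add_constant(features.astype(float), has_constant="add")
    bad = X.columns[~np.isfinite(X).all(axis=0)].tolist()
    if bad:
        raise ValueError(f"non-finite values in covariates {bad}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design matrix (rank {rank} < {X.shape[1]}); check covariates {list(features.columns)}"
        )
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # statsmodels raises PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed for covariates {list(features.columns)}: {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise ValueError(f"logistic fit did not converge for covariates {list(features.columns)}")

    params, se = res.params, res.bse
    table = pd.DataFrame(
        {
            "B": params,
            "SE": se,
            "Wald": (params / se) ** 2,
            "p": res.pvalues,
            "OR": np.exp(params),
            "OR_CI_lower": np.exp(params - 1.96 * se),
            "OR_CI_upper": np.exp(params + 1.96 * se),
        }
    )
    model = LogisticModel(
        intercept=float(params["const"]),
        coefficients={c: float(params[c]) for c in features.columns},
        provenance="fitted",
    )
    model.stats = table
    if cutoff_from_youden:
        model.cutoff = youden_cutoff(model.predict_proba(features), y)
    return model


def youden_cutoff(probabilities, outcome) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    The scan runs over the observed probabilities; ties in J are broken
    by the lower threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present to choose a cutoff")
    thresholds = np.unique(p)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_j, best_t = -np.inf, thresholds[0]
    for t in thresholds:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def classification_report(probabilities, outcome, cutoff: float) -> dict:
    """Metrics of the 2x2 table at a fixed cutoff.

    Returns confusion counts plus sensitivity, specificity, PPV, NPV and
    overall accuracy (as percentages) and the 1-df chi-square test of the
    table.  Metrics with an empty margin come back as NaN.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pred = p >= cutoff
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())

    def ratio(a, b):
        return 100.0 * a / b if b > 0 else float("nan")

    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, chi2_p = float("nan"), float("nan")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity_pct": ratio(tp, tp + fn),
        "specificity_pct": ratio(tn, tn + fp),
        "ppv_pct": ratio(tp, tp + fp),
        "npv_pct": ratio(tn, tn + fn),
        "accuracy_pct": ratio(tp + tn, tp + fp + tn + fn),
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
    }


def roc_auc(
    probabilities,
    outcome,
    n_bootstrap: int = 2000,
    seed: int = 0,
    method: str = "bootstrap",
) -> dict:
    """Trapezoidal AUROC with a 95% confidence interval.

    ``method='bootstrap'`` uses a class-stratified bootstrap of the
    subjects (percentile interval); ``method='delong'`` uses the DeLong
    variance of the underlying U-statistic.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present for AUROC")
    auc = float(roc_auc_score(y, p))
    if method == "delong":
        lo, hi = _delong_ci(p, y, auc)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
            reps[b] = roc_auc_score(y[idx], p[idx])
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {"auroc": auc, "ci_lower": float(lo), "ci_upper": float(hi), "method": method}


def _delong_ci(p: np.ndarray, y: np.ndarray, auc: float) -> tuple[float, float]:
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return max(auc - half, 0.0), min(auc + half, 1.0)
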