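"""Cross-validated signature discovery for high-dimensional imaging features.

Six-step pipeline, run inside a 5x repeated 5-fold stratified
cross-validation and aggregated across the 25 experiments:

1. development-fold Yeo-Johnson transform + z-normalization;
2. hierarchical agglomerative clustering of features on Spearman
   correlation (complete linkage, |rho| >= 0.75 within a cluster) with
   one representative per cluster (strongest rank-biserial association
   with the outcome);
3. Mann-Whitney U filter (features with p > 0.2 dropped);
4. minimum-redundancy maximum-relevance (MRMR) ranking, mutual-
   information difference criterion on discretized features;
5. logistic model development on the top-ranked features with AUROC on
   the internal validation fold;
6. Borda-score aggregation of the per-fold rankings, followed by a
   Wald-test / correlation pruning of the top rank groups into the final
   signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.preprocessing import PowerTransformer

log = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    n_repeats: int = 5
    n_folds: int = 5
    cluster_corr_threshold: float = 0.75
    mwu_p_exclude: float = 0.2
    final_corr_threshold: float = 0.5
    n_signature_ranks: int = 3
    n_model_features: int = 5  # per-fold logistic development size
    mrmr_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.cluster_corr_threshold, self.mwu_p_exclude, self.final_corr_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError("thresholds must lie in (0,1)")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class SelectionResult:
    fold_rankings: list[list[str]]
    fold_aurocs: list[float]
    borda_scores: pd.Series
    ranks: pd.Series
    candidates: list[list[str]]  # candidate features grouped by rank (1-based order)
    signature: list[str] = field(default_factory=list)
    wald: pd.Series | None = None


# ---------------------------------------------------------------------------
# Step 1: standardization


def yeo_johnson_standardize(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Yeo-Johnson transform + z-normalization, fitted on ``train`` only.

    Per-feature lambda is estimated by maximum likelihood on the
    development data; the same lambda/centre/scale is applied to
    ``apply_to``.  Constant features cannot be standardized and are
    dropped (logged).
    """
    variances = train.var(axis=0, ddof=0)
    keep = variances[variances > 0].index
    dropped = [c for c in train.columns if c not in set(keep)]
    if dropped:
        log.info("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
    train = train[keep]
    pt = PowerTransformer(method="yeo-johnson", standardize=True)
    train_t = pd.DataFrame(pt.fit_transform(train.to_numpy()), index=train.index, columns=keep)
    if apply_to is None:
        return train_t, None
    apply_t = pd.DataFrame(pt.transform(apply_to[keep].to_numpy()), index=apply_to.index, columns=keep)
    return train_t, apply_t


# ---------------------------------------------------------------------------
# Steps 2-3: clustering + univariate filter


def _rank_biserial(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-biserial effect size and MWU p-value of a feature vs. binary outcome."""
    x1, x0 = x[y == 1], x[y == 0]
    res = stats.mannwhitneyu(x1, x0, alternative="two-sided")
    r = 2.0 * res.statistic / (len(x1) * len(x0)) - 1.0
    return float(r), float(res.pvalue)


def cluster_and_represent(
    features: pd.DataFrame,
    outcome,
    corr_threshold: float = 0.75,
    mwu_p_exclude: float = 0.2,
) -> list[str]:
    """Collapse correlated feature clusters and drop irrelevant features.

    Features are clustered by complete-linkage HAC on the distance
    1 - |Spearman rho|, cut so every within-cluster pair has
    |rho| >= ``corr_threshold``.  Each cluster is represented by the
    feature with the largest absolute rank-biserial association with the
    outcome (ties broken lexicographically); representatives with a
    Mann-Whitney U p-value above ``mwu_p_exclude`` are then excluded.
    """
    y = np.asarray(outcome, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per outcome class")
    cols = list(features.columns)
    if len(cols) == 1:
        return cols
    rho = stats.spearmanr(features.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    labels = hierarchy.fcluster(link, t=1.0 - corr_threshold, criterion="distance")

    effects = {c: _rank_biserial(features[c].to_numpy(), y) for c in cols}
    selected = []
    for cluster in np.unique(labels):
        members = sorted(np.array(cols)[labels == cluster])
        rep = max(members, key=lambda c: (abs(effects[c][0]), [-ord(ch) for ch in c]))
        if effects[rep][1] <= mwu_p_exclude:
            selected.append(rep)
    return [c for c in cols if c in set(selected)]


# ---------------------------------------------------------------------------
# Step 4: MRMR ranking


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges, right=True)


def mrmr_rank(features: pd.DataFrame, outcome, k: int | None = None, bins: int = 4) -> list[str]:
    """Greedy MRMR ordering under the mutual-information difference (MID) criterion.

    Relevance is the mutual information between the (equal-frequency
    discretized) feature and the outcome; redundancy is the mean MI with
    the already-selected features.  At each step the feature maximizing
    relevance - redundancy is appended; ties resolve to the earlier
    column, so the ordering is deterministic given the input order.
    """
    y = np.asarray(outcome, dtype=int)
    cols = list(features.columns)
    if k is None or k > len(cols):
        k = len(cols)
    disc = {c: _discretize(features[c].to_numpy(), bins) for c in cols}
    relevance = {c: mutual_info_score(disc[c], y) for c in cols}

    selected: list[str] = []
    remaining = list(cols)
    mi_cache: dict[tuple[str, str], float] = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[a], disc[b])
        return mi_cache[key]

    while remaining and len(selected) < k:
        if not selected:
            scores = [relevance[c] for c in remaining]
        else:
            scores = [
                relevance[c] - np.mean([pair_mi(c, s) for s in selected]) for c in remaining
            ]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# Steps 5-6: cross-validated discovery + Borda aggregation


def borda_aggregate(fold_rankings: list[list[str]]) -> pd.Series:
    """Sum positional Borda points over folds: a ranking of length k
    awards k - position points to the feature at 1-based ``position``
    (top feature gets k - 1); unranked features score 0."""
    scores: dict[str, float] = {}
    for ranking in fold_rankings:
        k = len(ranking)
        for pos, name in enumerate(ranking, start=1):
            scores[name] = scores.get(name, 0.0) + (k - pos)
    return pd.Series(scores, dtype=float).sort_values(ascending=False)


def run_cv_discovery(features: pd.DataFrame, outcome, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Run the full cross-validated reduction pipeline.

    Each of the n_repeats x n_folds experiments standardizes, clusters,
    filters and MRMR-ranks the features on its development folds only,
    fits a logistic model on the top-ranked features and logs its AUROC
    on the held-out fold.  Rankings are Borda-aggregated; features in
    the top ``n_signature_ranks`` dense rank groups become signature
    candidates.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary with both classes present")
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.n_folds, n_repeats=cfg.n_repeats, random_state=cfg.seed
    )
    fold_rankings: list[list[str]] = []
    fold_aurocs: list[float] = []
    for dev_idx, val_idx in splitter.split(features, y):
        y_dev, y_val = y[dev_idx], y[val_idx]
        if len(np.unique(y_dev)) < 2 or len(np.unique(y_val)) < 2:
            raise ValueError("fold without both outcome classes; reduce folds or rebalance")
        dev_t, val_t = yeo_johnson_standardize(features.iloc[dev_idx], features.iloc[val_idx])
        kept = cluster_and_represent(
            dev_t, y_dev, cfg.cluster_corr_threshold, cfg.mwu_p_exclude
        )
        if not kept:
            fold_rankings.append([])
            fold_aurocs.append(float("nan"))
            continue
        ranking = mrmr_rank(dev_t[kept], y_dev, bins=cfg.mrmr_bins)
        fold_rankings.append(ranking)

        top = ranking[: cfg.n_model_features]
        clf = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized
        clf.fit(dev_t[top].to_numpy(), y_dev)
        p_val = clf.predict_proba(val_t[top].to_numpy())[:, 1]
        fold_aurocs.append(float(roc_auc_score(y_val, p_val)))

    borda = borda_aggregate(fold_rankings)
    # dense rank groups by descending Borda score
    unique_scores = sorted(borda.unique(), reverse=True)
    rank_of_score = {s: r for r, s in enumerate(unique_scores, start=1)}
    ranks = borda.map(rank_of_score).astype(int)
    candidates = [
        sorted(ranks.index[ranks == r]) for r in range(1, cfg.n_signature_ranks + 1)
        if (ranks == r).any()
    ]
    return SelectionResult(
        fold_rankings=fold_rankings,
        fold_aurocs=fold_aurocs,
        borda_scores=borda,
        ranks=ranks,
        candidates=candidates,
    )


def _univariate_wald(x: np.ndarray, y: np.ndarray) -> float:
    X = sm.add_constant(pd.DataFrame({"x": x}))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return float("inf")  # separation: maximally informative
    return float((res.params["x"] / res.bse["x"]) ** 2)


def finalize_signature(
    result: SelectionResult,
    features: pd.DataFrame,
    outcome,
    final_corr_threshold: float = 0.5,
) -> SelectionResult:
    """Prune the candidate rank groups into the final signature.

    Within each rank group the feature with the largest univariate
    logistic Wald statistic survives; the survivors are then scanned in
    rank order, and any feature whose absolute Spearman correlation with
    a retained, more important feature exceeds the threshold is dropped.
    """
    if not result.candidates or not any(result.candidates):
        raise ValueError("no signature candidates available")
    y = np.asarray(outcome, dtype=int)
    wald = pd.Series(
        {c: _univariate_wald(features[c].to_numpy(), y) for group in result.candidates for c in group}
    )
    per_group = [max(group, key=lambda c: (wald[c], [-ord(ch) for ch in c])) for group in result.candidates if group]

    signature: list[str] = []
    for cand in per_group:
        redundant = any(
            abs(stats.spearmanr(features[cand], features[kept]).statistic) > final_corr_threshold
            for kept in signature
        )
        if not redundant:
            signature.append(cand)
    result.signature = signature
    result.wald = wald
    return result
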