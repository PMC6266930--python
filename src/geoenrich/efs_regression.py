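"""Ensemble feature selection for regression on sparse enriched tables.

The pipeline mirrors ensemble feature selection (EFS): (1) prefilter features
with missing values, excessive zeros, or zero variance; (2) collapse groups of
mutually correlated features (Spearman |rho| > 0.7) to one representative;
(3) score the survivors with K complementary importance measures, each
normalised to sum to 1/K so the ensemble weight of all features sums to 1;
(4) keep features whose ensemble weight strictly exceeds the mean weight.

The default K = 4 regression measures are absolute Pearson and Spearman
correlation with the target, permutation importance from a bagged-trees
ensemble, and absolute coefficients of an L1-regularised standardised linear
fit. The measure set is pluggable: any callable
``(X: DataFrame, y: Series, rng: Generator) -> ndarray`` of non-negative
scores can be registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

ImportanceFn = Callable[[pd.DataFrame, pd.Series, np.random.Generator], np.ndarray]


@dataclass
class FeatureTable:
    """Instances x named numeric features plus an aligned target vector."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if self.X.columns.has_duplicates:
            raise ValueError("feature names must be unique")
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
            if self.y.isna().any():
                raise ValueError("instance ids of features and target do not align")

    @property
    def n_instances(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class FilterSpec:
    drop_any_missing: bool = True
    max_zero_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FeatureWeights:
    """Per-method and ensemble weights; ensemble weights sum to 1."""

    ensemble: pd.Series
    per_method: dict[str, pd.Series]

    def ranked(self) -> pd.Series:
        """Weights sorted descending, feature name as lexicographic tie-break."""
        df = self.ensemble.rename("w").rename_axis("feature").reset_index()
        df = df.sort_values(["w", "feature"], ascending=[False, True])
        return df.set_index("feature")["w"]


@dataclass(frozen=True)
class CorrelationGroups:
    """representative feature -> the set of pruned features it stands in for."""

    groups: dict[str, set[str]]


def prefilter_features(
    t: FeatureTable, spec: FilterSpec = FilterSpec()
) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Drop unusable features; return the reduced table and a drop report.

    Dropped: any feature with >= 1 missing value (databases occasionally fail
    per row); any feature whose zero fraction strictly exceeds
    ``max_zero_fraction``; any zero-variance feature. Strict inequality at the
    zero cutoff: a feature with exactly the cutoff fraction of zeros is kept.
    """
    if t.n_instances < 2:
        raise ValueError("prefilter needs at least 2 instances")
    X = t.X
    arr = X.to_numpy(dtype=float)
    n = len(X)
    has_missing = np.isnan(arr).any(axis=0) if spec.drop_any_missing else np.zeros(arr.shape[1], bool)
    zero_frac = (arr == 0).sum(axis=0) / n
    too_sparse = ~has_missing & (zero_frac > spec.max_zero_fraction)
    with np.errstate(invalid="ignore"):
        constant = ~has_missing & ~too_sparse & (np.nanstd(arr, axis=0) == 0)
    cols = np.asarray(X.columns)
    report = {
        "missing": list(cols[has_missing]),
        "zeros": list(cols[too_sparse]),
        "variance": list(cols[constant]),
    }
    keep = cols[~(has_missing | too_sparse | constant)]
    if len(keep) == 0:
        raise ValueError("prefilter dropped every feature")
    return FeatureTable(X[list(keep)], t.y), report


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=0)


def _abs_corr_with_target(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with y, vectorised; NaN (constant col) -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.abs(np.nan_to_num(r))


def correlation_prune(
    t: FeatureTable, rho_cutoff: float = 0.7
) -> tuple[FeatureTable, CorrelationGroups]:
    """Collapse Spearman-correlated feature groups to one representative.

    Features are visited in descending absolute Spearman correlation with the
    target (lexicographic tie-break), so the "most descriptive" member of each
    correlated set becomes its representative; a visited feature joins the
    first representative with |rho| > cutoff, else starts a new group. The
    group map is returned so selected features can be read as stand-ins for
    their correlated sets.
    """
    if t.n_instances < 3:
        raise ValueError("Spearman correlation needs at least 3 instances")
    cols = list(t.X.columns)
    Xr = _rank_matrix(t.X.to_numpy(dtype=float))
    yr = stats.rankdata(t.y.to_numpy(dtype=float))
    target_rho = _abs_corr_with_target(Xr, yr)
    order = sorted(range(len(cols)), key=lambda i: (-target_rho[i], cols[i]))
    # Feature-feature Spearman = Pearson on ranks; one matmul for the whole
    # matrix is far cheaper than pairwise calls inside the greedy loop.
    sd = Xr.std(axis=0)
    Xs = (Xr - Xr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = Xr.shape[0]
    rho_abs = np.abs(Xs.T @ Xs) / n
    reps: list[int] = []
    groups: dict[str, set[str]] = {}
    for i in order:
        if reps:
            hits = np.nonzero(rho_abs[i, reps] > rho_cutoff)[0]
            if hits.size:
                groups[cols[reps[int(hits[0])]]].add(cols[i])
                continue
        reps.append(i)
        groups[cols[i]] = set()
    kept = [cols[i] for i in sorted(reps)]
    return FeatureTable(t.X[kept], t.y), CorrelationGroups(groups)


# ---------------------------------------------------------------------------
# importance measures


def pearson_importance(X: pd.DataFrame, y: pd.Series, rng) -> np.ndarray:
    return _abs_corr_with_target(X.to_numpy(dtype=float), y.to_numpy(dtype=float))


def spearman_importance(X: pd.DataFrame, y: pd.Series, rng) -> np.ndarray:
    Xr = _rank_matrix(X.to_numpy(dtype=float))
    yr = stats.rankdata(y.to_numpy(dtype=float))
    return _abs_corr_with_target(Xr, yr)


def bagged_trees_permutation_importance(
    X: pd.DataFrame,
    y: pd.Series,
    rng: np.random.Generator,
    n_estimators: int = 100,
    n_repeats: int = 2,
    max_depth: int | None = 3,
) -> np.ndarray:
    """Permutation importance of a bagged-trees regressor, clipped at 0.

    Bagged trees = bootstrap forest with all features eligible at each split;
    depth is capped (default 3) so the trees act as committee-voted main
    effects rather than memorising the few dozen training rows. A feature's
    importance is the mean decrease in training R^2 when its column is
    shuffled.
    """
    seed = int(rng.integers(2**31 - 1))
    forest = RandomForestRegressor(
        n_estimators=n_estimators, max_features=1.0, bootstrap=True,
        max_depth=max_depth, random_state=seed,
    )
    Xa = X.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    forest.fit(Xa, ya)
    base = forest.score(Xa, ya)
    perm_rng = np.random.default_rng(seed)
    imp = np.zeros(Xa.shape[1])
    # a feature used in no split has exactly zero permutation importance
    used = np.nonzero(forest.feature_importances_ > 0)[0]
    for j in used:
        drop = 0.0
        for _ in range(n_repeats):
            saved = Xa[:, j].copy()
            Xa[:, j] = perm_rng.permutation(saved)
            drop += base - forest.score(Xa, ya)
            Xa[:, j] = saved
        imp[j] = drop / n_repeats
    return np.clip(imp, 0.0, None)


def lasso_importance(
    X: pd.DataFrame,
    y: pd.Series,
    rng: np.random.Generator,
    n_alphas: int = 10,
) -> np.ndarray:
    """L1-based importance: relaxed-lasso coefficients plus residual screening.

    An L1 fit on standardised features (penalty from a small fixed relative
    grid, chosen by internal 5-fold CV) yields a support; the support is
    refit by least squares (relaxed lasso) and scored by |coefficient|. The
    refit residual is then screened once against all features — the iterated
    sure-screening step — so a predictive feature masked by the selected set
    (whose partial association only appears once the captured signal is
    removed) still receives mass. Each half is normalised to sum 0.5.
    """
    Xa = X.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    n = len(ya)
    sd = Xa.std(axis=0)
    Xs = (Xa - Xa.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    seed = int(rng.integers(2**31 - 1))
    cv = KFold(n_splits=min(5, n), shuffle=True, random_state=seed)
    model = LassoCV(alphas=n_alphas, eps=1e-3, cv=cv, max_iter=5000)
    model.fit(Xs, ya)
    coef = np.abs(model.coef_)
    support = np.nonzero(coef)[0]
    if 0 < len(support) < n - 2:
        A = np.column_stack([np.ones(n), Xs[:, support]])
        beta = np.linalg.lstsq(A, ya, rcond=None)[0]
        coef = np.zeros_like(coef)
        coef[support] = np.abs(beta[1:])
        resid = ya - A @ beta
    else:
        resid = ya - model.predict(Xs)
    rcor = _abs_corr_with_target(Xs, resid) if resid.std() > 0 else np.zeros_like(coef)
    rcor[support] = 0.0  # support features already carry coefficient mass
    parts = []
    for v in (coef, rcor):
        s = v.sum()
        parts.append(v / (2.0 * s) if s > 0 else np.zeros_like(v))
    return parts[0] + parts[1]


DEFAULT_METHODS: dict[str, ImportanceFn] = {
    "pearson": pearson_importance,
    "spearman": spearman_importance,
    "permutation_bagged_trees": bagged_trees_permutation_importance,
    "lasso": lasso_importance,
}

#: Fast configuration (rank/linear correlation only) for heavy resampling
#: loops where the full ensemble is computationally out of reach.
CORRELATION_METHODS: dict[str, ImportanceFn] = {
    "pearson": pearson_importance,
    "spearman": spearman_importance,
}


def ensemble_importance(
    t: FeatureTable,
    seed: int = 0,
    methods: dict[str, ImportanceFn] | None = None,
) -> FeatureWeights:
    """Sum of K importance measures, each normalised to total 1/K.

    Every method's raw non-negative scores are divided by their own sum (a
    method yielding all-zero scores contributes a uniform 1/K instead, so the
    ensemble total is always exactly 1).
    """
    if t.n_instances < 5:
        raise ValueError("ensemble importance needs at least 5 instances")
    if t.X.shape[1] < 2:
        raise ValueError("ensemble importance needs at least 2 features")
    if t.y.nunique() <= 1:
        raise ValueError("target is constant; importance is undefined")
    methods = DEFAULT_METHODS if methods is None else methods
    k = len(methods)
    rng = np.random.default_rng(seed)
    per_method: dict[str, pd.Series] = {}
    for name, fn in methods.items():
        raw = np.asarray(fn(t.X, t.y, rng), dtype=float)
        if raw.min() < 0:
            raise ValueError(f"importance method {name!r} returned negative scores")
        total = raw.sum()
        w = raw / (total * k) if total > 0 else np.full(len(raw), 1.0 / (len(raw) * k))
        per_method[name] = pd.Series(w, index=t.X.columns)
    ensemble = sum(per_method.values())
    return FeatureWeights(ensemble=ensemble, per_method=per_method)


def select_by_mean_cutoff(w: FeatureWeights) -> list[str]:
    """Keep features whose ensemble weight strictly exceeds the mean weight.

    When all weights are equal the mean equals every weight and nothing would
    survive a strict cutoff, so the degenerate case keeps everything.
    """
    weights = w.ensemble
    if len(weights) == 0:
        raise ValueError("no features to select from")
    mean = weights.mean()
    selected = weights[weights > mean]
    if selected.empty:
        return list(weights.index)
    return list(selected.index)


@dataclass(frozen=True)
class EfsConfig:
    """One knob object for the full selection pipeline."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    rho_cutoff: float = 0.7
    methods: dict[str, ImportanceFn] | None = None  # None -> DEFAULT_METHODS


@dataclass(frozen=True)
class EfsResult:
    selected: list[str]
    weights: FeatureWeights
    groups: CorrelationGroups
    drop_report: dict[str, list[str]]


def efs_select(t: FeatureTable, config: EfsConfig = EfsConfig(), seed: int = 0) -> EfsResult:
    """Full pipeline: prefilter -> correlation prune -> ensemble -> cutoff."""
    filtered, report = prefilter_features(t, config.filter_spec)
    pruned, groups = correlation_prune(filtered, config.rho_cutoff)
    weights = ensemble_importance(pruned, seed=seed, methods=config.methods)
    selected = select_by_mean_cutoff(weights)
    return EfsResult(selected=selected, weights=weights, groups=groups, drop_report=report)
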