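"""LOOCV model evaluation with per-fold feature selection, plus inference
(bootstrap confidence intervals, permutation tests) and feature-ranking
stability diagnostics.

Evaluation is leave-one-out: for each instance, the full selection pipeline
runs on the remaining instances only, a regressor is trained on the selected
features, and the held-out instance is predicted — feature selection never
sees the held-out row, so pooled performance is leakage-free. Pooled R^2 is
the squared Pearson correlation between the n held-out predictions and the
observed targets.

Stability across folds is measured on the per-fold top-k ranked feature
lists: Kendall's tau-a on the induced rankings of each pair's common
features, and the Jaccard distance 1 - |intersection|/|union| on the sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .efs_regression import EfsConfig, FeatureTable, FeatureWeights, efs_select

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# regressor registry


def _make_ridge(seed: int):
    return make_pipeline(StandardScaler(), Ridge(alpha=1.0))


def _make_knn(seed: int):
    return make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=3))


def _make_tree(seed: int):
    return DecisionTreeRegressor(random_state=seed)


def _make_bagged(seed: int):
    return RandomForestRegressor(
        n_estimators=50, max_features=1.0, bootstrap=True, random_state=seed
    )


def _make_gbt(seed: int):
    return GradientBoostingRegressor(n_estimators=100, random_state=seed)


def _make_linear(seed: int):
    from sklearn.linear_model import LinearRegression

    return make_pipeline(StandardScaler(), LinearRegression())


def _make_mean(seed: int):
    # NOTE: under squared-correlation LOOCV scoring the fold-mean predictor is
    # exactly anti-correlated with the held-out values (pred = (S - y_i)/(n-1))
    # and scores ~1; use "constant" for a zero-skill baseline.
    from sklearn.dummy import DummyRegressor

    return DummyRegressor(strategy="mean")


def _make_constant(seed: int):
    from sklearn.dummy import DummyRegressor

    return DummyRegressor(strategy="constant", constant=0.0)


MODEL_REGISTRY: dict[str, Callable[[int], object]] = {
    "linear": _make_linear,
    "ridge": _make_ridge,
    "knn": _make_knn,
    "tree": _make_tree,
    "bagged": _make_bagged,
    "gbt": _make_gbt,
    "mean": _make_mean,
    "constant": _make_constant,
}


@dataclass(frozen=True)
class RegressorSpec:
    """A named model from the registry, or any fit/predict factory."""

    name: str
    factory: Callable[[int], object] | None = None

    def build(self, seed: int):
        factory = self.factory or MODEL_REGISTRY.get(self.name)
        if factory is None:
            raise ValueError(
                f"unknown model {self.name!r}; registered: {sorted(MODEL_REGISTRY)}"
            )
        return factory(seed)


# ---------------------------------------------------------------------------
# scoring


def pooled_r2(predictions: np.ndarray, observations: np.ndarray) -> float:
    """Squared Pearson correlation of predictions vs observations, in [0, 1].

    A degenerate (constant) prediction vector has undefined correlation and
    scores 0.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.std() == 0 or o.std() == 0:
        return 0.0
    return float(np.corrcoef(p, o)[0, 1] ** 2)


def coefficient_of_determination(predictions: np.ndarray, observations: np.ndarray) -> float:
    """1 - SS_res/SS_tot; can be negative, available as an alternative score."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    ss_tot = ((o - o.mean()) ** 2).sum()
    return float(1.0 - ((o - p) ** 2).sum() / ss_tot)


@dataclass
class FoldRecord:
    held_out_id: object
    selected: list[str]
    weights: FeatureWeights
    prediction: float


@dataclass
class EvaluationResult:
    r2: float
    predictions: pd.Series
    observations: pd.Series
    folds: list[FoldRecord]


def loocv_evaluate(
    t: FeatureTable,
    model: RegressorSpec,
    efs_config: EfsConfig = EfsConfig(),
    seed: int = 0,
) -> EvaluationResult:
    """Leave-one-out evaluation with feature selection strictly inside each fold."""
    if t.n_instances < 5:
        raise ValueError("LOOCV evaluation needs at least 5 instances")
    ids = list(t.X.index)
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(ids)) % (2**31 - 1)
    preds = []
    folds = []
    for i, held in enumerate(ids):
        train_ids = [x for x in ids if x != held]
        train = FeatureTable(t.X.loc[train_ids], t.y.loc[train_ids])
        fs = int(fold_seeds[i])
        reg = model.build(fs)  # unknown model -> clean error before any fitting
        try:
            result = efs_select(train, efs_config, seed=fs)
            reg.fit(train.X[result.selected].to_numpy(), train.y.to_numpy())
            # the held-out row may carry missing values invisible to the
            # training-fold prefilter; impute with training-fold means
            xh = t.X.loc[[held], result.selected]
            if xh.isna().any(axis=None):
                xh = xh.fillna(train.X[result.selected].mean())
            pred = float(np.asarray(reg.predict(xh.to_numpy())).ravel()[0])
        except Exception as exc:  # pragma: no cover - error contract
            raise RuntimeError(f"model fit failed on fold holding out {held!r}: {exc}") from exc
        preds.append(pred)
        folds.append(
            FoldRecord(held_out_id=held, selected=result.selected,
                       weights=result.weights, prediction=pred)
        )
    predictions = pd.Series(preds, index=ids, name="prediction")
    observations = t.y.copy()
    return EvaluationResult(
        r2=pooled_r2(predictions.to_numpy(), observations.to_numpy()),
        predictions=predictions,
        observations=observations,
        folds=folds,
    )


def bootstrap_r2_ci(
    predictions: np.ndarray,
    observations: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Bootstrap the R^2 of (prediction, observation) pairs.

    Pairs are resampled with replacement B times; each resample's squared
    Pearson correlation forms the distribution and the 2.5/97.5 percentiles
    the interval. Degenerate resamples (constant vector, undefined
    correlation) are redrawn; their count is logged.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if len(p) < 5:
        raise ValueError("bootstrap needs at least 5 pairs")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, len(p), size=len(p))
            if p[idx].std() > 0 and o[idx].std() > 0:
                out[b] = np.corrcoef(p[idx], o[idx])[0, 1] ** 2
                break
            redraws += 1
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    return out, (float(np.percentile(out, 2.5)), float(np.percentile(out, 97.5)))


@dataclass(frozen=True)
class PermutationResult:
    B: int
    t: int
    p: float
    observed_r2: float
    permuted_r2: np.ndarray
    seed: int

    @property
    def p_label(self) -> str:
        return f"< {1.0 / self.B:g}" if self.t == 0 else f"{self.p:g}"


def permutation_test(
    t: FeatureTable,
    model: RegressorSpec,
    efs_config: EfsConfig = EfsConfig(),
    B: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Target-permutation overfitting test on the entire pipeline.

    Each of the B rounds permutes the target and reruns everything —
    per-fold feature selection included — so selection bias cannot hide in
    the null distribution. t counts permuted R^2 >= the observed R^2 and
    p = t/B (reported as "< 1/B" when t = 0).
    """
    ss = np.random.SeedSequence(seed)
    eval_seed, perm_seed = (int(s) for s in ss.generate_state(2) % (2**31 - 1))
    observed = loocv_evaluate(t, model, efs_config, seed=eval_seed).r2
    rng = np.random.default_rng(perm_seed)
    permuted = np.empty(B)
    for b in range(B):
        y_perm = pd.Series(rng.permutation(t.y.to_numpy()), index=t.y.index)
        tb = FeatureTable(t.X, y_perm)
        permuted[b] = loocv_evaluate(tb, model, efs_config, seed=eval_seed).r2
    t_count = int((permuted >= observed).sum())
    return PermutationResult(
        B=B, t=t_count, p=t_count / B, observed_r2=observed,
        permuted_r2=permuted, seed=seed,
    )


# ---------------------------------------------------------------------------
# ranked-list distances


def kendall_tau(x: list[str], y: list[str], variant: str = "a") -> float:
    """Kendall's tau between two ranked feature lists.

    Restricted to the items both lists share; tau-a = (c - d) / (n(n-1)/2)
    over that intersection's induced strict rankings (no tie correction;
    ``variant="b"`` applies the tie-corrected form, identical here since
    induced ranks are strict). Returns NaN with a warning when fewer than two
    items are shared.
    """
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    y_set = set(y)
    common = [f for f in x if f in y_set]
    if len(common) < 2:
        logger.warning("kendall_tau undefined: lists share %d item(s)", len(common))
        return math.nan
    pos_y = {f: i for i, f in enumerate(y)}
    ry = np.array([pos_y[f] for f in common])
    n = len(common)
    # x's induced ranks are 0..n-1 in order, so pair (i < j) concordance is
    # sign(ry[j] - ry[i]); integer counting keeps the boundary values exact.
    # Induced ranks are strict, so tau-b's tie correction is a no-op and the
    # two variants coincide.
    diff = np.sign(ry[None, :] - ry[:, None])
    upper = np.triu_indices(n, k=1)
    c_minus_d = int(diff[upper].sum())
    return c_minus_d / (n * (n - 1) / 2)


def jaccard_distance(x: set[str], y: set[str]) -> float:
    """d_J = (|x ∪ y| - |x ∩ y|) / |x ∪ y|; 0 for identical, 1 for disjoint."""
    x, y = set(x), set(y)
    union = x | y
    if not union:
        raise ValueError("Jaccard distance undefined for two empty sets")
    return (len(union) - len(x & y)) / len(union)


def top_k_list(weights: FeatureWeights, k: int = 50) -> list[str]:
    """Feature names ranked by descending ensemble weight, truncated to k."""
    return list(weights.ranked().index[:k])


@dataclass(frozen=True)
class StabilityResult:
    mean_tau: float
    sd_tau: float
    mean_jaccard: float
    sd_jaccard: float
    n_pairs: int


def stability_summary(folds: list[FoldRecord], k: int = 50) -> StabilityResult:
    """Mean +/- sd of pairwise tau and Jaccard distance over fold top-k lists."""
    if len(folds) < 2:
        raise ValueError("stability needs at least 2 folds")
    lists = [top_k_list(f.weights, k) for f in folds]
    taus, jacs = [], []
    for i in range(len(lists)):
        for j in range(i + 1, len(lists)):
            tau = kendall_tau(lists[i], lists[j])
            if not math.isnan(tau):
                taus.append(tau)
            jacs.append(jaccard_distance(set(lists[i]), set(lists[j])))
    return StabilityResult(
        mean_tau=float(np.mean(taus)) if taus else math.nan,
        sd_tau=float(np.std(taus)) if taus else math.nan,
        mean_jaccard=float(np.mean(jacs)),
        sd_jaccard=float(np.std(jacs)),
        n_pairs=len(jacs),
    )


def importance_decline(
    folds: list[FoldRecord], top_m: int = 25
) -> pd.DataFrame:
    """Average normalised weight and modal-feature frequency per rank.

    Per fold, features are ranked by descending weight; the mean weight at
    each rank across folds is divided by the rank-1 mean (so rank 1 reads
    1.0), and the modal frequency is the relative frequency of the most
    common feature name at that rank.
    """
    if len(folds) < 2:
        raise ValueError("importance decline needs at least 2 folds")
    ranked = [f.weights.ranked() for f in folds]
    top_m = min(top_m, min(len(r) for r in ranked))
    mean_w = np.array(
        [np.mean([r.iloc[rank] for r in ranked]) for rank in range(top_m)]
    )
    norm_w = mean_w / mean_w[0]
    modal = []
    for rank in range(top_m):
        names = pd.Series([r.index[rank] for r in ranked])
        modal.append(names.value_counts(normalize=True).iloc[0])
    return pd.DataFrame(
        {"rank": np.arange(1, top_m + 1), "norm_mean_weight": norm_w,
         "modal_frequency": modal}
    ).set_index("rank")
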