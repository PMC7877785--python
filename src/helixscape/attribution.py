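"""Gradient-boosted-tree modelling of fold-change and SHAP attribution.

Genotypes are encoded as 32 one-hot features (8 sites x 4 nucleotides)
and a gradient-boosted regression-tree ensemble predicts the response
(log2 fold-change by default) from nucleotide identities alone.  Local
attribution uses exact tree-path-dependent SHAP values (computed by the
tree library itself via ``pred_contribs``), which satisfy the
local-accuracy identity: base value + sum of per-feature SHAP = model
prediction for every genotype.  DeltaSHAP aggregates these per feature
as mean(SHAP | feature present) - mean(SHAP | feature absent); total
split gain per feature supports the region-share permutation test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.model_selection import GridSearchCV, KFold, train_test_split

from .genotype_space import ALPHABET, SITES, parse_genotype

logger = logging.getLogger(__name__)

FEATURE_NAMES = [f"s{site}_{base}" for site in SITES for base in ALPHABET]
REGION_18_21 = [f"s{site}_{base}" for site in (18, 19, 20, 21) for base in ALPHABET]
REGION_2_5 = [f"s{site}_{base}" for site in (2, 3, 4, 5) for base in ALPHABET]

#: the hyperparameter grid used for full-scale tuning
FULL_GRID = {
    "n_estimators": [100, 200, 500, 1000],
    "learning_rate": [0.01, 0.05, 0.1, 0.3],
    "max_depth": [4, 6, 8, 10],
    "subsample": [0.5, 0.75, 1.0],
    "min_child_weight": [5, 10, 20],
}

#: reduced default grid; full grid available via ``GBMConfig(grid=FULL_GRID)``
FAST_GRID = {
    "n_estimators": [200],
    "learning_rate": [0.1, 0.3],
    "max_depth": [4, 6],
    "subsample": [0.75],
    "min_child_weight": [10],
}


@dataclass
class GBMConfig:
    grid: dict = field(default_factory=lambda: dict(FAST_GRID))
    cv_folds: int = 3
    test_fraction: float = 1 / 3
    seed: int = 0
    min_genotypes: int = 1000


@dataclass
class TrainedModel:
    model: xgb.XGBRegressor
    features: pd.DataFrame
    response: pd.Series
    test_index: pd.Index
    holdout_spearman: float
    best_params: dict


def one_hot_features(genotypes) -> pd.DataFrame:
    """32 binary features, one block of four per site (blocks sum to 1)."""
    seqs = np.array([list(parse_genotype(g).seq) for g in genotypes])
    data = {}
    for j, site in enumerate(SITES):
        for base in ALPHABET:
            data[f"s{site}_{base}"] = (seqs[:, j] == base).astype(np.int8)
    return pd.DataFrame(data, index=pd.Index(genotypes, name="genotype"))


def _make_regressor(seed: int, **params) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **params,
    )


def train_gbm(
    features: pd.DataFrame, response: pd.Series, config: GBMConfig | None = None
) -> TrainedModel:
    """Tune and fit the tree ensemble; report held-out rank accuracy.

    Two thirds of the genotypes train the model (with k-fold
    cross-validated grid search over ``config.grid``); the held-out
    third yields the Spearman correlation between predicted and
    observed response.
    """
    config = config or GBMConfig()
    if len(features) < config.min_genotypes:
        raise ValueError(
            f"need >= {config.min_genotypes} genotypes with a response, got {len(features)}"
        )
    y = response.loc[features.index]
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, y, test_size=config.test_fraction, random_state=config.seed
    )
    n_combos = int(np.prod([len(v) for v in config.grid.values()]))
    if n_combos > 1:
        search = GridSearchCV(
            _make_regressor(config.seed),
            config.grid,
            cv=KFold(config.cv_folds, shuffle=True, random_state=config.seed),
            scoring="neg_root_mean_squared_error",
            n_jobs=1,
        )
        search.fit(X_tr, y_tr)
        best = search.best_params_
        model = search.best_estimator_
    else:
        best = {k: v[0] for k, v in config.grid.items()}
        model = _make_regressor(config.seed, **best).fit(X_tr, y_tr)
    rho, _ = stats.spearmanr(model.predict(X_te), y_te)
    logger.info("held-out Spearman rho=%.3f best=%s", rho, best)
    return TrainedModel(model, features, y, X_te.index, float(rho), best)


def shap_values(model: xgb.XGBRegressor, features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Exact per-genotype, per-feature SHAP values and the base value.

    Uses the tree library's built-in tree-path-dependent algorithm; the
    last contribution column (the expected model output) is returned
    separately as ``base``.
    """
    contribs = model.get_booster().predict(
        xgb.DMatrix(features, feature_names=list(features.columns)), pred_contribs=True
    )
    shap = pd.DataFrame(contribs[:, :-1], index=features.index, columns=features.columns)
    base = contribs[:, -1]
    return shap, base


def delta_shap(shap: pd.DataFrame, features: pd.DataFrame) -> pd.Series:
    """mean SHAP with the feature present minus with it absent, per feature."""
    out = {}
    for name in features.columns:
        present = features[name].to_numpy(dtype=bool)
        if present.all() or not present.any():
            out[name] = np.nan  # constant feature: undefined
            continue
        col = shap[name].to_numpy()
        out[name] = float(col[present].mean() - col[~present].mean())
    return pd.Series(out, name="delta_shap")


def feature_gains(model: xgb.XGBRegressor, feature_names=FEATURE_NAMES) -> pd.Series:
    """Total split gain per feature (0 for features never used)."""
    raw = model.get_booster().get_score(importance_type="total_gain")
    return pd.Series({name: raw.get(name, 0.0) for name in feature_names}, name="gain")


@dataclass
class GainShareResult:
    observed_share: float
    null_mean: float
    null_lo: float  # 2.5th percentile
    null_hi: float  # 97.5th percentile
    n_shuffles: int

    @property
    def outside_null(self) -> bool:
        return self.observed_share > self.null_hi or self.observed_share < self.null_lo


def gain_share_test(
    gains: pd.Series,
    region: list[str] = REGION_18_21,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> GainShareResult:
    """Share of total gain in a feature region vs a permutation null.

    The null shuffles gain values across all feature slots, so its
    expected region share is (features in region)/(total features).
    """
    rng = rng or np.random.default_rng(0)
    total = gains.sum()
    if total <= 0:
        raise ValueError("total gain is zero; model has no splits")
    in_region = gains.index.isin(region)
    observed = float(gains[in_region].sum() / total)
    vals = gains.to_numpy(dtype=float)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = vals[rng.permutation(len(vals))][in_region].sum() / total
    return GainShareResult(
        observed_share=observed,
        null_mean=float(null.mean()),
        null_lo=float(np.percentile(null, 2.5)),
        null_hi=float(np.percentile(null, 97.5)),
        n_shuffles=n_shuffles,
    )


def replicate_log2fc(
    pre: pd.DataFrame, post: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-replicate log2 fold-change of depth-normalized frequencies."""
    out = {}
    for i, (cpre, cpost) in enumerate(zip(pre.columns, post.columns)):
        fpre = (pre[cpre] + pseudocount) / pre[cpre].sum()
        fpost = (post[cpost] + pseudocount) / post[cpost].sum()
        out[f"rep{i + 1}"] = np.log2(fpost / fpre)
    return pd.DataFrame(out, index=pre.index)


def leave_one_replicate_out(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    config: GBMConfig | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Train on fold-changes from all-but-one replicate, test on the rest.

    For each replicate r the response is the mean per-replicate log2
    fold-change over the other replicates; model accuracy is the
    Spearman correlation against replicate r's own fold-change on the
    held-out genotype third.  Requires >= 3 replicates.
    """
    if pre.shape[1] < 3:
        raise ValueError("need at least 3 replicates")
    config = config or GBMConfig()
    l2fc = replicate_log2fc(pre, post, pseudocount)
    feats = one_hot_features(list(l2fc.index))
    rows = []
    for r, col in enumerate(l2fc.columns):
        others = l2fc.drop(columns=col).mean(axis=1)
        trained = train_gbm(feats, others, config)
        pred = trained.model.predict(feats.loc[trained.test_index])
        rho, _ = stats.spearmanr(pred, l2fc.loc[trained.test_index, col])
        rows.append((col, float(rho), trained.holdout_spearman))
    out = pd.DataFrame(rows, columns=["replicate", "loro_spearman", "pooled_holdout_spearman"])
    return out
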