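"""Diversity metrics, DFE summaries and simple fitness correlates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from sklearn.mixture import GaussianMixture

from .genotype_space import gc_count, hamming


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity ``H = -sum p ln p`` of a count vector.

    Natural log by default; pass ``base`` to change the unit.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(x, y))


def pairwise_bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis matrix across the columns of a count table."""
    cols = counts.columns
    out = pd.DataFrame(0.0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            d = bray_curtis(counts[a], counts[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out


@dataclass
class DFESummary:
    """Moment statistics and a two-component view of the fitness distribution."""

    n: int
    mean: float
    median: float
    skewness: float
    excess_kurtosis: float
    component_means: tuple[float, float]
    component_weights: tuple[float, float]
    bimodal: bool
    histogram: tuple[np.ndarray, np.ndarray]


def dfe_summary(
    fitness, bins: int = 50, random_state: int = 0, log: bool = True
) -> DFESummary:
    """Summarize the distribution of fitness effects.

    Moments are computed on the given scale; bimodality is assessed by a
    two-component Gaussian mixture on log fitness (positive values
    only), flagged when the component means are separated by more than
    twice the larger component standard deviation.
    """
    f = np.asarray(fitness, dtype=float)
    f = f[np.isfinite(f)]
    if len(f) < 2:
        raise ValueError("need at least two fitness estimates")
    x = np.log(f[f > 0]) if log else f
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(
        x.reshape(-1, 1)
    )
    means = gm.means_.ravel()
    order = np.argsort(means)
    means = means[order]
    weights = gm.weights_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel())[order]
    bimodal = bool(
        abs(means[1] - means[0]) > 2.0 * max(sds) and min(weights) > 0.05
    )
    hist = np.histogram(x, bins=bins)
    return DFESummary(
        n=len(f),
        mean=float(f.mean()),
        median=float(np.median(f)),
        skewness=float(stats.skew(f)),
        excess_kurtosis=float(stats.kurtosis(f)),
        component_means=(float(means[0]), float(means[1])),
        component_weights=(float(weights[0]), float(weights[1])),
        bimodal=bimodal,
        histogram=hist,
    )


def fitness_by_hamming(fitness: pd.Series, reference: str) -> pd.DataFrame:
    """Median and quartiles of fitness grouped by distance to ``reference``."""
    d = np.array([hamming(g, reference) for g in fitness.index])
    df = pd.DataFrame({"f": fitness.to_numpy(), "d": d})
    g = df.groupby("d")["f"]
    out = pd.DataFrame(
        {
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
            "n": g.size(),
        }
    )
    out.index.name = "d"
    return out


def feature_correlates(
    fitness: pd.Series, features: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Spearman rank correlation of fitness with per-genotype features.

    With no ``features`` given, the GC count over the eight variable
    sites is used.  Constant features are reported with NaN correlation.
    """
    if features is None:
        features = pd.DataFrame(
            {"gc_count": [gc_count(g) for g in fitness.index]}, index=fitness.index
        )
    rows = []
    f = fitness.to_numpy(dtype=float)
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(f)
        if len(np.unique(x[ok])) < 2:
            rows.append((name, np.nan, np.nan, int(ok.sum())))
            continue
        rho, p = stats.spearmanr(x[ok], f[ok])
        rows.append((name, float(rho), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["feature", "rho", "p", "n"]).set_index("feature")
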