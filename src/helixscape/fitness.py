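"""Relative fitness from pre/post-selection counts across replicates.

Each genotype's fitness is estimated the way variant-effect pipelines
score deep mutational scans: per replicate, the log ratio of the
genotype's frequency change is taken relative to the master sequence
(``s_r = ln[(n_post+c)/(n_post_master+c)] - ln[(n_pre+c)/(n_pre_master+c)]``),
replicates are combined by inverse-variance weighting with Poisson
count-propagated variances, and the standard error is inflated whenever
between-replicate scatter exceeds the Poisson expectation.  Relative
fitness is ``f = exp(s)`` with ``f(master) = 1`` exactly.  A pooled
log2 fold-change per genotype (selected vs unselected, median-of-ratios
normalized) is reported alongside, and a two-sided z-test with
Benjamini-Hochberg adjustment flags significant frequency changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_space import MASTER

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The geometric mean over samples is taken per genotype using only
    genotypes with nonzero counts in every sample; each sample's factor
    is the median of its counts over those reference rows.  With no
    common nonzero genotype the method degrades to total-count
    normalization (logged).
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        logger.warning("no genotype covered in all samples; using total-count factors")
        totals = mat.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(totals))), index=counts.columns)
    ref = mat[allpos]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.median(ref / np.exp(log_geo), axis=0)
    return pd.Series(factors, index=counts.columns)


def _split_by_replicate(
    counts: pd.DataFrame, sheet: pd.DataFrame, temperature: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sub = sheet[sheet["temperature"] == temperature]
    pre_cols, post_cols = [], []
    for rep in sorted(sub["replicate"].unique()):
        r = sub[sub["replicate"] == rep]
        pre = r.loc[~r["selected"], "sample"]
        post = r.loc[r["selected"], "sample"]
        if len(pre) != 1 or len(post) != 1:
            raise ValueError(f"replicate {rep} needs exactly one pre and one post sample")
        pre_cols.append(pre.iloc[0])
        post_cols.append(post.iloc[0])
    return counts[pre_cols], counts[post_cols]


def replicate_fitness(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    master: str = MASTER,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate master-normalized log fitness and Poisson variance.

    ``pre`` and ``post`` must have the same number of columns, ordered
    by replicate.  Returns ``(s, var)``, each genotype x replicate.
    """
    if pre.shape[1] != post.shape[1]:
        raise ValueError("pre and post must have the same replicate structure")
    if master not in pre.index:
        raise ValueError(f"master genotype {master!r} not in count table")
    c = pseudocount
    npre = pre.to_numpy(dtype=float) + c
    npost = post.to_numpy(dtype=float) + c
    mpre = npre[pre.index.get_loc(master)]
    mpost = npost[post.index.get_loc(master)]
    s = (np.log(npost) - np.log(mpost)) - (np.log(npre) - np.log(mpre))
    var = 1.0 / npre + 1.0 / npost + 1.0 / mpre + 1.0 / mpost
    cols = [f"rep{i + 1}" for i in range(pre.shape[1])]
    return (
        pd.DataFrame(s, index=pre.index, columns=cols),
        pd.DataFrame(var, index=pre.index, columns=cols),
    )


def combine_replicates(
    s: pd.DataFrame, var: pd.DataFrame
) -> pd.DataFrame:
    """Error-weighted combination of replicate log-fitness values.

    Weighted mean with ``w_r = 1/var_r``; the standard error
    ``1/sqrt(sum w_r)`` is inflated by ``sqrt(chi2/(R-1))`` whenever the
    replicate scatter exceeds its Poisson expectation.  Genotypes with
    no finite-variance replicate are flagged unestimable (NaN).
    """
    sv = s.to_numpy(dtype=float)
    vv = var.to_numpy(dtype=float)
    w = np.zeros_like(vv)
    finite = np.isfinite(vv) & (vv > 0)
    w[finite] = 1.0 / vv[finite]
    wsum = w.sum(axis=1)
    ok = wsum > 0
    shat = np.full(len(sv), np.nan)
    shat[ok] = (w * np.nan_to_num(sv))[ok].sum(axis=1) / wsum[ok]
    se = np.full(len(sv), np.nan)
    se[ok] = 1.0 / np.sqrt(wsum[ok])
    nrep = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        chi2 = (w * (sv - shat[:, None]) ** 2).sum(axis=1)
        dof = np.maximum(nrep - 1, 1)
        inflate = np.sqrt(np.maximum(1.0, chi2 / dof))
    se = se * inflate
    out = pd.DataFrame({"s": shat, "se": se, "n_replicates": nrep}, index=s.index)
    out.loc[~ok, ["s", "se"]] = np.nan
    return out


def test_differential(combined: pd.DataFrame) -> pd.Series:
    """Two-sided z-test on ``s/se`` with Benjamini-Hochberg adjustment."""
    z = combined["s"] / combined["se"]
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = np.full(len(p), np.nan)
    ok = np.isfinite(p)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.Series(p_adj, index=combined.index, name="p_adj")


def log2_foldchange(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """Pooled log2 fold-change of normalized post vs pre abundance."""
    if factors is None:
        factors = size_factors(pd.concat([pre, post], axis=1))
    pre_n = (pre / factors[pre.columns]).sum(axis=1)
    post_n = (post / factors[post.columns]).sum(axis=1)
    return np.log2(post_n + pseudocount) - np.log2(pre_n + pseudocount)


def fitness_table(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    temperature: str = "30C",
    master: str = MASTER,
    pseudocount: float = PSEUDOCOUNT,
    min_pre_count: int = 0,
) -> pd.DataFrame:
    """Full fitness table for one temperature condition.

    Columns: ``f`` (relative fitness, master = 1), ``log2fc``, ``se``,
    ``p_adj``, ``n_pre``, ``n_post``, ``condition``.  Genotypes with
    zero counts in every pre-selection sample are reported as missing
    (dropped), not as fitness 0.
    """
    pre, post = _split_by_replicate(counts, sheet, temperature)
    n_pre = pre.sum(axis=1)
    n_post = post.sum(axis=1)
    observed = n_pre > 0
    if min_pre_count:
        observed &= n_pre >= min_pre_count
    pre, post = pre[observed], post[observed]

    s, var = replicate_fitness(pre, post, master, pseudocount)
    combined = combine_replicates(s, var)
    p_adj = test_differential(combined)
    l2fc = log2_foldchange(pre, post, pseudocount=pseudocount)

    out = pd.DataFrame(
        {
            "f": np.exp(combined["s"]),
            "log2fc": l2fc,
            "se": combined["se"],
            "p_adj": p_adj,
            "n_pre": n_pre[observed],
            "n_post": n_post[observed],
        }
    )
    out["condition"] = temperature
    # master-normalized by construction; enforce exactness
    out.loc[master, "f"] = 1.0
    return out
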