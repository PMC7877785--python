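"""Pairwise epistasis, region-partitioned epistasis, gamma(d) and the mirror test.

Pairwise epistasis is measured on relative fitness (master = 1) as

    epsilon = log10( f_master * f_m12 / (f_m1 * f_m2) )

so that epsilon > 0 means the double mutant does better than the
multiplicative expectation of its constituent singles.  Genotypes with
nonpositive or missing fitness are excluded, never clipped: clipping
would manufacture spurious epistasis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_space import ALPHABET, MASTER, SITES, hamming, mirror, parse_genotype

logger = logging.getLogger(__name__)

_LEFT_SITES = frozenset((2, 3, 4, 5))


def _norm(g: str) -> str:
    return g.replace("-", "").upper()


def _site_labels(n: int) -> tuple[int, ...]:
    """Canonical intron site labels for 8-site genotypes, positional otherwise."""
    return SITES if n == 8 else tuple(range(1, n + 1))


def pairwise_epsilon(f_master: float, f_m1: float, f_m2: float, f_m12: float) -> float:
    """Deviation of the double mutant from multiplicative expectation."""
    vals = (f_master, f_m1, f_m2, f_m12)
    if any(v is None or not np.isfinite(v) or v <= 0 for v in vals):
        return float("nan")
    return math.log10(f_master * f_m12 / (f_m1 * f_m2))


def _classify(site1: int, site2: int, n_sites: int) -> str:
    if n_sites != 8:
        return "unlabeled"
    a, b = site1 in _LEFT_SITES, site2 in _LEFT_SITES
    if a and b:
        return "within_2_5"
    if not a and not b:
        return "within_18_21"
    return "cross_helix"


def _mutate(seq: str, idx: int, base: str) -> str:
    return seq[:idx] + base + seq[idx + 1 :]


def _canon(seq: str) -> str:
    return seq[:4] + "-" + seq[4:]


def epistasis_map_d2(fitness: pd.Series, reference: str = MASTER) -> pd.DataFrame:
    """All pairwise-epistasis records for double mutants of ``reference``.

    One record per (site pair, allele pair): 28 site pairs x 9 allele
    combinations = 252 when the fitness table is complete.  Missing or
    nonpositive fitness values yield NaN epsilon (logged in bulk).
    Accepts genotypes of any fixed length; for 8-site genotypes the
    records carry intron site labels and a helix-region class.
    """
    ref = _norm(reference)
    lookup = {_norm(g): v for g, v in fitness.items()}
    f_ref = lookup.get(ref, np.nan)
    labels = _site_labels(len(ref))
    rows = []
    for (i, s1), (j, s2) in itertools.combinations(enumerate(labels), 2):
        for b1 in ALPHABET:
            if b1 == ref[i]:
                continue
            for b2 in ALPHABET:
                if b2 == ref[j]:
                    continue
                f1 = lookup.get(_mutate(ref, i, b1), np.nan)
                f2 = lookup.get(_mutate(ref, j, b2), np.nan)
                f12 = lookup.get(_mutate(_mutate(ref, i, b1), j, b2), np.nan)
                eps = pairwise_epsilon(f_ref, f1, f2, f12)
                rows.append(
                    (s1, b1, s2, b2, f_ref, f1, f2, f12, eps, _classify(s1, s2, len(ref)))
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "site1", "base1", "site2", "base2",
            "f_master", "f_m1", "f_m2", "f_m12", "epsilon", "pair_class",
        ],
    )
    n_bad = int(out["epsilon"].isna().sum())
    if n_bad:
        logger.info("epistasis map: %d/%d records undefined (missing/nonpositive fitness)", n_bad, len(out))
    return out


def epistasis_summary(records: pd.DataFrame) -> dict:
    eps = records["epsilon"].dropna()
    return {
        "n": int(len(eps)),
        "mean": float(eps.mean()) if len(eps) else float("nan"),
        "fraction_positive": float((eps > 0).mean()) if len(eps) else float("nan"),
    }


def partitioned_epistasis(
    fitness: pd.Series, reference: str = MASTER
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Epsilon distributions split by where the two mutations fall.

    Classes: both in sites 2-5 (other half fixed), both in sites 18-21,
    or one in each (cross-helix).  Returns the per-class epsilon samples
    and a rank-sum (Mann-Whitney) comparison between each class pair.
    """
    records = epistasis_map_d2(fitness, reference)
    groups = {
        cls: sub["epsilon"].dropna().to_numpy()
        for cls, sub in records.groupby("pair_class")
    }
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) and len(groups[b]):
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append((a, b, float(u), float(p), float(np.median(groups[a]) - np.median(groups[b]))))
    tests = pd.DataFrame(rows, columns=["class_a", "class_b", "U", "p", "median_diff"])
    return groups, tests


@dataclass
class GammaPoint:
    d: int
    gamma: float
    n_pairs: int


def gamma_correlation(
    fitness: pd.Series, reference: str = MASTER, d: int = 1, log: bool = True
) -> GammaPoint:
    """Correlation of fitness effects between the reference and distance-d backgrounds.

    For every single substitution ``m`` (site s, base b) applicable to
    the reference, and every background ``g`` at Hamming distance ``d``
    from the reference that agrees with the reference at site s, the
    effect of ``m`` in the reference, ``logf(ref+m) - logf(ref)``, is
    paired with its effect in the background, ``logf(g+m) - logf(g)``.
    gamma(d) is the Pearson correlation over all such pairs; an additive
    landscape gives gamma = 1 at every distance, a random landscape
    gamma ~ 0.  Effects are computed on log fitness by default.
    """
    ref = _norm(reference)
    n_sites = len(ref)
    if not 0 <= d <= n_sites - 1:
        raise ValueError("d must be in [0, n_sites - 1]")
    lookup = {}
    for g, v in fitness.items():
        if np.isfinite(v) and (v > 0 or not log):
            lookup[_norm(g)] = math.log(v) if log else v

    xs, ys = [], []
    backgrounds = [
        s for s in lookup if sum(a != b for a, b in zip(s, ref)) == d
    ]
    for i in range(n_sites):
        for b in ALPHABET:
            if b == ref[i]:
                continue
            ref_mut = _mutate(ref, i, b)
            if ref not in lookup or ref_mut not in lookup:
                continue
            eff_ref = lookup[ref_mut] - lookup[ref]
            for g in backgrounds:
                if g[i] != ref[i]:
                    continue
                gm = _mutate(g, i, b)
                if gm in lookup:
                    xs.append(eff_ref)
                    ys.append(lookup[gm] - lookup[g])
    if len(xs) < 3:
        return GammaPoint(d, float("nan"), len(xs))
    r, _ = stats.pearsonr(xs, ys)
    return GammaPoint(d, float(r), len(xs))


def gamma_profile(
    fitness: pd.Series, reference: str = MASTER, max_d: int | None = None
) -> pd.DataFrame:
    n_sites = len(_norm(reference))
    max_d = n_sites - 1 if max_d is None else max_d
    pts = [gamma_correlation(fitness, reference, d) for d in range(max_d + 1)]
    return pd.DataFrame(
        {"d": [p.d for p in pts], "gamma": [p.gamma for p in pts], "n_pairs": [p.n_pairs for p in pts]}
    )


def mirror_test(
    fitness: pd.Series, reference: str = MASTER, d: int = 2
) -> tuple[float, float, int]:
    """Spearman correlation between fitness of genotypes and their helix mirrors.

    Only genotypes whose mirror lies at the same Hamming distance ``d``
    from the reference are compared; self-mirror genotypes are excluded
    and each unordered pair is counted once.  Returns ``(rho, p, N)``;
    with fewer than 3 pairs the correlation is undefined (NaN).
    """
    lookup = {str(parse_genotype(g)): v for g, v in fitness.items()}
    seen = set()
    xs, ys = [], []
    for g, v in lookup.items():
        if g in seen or not np.isfinite(v):
            continue
        m = str(mirror(g))
        if m == g or m in seen:
            continue
        if hamming(g, reference) != d or hamming(m, reference) != d:
            continue
        vm = lookup.get(m, np.nan)
        if not np.isfinite(vm):
            continue
        seen.update((g, m))
        xs.append(v)
        ys.append(vm)
    n = len(xs)
    if n < 3:
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), n
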