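"""Imaging-pathology association battery.

Normality screening (Shapiro-Wilk), nonparametric group comparison
(Kruskal-Wallis, used also for two-level factors), rank correlation
(Spearman, exact permutation p for tiny samples), categorical association
(chi-squared when expected counts allow, Fisher's exact otherwise), cohort
frequency summaries and a correlation-matrix report of every imaging
feature against every pathology covariate.  No multiplicity correction is
applied by default; each cell is flagged at the two-sided 0.05 level (a
Benjamini-Hochberg option exists but is off unless requested).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
#: exact-permutation thresholds (total sample size)
SPEARMAN_EXACT_N = 8
KRUSKAL_EXACT_N = 9


@dataclass
class AssociationResult:
    test: str
    description: str
    statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; valid for 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_statistic(values, labels, n_groups):
    """Tie-corrected H for integer group labels 0..n_groups-1."""
    ranks = sps.rankdata(values)
    n = values.size
    h = 0.0
    for g in range(n_groups):
        r = ranks[labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(groups, exact_max_n: int = KRUSKAL_EXACT_N) -> AssociationResult:
    """Kruskal-Wallis H test across two or more samples.

    For total n <= ``exact_max_n`` the p-value is the exact permutation
    tail over all assignments of the pooled values to the group sizes;
    otherwise the chi-squared approximation with g-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    n = sum(g.size for g in groups)
    if n < 3:
        raise ValueError("need a total of at least 3 observations")

    values = np.concatenate(groups)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h = _kw_statistic(values, labels, len(groups))
        if n <= exact_max_n:
            p = _kw_exact_p(values, [g.size for g in groups], h)
        else:
            p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return AssociationResult("kruskal-wallis", f"{len(groups)} groups", float(h), p, n)


def _kw_exact_p(values, sizes, h_obs):
    """Exact permutation distribution of H over all group assignments."""
    idx = np.arange(values.size)
    count = total = 0
    for labels in _assignments(idx, sizes):
        h = _kw_statistic(values, labels, len(sizes))
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _assignments(idx, sizes):
    """Yield label vectors for every partition of idx into the group sizes."""
    if len(sizes) == 1:
        lab = np.zeros(idx.size, dtype=int)
        yield lab
        return
    for combo in itertools.combinations(range(idx.size), sizes[0]):
        first = np.zeros(idx.size, dtype=bool)
        first[list(combo)] = True
        for sub in _assignments(idx[~first], sizes[1:]):
            lab = np.empty(idx.size, dtype=int)
            lab[first] = 0
            lab[~first] = sub + 1
            yield lab


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x, y, exact_max_n: int = SPEARMAN_EXACT_N) -> AssociationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t approximation, or from the exhaustive n!
    permutation distribution when n <= ``exact_max_n``.  Constant input
    yields a NaN statistic (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult("spearman", "constant input", np.nan, np.nan, n)

    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - ry.mean()
        rhos = (p_c @ rx_c) / np.sqrt((rx_c**2).sum() * (p_c**2).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return AssociationResult("spearman", f"n={n}", rho, p, n)


# ---------------------------------------------------------------------------
# categorical association
# ---------------------------------------------------------------------------

def categorical_assoc(table, seed: int = 0, n_sim: int = 10000) -> AssociationResult:
    """Chi-squared or Fisher's exact test on a contingency table.

    Chi-squared (no continuity correction) when every expected count is
    >= 5; otherwise Fisher's exact for 2x2 tables, or a seeded Monte
    Carlo chi-squared p (random tables with fixed margins) for larger
    ones.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2x2 or larger table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("table has a zero margin")
    n = int(t.sum())
    expected = np.outer(rows, cols) / n

    if np.all(expected >= 5):
        res = sps.chi2_contingency(t, correction=False)
        return AssociationResult("chi-squared", f"{t.shape[0]}x{t.shape[1]}",
                                 float(res.statistic), float(res.pvalue), n)
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return AssociationResult("fisher-exact", "2x2", np.nan, float(p), n)
    stat_obs = float(np.sum((t - expected) ** 2 / expected))
    rng = np.random.default_rng(seed)
    sim = sps.random_table(rows, cols).rvs(n_sim, random_state=rng)
    stats_sim = np.sum((sim - expected) ** 2 / expected, axis=(1, 2))
    p = (1 + np.sum(stats_sim >= stat_obs - 1e-12)) / (1 + n_sim)
    return AssociationResult("fisher-simulated", f"{t.shape[0]}x{t.shape[1]}",
                             stat_obs, float(p), n)


# ---------------------------------------------------------------------------
# cohort summaries and the association report
# ---------------------------------------------------------------------------

def cohort_summary(cohort: pd.DataFrame, categorical=None, continuous=None) -> dict:
    """Frequency summary of a cohort table.

    Categorical columns: level counts and percentages of the cohort size
    (one decimal).  Continuous columns: median and interquartile range.
    Returns ``{"categorical": DataFrame, "continuous": DataFrame}``.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if categorical is None:
        categorical = [c for c in cohort.columns
                       if cohort[c].dtype == object or cohort[c].dtype == bool]
    if continuous is None:
        continuous = [c for c in cohort.columns
                      if np.issubdtype(cohort[c].dtype, np.number)]

    cat_rows = []
    for col in categorical:
        counts = cohort[col].value_counts(dropna=True)
        denom = int(counts.sum())
        for level, cnt in counts.items():
            cat_rows.append({
                "variable": col, "level": level, "count": int(cnt),
                "percent": round(100.0 * cnt / denom, 1),
            })
    cont_rows = []
    for col in continuous:
        v = cohort[col].dropna()
        q25, q50, q75 = np.percentile(v, [25, 50, 75]) if len(v) else (np.nan,) * 3
        cont_rows.append({"variable": col, "median": q50, "iqr": q75 - q25,
                          "n": int(len(v))})
    return {"categorical": pd.DataFrame(cat_rows),
            "continuous": pd.DataFrame(cont_rows)}


def association_report(cohort: pd.DataFrame, feature_cols, factor_cols=(),
                       continuous_cols=("tils_percent", "tsr_percent"),
                       alpha: float = ALPHA, bh_correct: bool = False) -> dict:
    """Feature-by-covariate association matrices.

    For each imaging feature column: Kruskal-Wallis across the levels of
    every categorical factor and Spearman correlation against every
    continuous covariate, with pairwise deletion of missing rows.
    Factors with fewer than two populated levels are skipped (logged).

    Returns dict with ``spearman_rho``/``spearman_p`` (covariates x
    features), ``kruskal_h``/``kruskal_p`` (factors x features),
    ``significant`` concatenated flags, and the ``skipped`` list.
    """
    feature_cols = list(feature_cols)
    rho = pd.DataFrame(index=list(continuous_cols), columns=feature_cols, dtype=float)
    sp_p = rho.copy()
    kw_h = pd.DataFrame(index=list(factor_cols), columns=feature_cols, dtype=float)
    kw_p = kw_h.copy()
    skipped = []

    for feat in feature_cols:
        fvals = cohort[feat]
        for cov in continuous_cols:
            pair = pd.concat([fvals, cohort[cov]], axis=1).dropna()
            if len(pair) < 3:
                skipped.append((feat, cov, "fewer than 3 complete pairs"))
                continue
            res = spearman(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            rho.loc[cov, feat] = res.statistic
            sp_p.loc[cov, feat] = res.p_value
        for fac in factor_cols:
            pair = pd.concat([fvals, cohort[fac]], axis=1).dropna()
            levels = pair.iloc[:, 1].unique()
            if len(levels) < 2:
                skipped.append((feat, fac, "fewer than 2 populated levels"))
                logger.info("skipping %s x %s: fewer than 2 populated levels", feat, fac)
                continue
            groups = [pair.loc[pair.iloc[:, 1] == lev, feat].to_numpy() for lev in levels]
            if sum(g.size for g in groups) < 3:
                skipped.append((feat, fac, "too few observations"))
                continue
            res = kruskal_wallis(groups)
            kw_h.loc[fac, feat] = res.statistic
            kw_p.loc[fac, feat] = res.p_value

    p_all = pd.concat([sp_p, kw_p])
    if bh_correct:
        flat = p_all.to_numpy().ravel()
        mask = np.isfinite(flat)
        adj = flat.copy()
        adj[mask] = sps.false_discovery_control(flat[mask], method="bh")
        p_adj = pd.DataFrame(adj.reshape(p_all.shape), index=p_all.index,
                             columns=p_all.columns)
        logger.warning("Benjamini-Hochberg correction applied; the default "
                       "report is uncorrected")
        significant = p_adj < alpha
    else:
        significant = p_all < alpha
    return {"spearman_rho": rho, "spearman_p": sp_p, "kruskal_h": kw_h,
            "kruskal_p": kw_p, "significant": significant, "skipped": skipped}
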