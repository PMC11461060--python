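"""Inferential toolbox shared by the proxy modules.

Non-parametric rank tests (rank-sum, Spearman with the
sum-of-squared-rank-differences statistic S), the Box-Cox transform,
sequential-SS factorial (M)ANOVA and LSD post hoc contrasts.  Thin,
documented wrappers around scipy/statsmodels where those implement the
standard machinery, with the reporting conventions pinned down (exact
enumeration for small rank-sum samples, S = (1 − rho)·n(n² − 1)/6).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from paleodent.datamodel import ValidationError


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    dof: float | tuple | None = None
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Rank tests
# --------------------------------------------------------------------------

_EXACT_LIMIT = 200_000  # max number of enumerated subsets for the exact branch


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample rank-sum test (Wilcoxon / Mann-Whitney) with midrank ties.

    Exact enumeration of the permutation distribution of the rank sum
    when the number of subsets is small enough; otherwise the normal
    approximation with tie correction.  Two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("rank-sum", 0.0, 1.0, n=(len(x), len(y)))
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    w = float(ranks[:n].sum())

    if math.comb(n + m, n) <= _EXACT_LIMIT:
        # full enumeration of the rank-sum distribution under exchange
        sums = np.fromiter(
            (ranks[list(idx)].sum() for idx in itertools.combinations(range(n + m), n)),
            dtype=float)
        mean = sums.mean()
        p = float(np.mean(np.abs(sums - mean) >= abs(w - mean) - 1e-12))
        method = "exact"
    else:
        mean = n * (n + m + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts))
        var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
        if var <= 0:
            return TestResult("rank-sum", w, 1.0, n=(n, m))
        zstat = (w - mean) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(zstat)))
        method = "normal"
    return TestResult("rank-sum", w, min(1.0, p), n=(n, m), extra={"method": method})


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with the classical S statistic.

    rho is the product-moment correlation of midranks;
    S = (1 − rho)·n(n² − 1)/6, the convention under which rho and S are
    mutually consistent even in the presence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    n = len(x)
    s = (1.0 - rho) * n * (n ** 2 - 1) / 6.0
    return TestResult("spearman", float(rho), float(p), n=(n,),
                      extra={"S": float(s)})


def spearman_n_from_s(rho: float, s: float) -> int:
    """Invert S = (1 − rho)·n(n² − 1)/6 for the integer sample size."""
    target = 6.0 * s / (1.0 - rho)
    # n(n²−1) is strictly increasing; solve by rounding the cubic root
    n = round(target ** (1.0 / 3.0))
    best = min(range(max(2, n - 2), n + 3), key=lambda k: abs(k * (k * k - 1) - target))
    return best


# --------------------------------------------------------------------------
# Box-Cox
# --------------------------------------------------------------------------

def boxcox(x: Sequence[float], shift: float = 0.0,
           grid: tuple[float, float, float] = (-5.0, 5.0, 0.01)
           ) -> tuple[float, np.ndarray]:
    """Box-Cox transform with the profile-likelihood λ from a grid search.

    ``shift`` is added first to accommodate zero-inflated texture
    variables; all shifted values must be positive.
    """
    arr = np.asarray(x, dtype=float) + shift
    if np.any(arr <= 0):
        raise ValidationError("Box-Cox requires positive data (use a shift)")
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    ll = np.array([sps.boxcox_llf(l, arr) for l in lambdas])
    lam = float(lambdas[int(np.argmax(ll))])
    if abs(lam) < 1e-12:
        transformed = np.log(arr)
    else:
        transformed = (arr ** lam - 1.0) / lam
    return lam, transformed


# --------------------------------------------------------------------------
# Factorial ANOVA / MANOVA (sequential sums of squares)
# --------------------------------------------------------------------------

def _design(data: pd.DataFrame, factors: Sequence[str],
            interactions: bool) -> str:
    terms = list(factors)
    if interactions and len(factors) > 1:
        terms += [f"{a}:{b}" for i, a in enumerate(factors) for b in factors[i + 1:]]
    return " + ".join(f"C({t.replace(':', '):C(')})" if ":" in t else f"C({t})"
                      for t in terms)


def anova_factorial(data: pd.DataFrame, response: str,
                    factors: Sequence[str],
                    interactions: bool = True) -> pd.DataFrame:
    """Sequential (type-I) factorial ANOVA; one row per model term.

    Factor order follows the ``factors`` argument, so the sequential
    decomposition is reproducible.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in factors:
        if data[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels")
    rhs = _design(data, factors, interactions)
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=1)
    return table.rename(columns={"PR(>F)": "p_value"})


def manova(data: pd.DataFrame, responses: Sequence[str],
           factors: Sequence[str],
           interactions: bool = False) -> pd.DataFrame:
    """Multivariate ANOVA: Wilks' lambda (with its F approximation) per term."""
    from statsmodels.multivariate.manova import MANOVA

    ycols = list(responses)
    if len(ycols) == 1:
        # 1-D reduction: Wilks' lambda collapses to the univariate F test
        table = anova_factorial(data, ycols[0], factors, interactions)
        ss_resid = float(table.loc["Residual", "sum_sq"])
        rows = []
        for term in table.index:
            if term == "Residual":
                continue
            ss = float(table.loc[term, "sum_sq"])
            rows.append({"term": term,
                         "wilks_lambda": ss_resid / (ss_resid + ss),
                         "F": float(table.loc[term, "F"]),
                         "df_num": float(table.loc[term, "df"]),
                         "df_den": float(table.loc["Residual", "df"]),
                         "p_value": float(table.loc[term, "p_value"])})
        return pd.DataFrame(rows).set_index("term")
    ymat = data[ycols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(ymat - ymat.mean(axis=0)) < len(ycols):
        raise ValidationError("response matrix is rank-deficient")
    n_cells = data.groupby(list(factors)).ngroups
    if len(data) - n_cells < len(ycols):
        raise ValidationError("fewer residual observations than responses")
    rhs = _design(data, factors, interactions)
    lhs = " + ".join(ycols)
    mv = MANOVA.from_formula(f"{lhs} ~ {rhs}", data=data)
    res = mv.mv_test()
    rows = []
    for term, payload in res.results.items():
        if term == "Intercept":
            continue
        stat = payload["stat"]
        wl = stat.loc["Wilks' lambda"]
        rows.append({"term": term, "wilks_lambda": float(wl["Value"]),
                     "F": float(wl["F Value"]),
                     "df_num": float(wl["Num DF"]), "df_den": float(wl["Den DF"]),
                     "p_value": float(wl["Pr > F"])})
    return pd.DataFrame(rows).set_index("term")


def lsd_posthoc(data: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """Fisher's LSD: pairwise t-tests sharing the pooled ANOVA residual MS.

    Unadjusted p-values (the LSD convention) plus a Holm column.
    """
    groups = {str(k): g[response].to_numpy(dtype=float)
              for k, g in data.groupby(factor, sort=True)}
    if len(groups) < 2:
        raise ValidationError("need >= 2 factor levels")
    ns = {k: len(v) for k, v in groups.items()}
    n_total = sum(ns.values())
    df_resid = n_total - len(groups)
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    mse = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values()) / df_resid
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = groups[a].mean() - groups[b].mean()
            se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                t, p = 0.0, 1.0
            else:
                t = diff / se
                p = float(2 * sps.t.sf(abs(t), df_resid))
            rows.append({"group_a": a, "group_b": b, "mean_diff": diff,
                         "t": t, "p_value": p})
    out = pd.DataFrame(rows)
    order = np.argsort(out["p_value"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p_value"].iloc[idx])
        adj[idx] = min(1.0, running)
    out["p_holm"] = adj
    return out
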