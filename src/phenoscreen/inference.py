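"""Statistics layer: AUC-distribution comparison, mixed-effects effect
sizes on per-culture predictions, prediction correlation, and clustering
of effect-size profiles.

* ``mann_whitney_one_sided`` compares two AUC distributions (exact
  permutation enumeration for combined n <= 12, tie-corrected normal
  approximation with continuity correction otherwise).
* ``fit_random_intercept_lmm`` fits, by maximum likelihood, a linear mixed
  model of per-culture classifier predictions on a binary condition with
  crossed random intercepts for cell line and experiment, and reports the
  condition effect size with a likelihood-ratio test against the
  random-effects-only model.  ML (not REML) is used throughout because the
  LRT compares models with different fixed effects.
* ``ward_cluster`` hierarchically clusters condition effect-size profiles
  with Euclidean distance and Ward linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = ["RankTestResult", "EffectEstimate", "WardClustering",
           "mann_whitney_one_sided", "fit_random_intercept_lmm",
           "likelihood_ratio_test", "pearson_correlation", "ward_cluster"]

EXACT_ENUMERATION_LIMIT = 12  # combined sample size for the exact MW path


@dataclass(frozen=True)
class RankTestResult:
    u: float                 # U statistic of the sample tested as larger
    p: float                 # one-sided p-value
    direction: str           # "a_greater" or "b_greater"
    n_a: int
    n_b: int
    exact: bool


def mann_whitney_one_sided(auc_a: Sequence[float], auc_b: Sequence[float],
                           alternative: str = "b_greater") -> RankTestResult:
    """One-sided Mann-Whitney test between two score samples.

    ``alternative='b_greater'`` tests whether sample b tends to exceed
    sample a.  For combined n <= 12 the p-value is computed by exhaustive
    enumeration of rank assignments (conditional on the observed midranks,
    so ties are handled exactly); larger samples use the normal
    approximation with midrank tie correction and continuity correction.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError("alternative must be 'a_greater' or 'b_greater'")
    if alternative == "a_greater":
        res = mann_whitney_one_sided(b, a, "b_greater")
        return RankTestResult(res.u, res.p, "a_greater", a.size, b.size, res.exact)

    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[n_a:].sum() - n_b * (n_b + 1) / 2  # U for sample b

    if n <= EXACT_ENUMERATION_LIMIT:
        total = 0
        at_least = 0
        base = n_b * (n_b + 1) / 2
        for subset in _combinations(range(n), n_b):
            u = sum(ranks[i] for i in subset) - base
            total += 1
            if u >= u_obs - 1e-12:
                at_least += 1
        p = at_least / total
        return RankTestResult(float(u_obs), float(p), "b_greater", n_a, n_b, True)

    mean = n_a * n_b / 2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return RankTestResult(float(u_obs), 1.0, "b_greater", n_a, n_b, False)
    z = (u_obs - mean - 0.5) / np.sqrt(var)
    p = float(stats.norm.sf(z))
    return RankTestResult(float(u_obs), min(max(p, np.finfo(float).tiny), 1.0),
                          "b_greater", n_a, n_b, False)


@dataclass(frozen=True)
class EffectEstimate:
    """Condition fixed-effect on per-culture predictions, from the ML fit
    of the crossed random-intercept model, with the LRT against the
    random-effects-only reduced model."""

    beta_hat: float
    se: float
    chi2: float
    p: float
    var_line: float
    var_experiment: float
    var_resid: float
    loglik_full: float
    loglik_reduced: float
    n: int


def likelihood_ratio_test(full_loglik: float, reduced_loglik: float,
                          df: int = 1) -> tuple[float, float]:
    """chi2 = 2 (full - reduced), clipped at zero; p from chi2_df."""
    delta = 2.0 * (full_loglik - reduced_loglik)
    if delta < -1e-6:
        raise RuntimeError(
            f"full model log-likelihood ({full_loglik:.6f}) is below the reduced "
            f"model's ({reduced_loglik:.6f}): optimization failure")
    chi2 = max(delta, 0.0)
    return chi2, float(stats.chi2.sf(chi2, df))


def _fit_mixed(df: pd.DataFrame, formula: str, vc: dict[str, str],
               methods: Sequence[str] = ("lbfgs",)):
    """ML fit of a crossed random-intercept model; with several optimizers
    requested, the fit with the highest log-likelihood wins."""
    import statsmodels.formula.api as smf
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups="_grp",
                            vc_formula=vc, re_formula="0")
        for method in methods:
            try:
                res = model.fit(reml=False, method=method, maxiter=1000)
            except Exception:
                continue
            if best is None or res.llf > best.llf:
                best = res
    if best is None:
        raise RuntimeError(f"mixed-model fit failed for {formula!r}")
    return best


def fit_random_intercept_lmm(table: pd.DataFrame, response: str = "prediction",
                             fixed: str = "condition",
                             random: Sequence[str] = ("cell_line", "experiment"),
                             ) -> EffectEstimate:
    """Effect of a binary condition on per-culture predictions, accounting
    for cell-line and experiment random intercepts (both by default; pass a
    single name to use one alone).

    The fixed effect must have exactly 2 levels; it is coded 0/1 in sorted
    level order, so ``beta_hat`` is the mean shift of the second level in
    prediction-probability units.  If every random factor is degenerate
    (single level), the model collapses to ordinary least squares with a
    warning, and the LRT compares the two OLS fits.
    """
    df = table.copy()
    levels = np.sort(df[fixed].unique())
    if levels.size != 2:
        raise ValueError(f"fixed effect {fixed!r} must have exactly 2 levels, "
                         f"found {levels.tolist()}")
    df["_cond"] = (df[fixed] == levels[1]).astype(float)
    df["_grp"] = 1

    vc = {}
    for factor in random:
        if factor not in df.columns:
            raise ValueError(f"random factor {factor!r} not in table")
        if df[factor].nunique() > 1:
            vc[factor] = f"0 + C({factor})"

    if not vc:
        warnings.warn("all random factors are degenerate (single level); "
                      "falling back to a single-intercept linear model")
        import statsmodels.formula.api as smf
        full = smf.ols(f"{response} ~ _cond", data=df).fit()
        reduced = smf.ols(f"{response} ~ 1", data=df).fit()
        chi2, p = likelihood_ratio_test(full.llf, reduced.llf)
        return EffectEstimate(float(full.params["_cond"]), float(full.bse["_cond"]),
                              chi2, p, 0.0, 0.0, float(full.scale),
                              float(full.llf), float(reduced.llf), len(df))

    full = _fit_mixed(df, f"{response} ~ _cond", vc)
    reduced = _fit_mixed(df, f"{response} ~ 1", vc)
    if full.llf < reduced.llf - 1e-8:
        # an optimizer stuck in a poor spot breaks the nesting guarantee:
        # retry both fits with a wider optimizer roster before giving up
        roster = ("lbfgs", "bfgs", "powell", "nm")
        full = _fit_mixed(df, f"{response} ~ _cond", vc, methods=roster)
        reduced = _fit_mixed(df, f"{response} ~ 1", vc, methods=roster)
    chi2, p = likelihood_ratio_test(full.llf, reduced.llf)
    vcomp = dict(zip(vc.keys(), np.asarray(full.vcomp, dtype=float)))
    return EffectEstimate(
        beta_hat=float(full.fe_params["_cond"]), se=float(full.bse["_cond"]),
        chi2=chi2, p=p,
        var_line=float(vcomp.get("cell_line", 0.0)),
        var_experiment=float(vcomp.get("experiment", 0.0)),
        var_resid=float(full.scale),
        loglik_full=float(full.llf), loglik_reduced=float(reduced.llf),
        n=len(df))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class WardClustering:
    """Ward linkage over row profiles plus the dendrogram leaf order."""

    linkage: np.ndarray          # scipy linkage matrix, (n-1, 4)
    labels: list[str]
    leaf_order: list[str]

    def adjacent(self, a: str, b: str) -> bool:
        """True if labels a and b are neighbors in the dendrogram leaf
        order (share their first merge neighborhood)."""
        ia, ib = self.leaf_order.index(a), self.leaf_order.index(b)
        return abs(ia - ib) == 1


def ward_cluster(profiles: pd.DataFrame | np.ndarray,
                 labels: Sequence[str] | None = None) -> WardClustering:
    """Hierarchical Ward clustering of effect-size profiles (rows =
    conditions, columns = classifiers) under Euclidean distance."""
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in profiles.index]
        x = profiles.to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(x.shape[0])]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("profile matrix contains missing values")
    z = linkage(x, method="ward")
    order = [labels[i] for i in leaves_list(z)]
    return WardClustering(linkage=z, labels=list(labels), leaf_order=order)
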