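"""Plantation-year panel assembly and the statistical battery.

The dependent variable is plantation efficiency: the fraction of a
plantation's area classified as oil palm. Certification cohorts (certified
in 2018 vs 2023) are modelled separately with linear mixed models — fixed
effects for plantation type (small-grower baseline), the three environmental
indices, the annual palm-oil price and year dummies (2018 reference), plus a
random intercept per plantation. Estimation is by maximum likelihood so that
log-likelihood, AIC and BIC are comparable across nested models.
Cross-type coverage differences are assessed with a Kruskal–Wallis rank-sum
test and Dunn's post-hoc pairwise comparisons, both with tie correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

log = logging.getLogger(__name__)

FIXED_REGRESSORS = ("self_produced", "outsourced", "ndvi", "ndmi", "bsi", "price")


@dataclass
class PanelFit:
    """A fitted random-intercept model for one cohort."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    residual_var: float
    marginal_r2: float
    conditional_r2: float
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }

    def summary_table(self) -> str:
        """Human-readable coefficient table with significance stars."""
        lines = [f"{'term':<16}{'coef':>12}{'(SE)':>12}  sig"]
        for term, coef in self.coefficients.items():
            p = self.p_values[term]
            stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            lines.append(f"{term:<16}{coef:>12.4f}{self.std_errors[term]:>12.4f}  {stars}")
        lines.append(f"Observations      {self.n_obs}")
        lines.append(f"Marginal R2       {self.marginal_r2:.3f}")
        lines.append(f"Conditional R2    {self.conditional_r2:.3f}")
        lines.append(f"Log likelihood    {self.log_likelihood:.3f}")
        lines.append(f"Akaike Inf. Crit. {self.aic:.3f}")
        lines.append(f"Bayesian Inf. Crit. {self.bic:.3f}")
        return "\n".join(lines)


def build_panel(
    coverage: pd.DataFrame,
    indices: pd.DataFrame,
    plantations: pd.DataFrame,
    prices: dict[int, float],
) -> pd.DataFrame:
    """Join coverage, index means, plantation attributes and prices.

    One row per plantation-year; cohort assigned from the certification
    year; rows with missing coverage are dropped with a logged count.
    """
    if coverage.empty:
        return pd.DataFrame(
            columns=["plantation_id", "mill", "year", "coverage", "self_produced",
                     "outsourced", "type", "ndvi", "ndmi", "bsi", "price", "cohort"]
        )
    dup = coverage.duplicated(subset=["plantation_id", "year"])
    if dup.any():
        pairs = coverage.loc[dup, ["plantation_id", "year"]].values.tolist()
        raise ValueError(f"duplicate plantation-year rows: {pairs[:5]}")
    missing_years = sorted(set(coverage["year"]) - set(prices))
    if missing_years:
        raise ValueError(f"no price for years {missing_years}")

    panel = coverage.merge(indices, on=["plantation_id", "year"], how="left")
    panel = panel.merge(
        plantations[["plantation_id", "mill", "type", "certification_year"]],
        on="plantation_id",
        how="left",
    )
    n_before = len(panel)
    panel = panel.dropna(subset=["coverage"])
    dropped = n_before - len(panel)
    if dropped:
        log.info("build_panel: dropped %d rows with missing coverage", dropped)
    panel["self_produced"] = (panel["type"] == "own_estate").astype(int)
    panel["outsourced"] = (panel["type"] == "outside_supplier_estate").astype(int)
    panel["price"] = panel["year"].map(prices)
    panel["cohort"] = "certified-" + panel["certification_year"].astype(int).astype(str)
    cols = ["plantation_id", "mill", "year", "coverage", "self_produced", "outsourced",
            "type", "ndvi", "ndmi", "bsi", "price", "cohort"]
    return panel[cols].reset_index(drop=True)


def _design_matrix(
    panel: pd.DataFrame, include_year_dummies: bool, reference_year: int
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix with intercept, fixed regressors and year dummies.

    The annual price is constant within a year, so a full set of year
    dummies plus price is exactly aliased; trailing year dummies are dropped
    until the design has full rank (with a 7-year panel this removes the
    final year, leaving dummies for the years before it).
    """
    names = ["intercept"]
    cols = [np.ones(len(panel))]
    dropped: list[str] = []
    for r in FIXED_REGRESSORS:
        col = panel[r].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            # constant in this cohort (e.g. no own estates): unestimable
            dropped.append(r)
            continue
        names.append(r)
        cols.append(col)
    if dropped:
        log.info("dropped constant regressors: %s", dropped)
    n_base = len(cols)
    if include_year_dummies:
        dummy_years = [y for y in sorted(panel["year"].unique()) if y != reference_year]
        for year in dummy_years:
            names.append(f"year_{year}")
            cols.append((panel["year"] == year).to_numpy(dtype=float))
        X = np.column_stack(cols)
        while len(cols) > n_base and np.linalg.matrix_rank(X) < X.shape[1]:
            dropped.append(names.pop())
            cols.pop()
            X = np.column_stack(cols)
        if dropped:
            log.info("dropped aliased year dummies: %s", dropped)
    return np.column_stack(cols), names, dropped


def fit_random_effects(
    panel: pd.DataFrame,
    include_year_dummies: bool = True,
    reference_year: int = 2018,
) -> PanelFit:
    """ML fit of coverage on fixed regressors with a plantation random intercept.

    p-values are two-tailed Wald z on coefficient/SE. Marginal and
    conditional R2 follow the variance-partition formulation: fixed-effect
    variance over total, and fixed-plus-random over total. AIC/BIC are
    recomputed from the ML log-likelihood with k = #fixed + 2 variance
    parameters.
    """
    groups = panel["plantation_id"]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 plantations (groups)")
    if panel["year"].nunique() < 2:
        raise ValueError("need at least 2 years")
    X, names, dropped = _design_matrix(panel, include_year_dummies, reference_year)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear regressors)")
    y = panel["coverage"].to_numpy(dtype=float)

    import warnings

    model = MixedLM(y, X, groups=groups.to_numpy())
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method=["lbfgs", "bfgs"], maxiter=500)
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        sigma_re = float(np.asarray(res.cov_re)[0, 0])
        sigma_res = float(res.scale)
        llf = float(res.llf)
        converged = bool(res.converged)
    except np.linalg.LinAlgError:
        # ML solution sits on the zero group-variance boundary, where the
        # variance Hessian is singular; the model degenerates to pooled OLS.
        import statsmodels.api as sm

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = sm.OLS(y, X).fit()
            beta = np.asarray(ols.params)
            se = np.asarray(ols.bse)
        sigma_re = 0.0
        sigma_res = float(ols.ssr / len(y))
        llf = float(ols.llf)
        converged = True

    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    var_fixed = float(np.var(X @ beta))
    total = var_fixed + sigma_re + sigma_res
    marginal_r2 = var_fixed / total
    conditional_r2 = (var_fixed + sigma_re) / total

    k = X.shape[1] + 2  # fixed effects + random-intercept var + residual var
    n = len(panel)
    aic = 2 * k - 2 * llf
    bic = k * np.log(n) - 2 * llf

    return PanelFit(
        coefficients=dict(zip(names, beta.tolist())),
        std_errors=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, pval.tolist())),
        random_intercept_var=sigma_re,
        residual_var=sigma_res,
        marginal_r2=marginal_r2,
        conditional_r2=conditional_r2,
        log_likelihood=llf,
        aic=aic,
        bic=bic,
        n_obs=n,
        n_groups=int(groups.nunique()),
        converged=converged,
        extra={"dropped_aliased_terms": dropped},
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal–Wallis H with tie correction; returns (H, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: tie correction is degenerate")
    h, p = stats.kruskal(*arrays)
    return float(h), len(arrays) - 1, float(p)


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc z tests from pooled ranks with tie correction.

    z(i, j) is positive when group i has the larger mean rank. p-values are
    two-tailed normal, unadjusted by default; ``adjust='holm'`` applies a
    Holm step-down correction across the pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group_{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p"], method="holm")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
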