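"""Mixed-model statistical layer.

Observations arrive as a long table (subject, genotype, state, trial,
measure, value).  Multivariate outliers are flagged per genotype x state
x trial cell by Hotelling's T^2 on principal-component scores; each
measure is then fit with a restricted-maximum-likelihood linear mixed
model with a per-subject random intercept and treatment-coded fixed
effects (reference: WT, exploration, trial 1).  For the two-factor
genotype x trial analyses, a non-significant interaction is dropped and
the model refit on main effects only.  Post hoc Welch t contrasts are
corrected with Benjamini-Hochberg FDR within a measure family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.formula.api import mixedlm
from statsmodels.stats.multitest import multipletests

REFERENCE_LEVELS = {"genotype": "WT", "state": "exploration", "trial": 1}


@dataclass
class ModelResult:
    params: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    converged: bool
    formula: str
    reduced: bool = False          # interaction dropped and refit
    df_method: str = "wald-z (statsmodels MixedLM default)"
    posthoc: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def term_p(self, term: str) -> float:
        """p-value of a fixed-effect term by fuzzy name match."""
        for name in self.pvalues.index:
            if _canon(name) == _canon(term):
                return float(self.pvalues[name])
        raise KeyError(term)


def _canon(name: str) -> str:
    out = name
    for raw, ref in (
        ("C(genotype, Treatment('WT'))[T.TG]", "genotype"),
        ("C(state, Treatment('exploration'))[T.wake_immobility]", "state"),
        ("C(trial, Treatment(1))[T.2]", "trial"),
    ):
        out = out.replace(raw, ref)
    return out.replace(" ", "")


def t2_outliers(
    table: pd.DataFrame,
    value_cols: list[str] | None = None,
    group_cols: tuple[str, ...] = ("genotype", "state", "trial"),
    alpha: float = 0.05,
    var_explained: float = 0.95,
) -> pd.Series:
    """Inclusion mask (True = keep) from per-group PCA Hotelling T^2.

    Within each group, rows are projected onto the principal components
    explaining >= ``var_explained`` of the variance; each row's T^2 (sum
    of squared standardized scores) is compared with the F-distribution
    95% bound  k(n-1)/(n-k) * F_{k, n-k, 1-alpha}.  Groups too small for
    a covariance estimate, or with singular covariance, fall back to a
    univariate z rule (|z| > the two-sided normal quantile) with a
    warning.  The mask is returned, never applied.
    """
    if value_cols is None:
        value_cols = [
            c for c in table.columns
            if c not in group_cols and c not in ("subject", "measure")
            and np.issubdtype(table[c].dtype, np.number)
        ]
    keep = pd.Series(True, index=table.index)
    zcrit = spstats.norm.ppf(1 - alpha / 2)
    for _, g in table.groupby(list(group_cols), observed=True):
        X = g[value_cols].to_numpy(float)
        n, p = X.shape
        if n < 3:
            continue
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0, ddof=1)
        if np.all(sd == 0):
            continue
        try:
            u, s, vt = np.linalg.svd(Xc, full_matrices=False)
            lam = s ** 2 / (n - 1)
            if lam[0] <= 0:
                raise np.linalg.LinAlgError
            frac = np.cumsum(lam) / lam.sum()
            k = int(np.searchsorted(frac, var_explained) + 1)
            k = min(k, n - 2) if n - 2 >= 1 else 1
            scores = Xc @ vt[:k].T
            t2 = np.sum(scores ** 2 / lam[:k], axis=1)
            bound = (
                k * (n - 1) / (n - k) * spstats.f.ppf(1 - alpha, k, n - k)
            )
            keep.loc[g.index] &= t2 <= bound
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular covariance; falling back to univariate z rule",
                stacklevel=2,
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, np.abs(Xc) / sd, 0.0)
            keep.loc[g.index] &= (z <= zcrit).all(axis=1)
    return keep


def _build_formula(fixed: tuple[str, ...], interactions: bool) -> str:
    coded = []
    for f in fixed:
        ref = REFERENCE_LEVELS.get(f)
        ref_repr = repr(ref) if isinstance(ref, str) else ref
        coded.append(f"C({f}, Treatment({ref_repr}))")
    joiner = " * " if interactions else " + "
    return "value ~ " + joiner.join(coded)


def fit_lmm(
    table: pd.DataFrame,
    fixed: tuple[str, ...] = ("genotype", "state", "trial"),
    interactions: bool = True,
    reml: bool = True,
) -> ModelResult:
    """Random-intercept linear mixed model for one measure.

    ``table`` needs columns ``subject``, ``value`` and the fixed factors.
    Non-convergence is flagged on the result, never raised.
    """
    for col in ("subject", "value", *fixed):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["value"].std() == 0:
        # constant response: all effects are exactly zero
        params = pd.Series({"Intercept": float(table["value"].iloc[0])})
        return ModelResult(
            params=params, pvalues=pd.Series(dtype=float),
            random_intercept_var=0.0, converged=True,
            formula="value ~ 1 (constant response)",
        )
    formula = _build_formula(fixed, interactions)
    last_err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the random-intercept variance often sits on the zero boundary in
        # small balanced designs, where lbfgs can fail; fall back in order
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                model = mixedlm(formula, table, groups=table["subject"])
                fit = model.fit(reml=reml, method=method)
            except Exception as exc:
                last_err = exc
                continue
            converged = bool(getattr(fit, "converged", True))
            fe = fit.fe_params
            pv = fit.pvalues[fe.index]
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
            return ModelResult(
                params=fe, pvalues=pv, random_intercept_var=re_var,
                converged=converged, formula=formula,
                diagnostics={"llf": float(fit.llf), "optimizer": method},
            )
    # every optimizer failed: flagged result, never a crash
    return ModelResult(
        params=pd.Series(dtype=float),
        pvalues=pd.Series(dtype=float),
        random_intercept_var=np.nan, converged=False,
        formula=formula, diagnostics={"error": str(last_err)},
    )


def refit_without_interaction(
    result: ModelResult,
    table: pd.DataFrame,
    fixed: tuple[str, ...] = ("genotype", "trial"),
    alpha: float = 0.05,
) -> ModelResult:
    """Drop a non-significant two-factor interaction and refit.

    If the genotype x trial interaction of ``result`` has p >= alpha the
    model is refit with main effects only and the reduced result is
    returned (flagged); otherwise the full model is returned unchanged.
    """
    inter_name = ":".join(fixed)
    try:
        p_int = result.term_p(inter_name)
    except KeyError:
        return result
    if np.isnan(p_int) or p_int < alpha:
        return result
    reduced = fit_lmm(table, fixed=fixed, interactions=False)
    reduced.reduced = True
    return reduced


def bh_fdr(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection mask)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def posthoc_contrasts(
    table: pd.DataFrame,
    between: str = "genotype",
    within: tuple[str, ...] = ("state", "trial"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t contrasts of ``between`` within each cell, BH-corrected.

    One contrast per combination of the ``within`` factor levels; the BH
    family is this set of contrasts (one measure family).
    """
    rows = []
    groups = table.groupby(list(within), observed=True) if within \
        else [((), table)]
    for key, g in groups:
        levels = sorted(g[between].astype(str).unique())
        if len(levels) != 2:
            continue
        a = g.loc[g[between].astype(str) == levels[0], "value"]
        b = g.loc[g[between].astype(str) == levels[1], "value"]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = spstats.ttest_ind(a, b, equal_var=False)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **{w: k for w, k in zip(within, key)},
                "contrast": f"{levels[0]} vs {levels[1]}",
                "t": float(t), "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"], out["reject"] = bh_fdr(out["p"].to_numpy(), alpha)
    return out


def analyze_measure(
    table: pd.DataFrame,
    design: str = "three_factor",
    alpha: float = 0.05,
) -> ModelResult:
    """Full statistical path for one measure.

    ``three_factor``: genotype x state x trial LMM + post hocs (band
    power, SWR features).  ``two_factor``: genotype x trial LMM with the
    interaction-dropping rule (PAC, occurrence ratio, whole-trial
    behavior).
    """
    if design == "three_factor":
        res = fit_lmm(table, fixed=("genotype", "state", "trial"))
        within: tuple[str, ...] = ("state", "trial")
    elif design == "two_factor":
        res = fit_lmm(table, fixed=("genotype", "trial"))
        res = refit_without_interaction(res, table, alpha=alpha)
        within = ("trial",)
    else:
        raise ValueError(f"unknown design {design!r}")
    any_sig = bool(
        len(res.pvalues)
        and np.nanmin(res.pvalues.drop("Intercept", errors="ignore")) < alpha
    )
    if any_sig:
        res.posthoc = posthoc_contrasts(table, within=within, alpha=alpha)
    return res
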