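"""Group comparisons: mixed-model contrasts of annual change rates,
covariate-adjusted linear models, and Bonferroni correction.

The central comparison is a linear mixed model on the per-putamen
annual change rates with baseline SBR, disease duration at baseline,
group, and the group × baseline interaction as fixed effects and a
per-subject random intercept (each subject contributes two putamina).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


class LmmConvergenceError(RuntimeError):
    pass


def apply_bonferroni(p_values, family_size: int | None = None):
    """Bonferroni-corrected p-values: min(1, p · m).

    ``family_size`` defaults to the number of p-values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, float))
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out[0]) if np.isscalar(p_values) else out


@dataclass
class GroupComparisonResult:
    """Estimates, SEs and (corrected) p-values for group terms of the LMM."""

    reference_group: str
    terms: pd.DataFrame  # index: term; columns: estimate, se, p, p_corrected
    family_size: int
    n_subjects: int
    n_putamina: int
    converged: bool
    random_intercept_sd: float
    residual_sd: float = float("nan")
    params: pd.Series = field(repr=False, default=None)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def _rates_frame(rate_samples) -> pd.DataFrame:
    return pd.DataFrame({
        "annual_change": [s.annual_change for s in rate_samples],
        "baseline_sbr": [s.baseline_sbr for s in rate_samples],
        "baseline_duration": [
            s.baseline_duration if s.baseline_duration is not None else np.nan
            for s in rate_samples
        ],
        "group": [s.group for s in rate_samples],
        "subject": [s.subject_id for s in rate_samples],
    })


def compare_annual_rates_lmm(rate_samples, reference_group: str | None = None,
                             family_size: int | None = None,
                             include_duration: bool = True
                             ) -> GroupComparisonResult:
    """LMM: annual change ~ baseline + duration + group + group:baseline, (1|subject).

    Wald z tests on the group main effects and group × baseline
    interactions, Bonferroni-corrected over the declared family (default:
    the number of reported group terms).
    """
    df = _rates_frame(rate_samples)
    groups = sorted(df["group"].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    if reference_group is None:
        reference_group = groups[0]
    df["group"] = pd.Categorical(
        df["group"], categories=[reference_group]
        + [g for g in groups if g != reference_group])
    dur_term = " + baseline_duration" if (
        include_duration and df["baseline_duration"].notna().all()) else ""
    formula = (f"annual_change ~ baseline_sbr{dur_term} + group "
               "+ baseline_sbr:group")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, df, groups=df["subject"]).fit(
                reml=False, method=["lbfgs", "powell"], maxiter=500)
        except np.linalg.LinAlgError:
            # random-intercept variance on the zero boundary: the mixed model
            # degenerates to OLS, which is then the exact GLS fit
            pass
        except Exception as e:  # noqa: BLE001
            raise LmmConvergenceError(f"LMM fit failed: {e}") from e
    if res is None:
        ols = smf.ols(formula, df).fit()
        params, bse, pvalues = ols.params, ols.bse, ols.pvalues
        converged, re_var, scale = True, 0.0, float(ols.scale)
    else:
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        if not res.converged and re_var > 1e-10:
            raise LmmConvergenceError(
                f"LMM did not converge (cov_re={re_var:.3g}, scale={res.scale:.3g})")
        params, bse, pvalues = res.fe_params, res.bse_fe, res.pvalues
        converged = bool(res.converged)
        scale = float(res.scale)

    group_terms = [t for t in params.index
                   if t.startswith("group[") or ":group[" in t
                   or t.startswith("baseline_sbr:group[")]
    m = family_size if family_size is not None else len(group_terms)
    rows = {}
    for t in group_terms:
        p = float(pvalues[t])
        rows[t] = {
            "estimate": float(params[t]),
            "se": float(bse[t]),
            "p": p,
            "p_corrected": apply_bonferroni(p, m),
        }
    return GroupComparisonResult(
        reference_group=reference_group,
        terms=pd.DataFrame(rows).T,
        family_size=m,
        n_subjects=df["subject"].nunique(),
        n_putamina=len(df),
        converged=converged,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(scale)),
        params=params,
    )


def compare_continuous_glm(values, group, covariates: pd.DataFrame | None = None,
                           reference_group: str | None = None) -> pd.DataFrame:
    """Covariate-adjusted linear-model group contrasts.

    Fits value ~ group + covariates (e.g. age and sex; plus disease
    duration for PD-subgroup contrasts) and returns the group contrast
    estimates with SEs and p-values relative to the reference level.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": list(group)})
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy()
    levels = sorted(df["group"].unique())
    if reference_group is None:
        reference_group = levels[0]
    df["group"] = pd.Categorical(
        df["group"], categories=[reference_group]
        + [g for g in levels if g != reference_group])
    cov_terms = "".join(
        f" + {c}" if np.issubdtype(df[c].dtype, np.number) else f" + C({c})"
        for c in (covariates.columns if covariates is not None else [])
    )
    res = smf.ols(f"value ~ group{cov_terms}", df).fit()
    rows = {}
    for t in res.params.index:
        if t.startswith("group["):
            rows[t] = {
                "estimate": float(res.params[t]),
                "se": float(res.bse[t]),
                "p": float(res.pvalues[t]),
            }
    return pd.DataFrame(rows).T
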