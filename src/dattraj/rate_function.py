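"""Stage 2: the annual-change-rate-vs-baseline-SBR function f(S).

The (baseline SBR, annual change) pairs — two per subject, one per
putamen — are fitted with a linear mixed model whose fixed effects are a
restricted (natural) cubic spline basis of baseline SBR and whose random
effect is a per-subject intercept, absorbing the within-subject
correlation of the two putamina.  A restricted cubic spline with the
same knots is then refitted through the mixed model's population
predictions; that refit is the stored, evaluable rate function f(S)
used as the right-hand side of dS/dt = f(S).

Knots sit at the 5/35/65/95 percentiles of the baseline SBRs, or at
10/50/90 when fewer than 100 putamina are available.

The spline basis is the standard truncated-power restricted cubic
spline: columns [S, d_1(S), …, d_{k−2}(S)] with

    d_j(S) = [ (S−t_j)_+³ − (S−t_{k−1})_+³ (t_k−t_j)/(t_k−t_{k−1})
               + (S−t_k)_+³ (t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t_1)²

which is linear outside the boundary knots and C² everywhere.  Only the
values of f are contractually meaningful; the coefficients depend on
this basis convention (recorded in the serialized form).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

BASIS_TAG = "rcs-truncated-power-v1"


class RateFitError(RuntimeError):
    """Mixed-model fit failed to converge; carries optimizer diagnostics."""


class KnotPlacementError(ValueError):
    pass


@dataclass(frozen=True)
class KnotSet:
    knots: tuple[float, ...]
    placement_rule: str  # "p5_35_65_95" or "p10_50_90"

    def __post_init__(self):
        k = np.asarray(self.knots, float)
        if k.size < 3:
            raise KnotPlacementError("need at least 3 knots")
        if np.any(np.diff(k) <= 0):
            raise KnotPlacementError(
                f"knots must be strictly increasing, got {tuple(k)}"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.knots, float)


def place_knots(baseline_sbrs, rule_auto: bool = True,
                rule: str | None = None) -> KnotSet:
    """Percentile knots with the sample-count-dependent rule.

    With ``rule_auto`` (default) the 5/35/65/95-percentile set is used
    when the putamen count is ≥ 100 and 10/50/90 otherwise; pass
    ``rule`` explicitly to override.  Duplicate percentile values
    (degenerate data) raise :class:`KnotPlacementError`.
    """
    x = np.asarray(baseline_sbrs, float)
    if x.size < 10:
        raise KnotPlacementError("need at least 10 samples to place knots")
    if rule is None:
        rule = "p5_35_65_95" if (rule_auto and x.size >= 100) else "p10_50_90"
        if not rule_auto:
            rule = "p5_35_65_95"
    pct = {"p5_35_65_95": [5, 35, 65, 95], "p10_50_90": [10, 50, 90]}[rule]
    knots = np.percentile(x, pct)  # linear interpolation (type 7)
    return KnotSet(knots=tuple(float(v) for v in knots), placement_rule=rule)


def rcs_basis(x, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline design columns [x, d_1(x) … d_{k−2}(x)].

    No intercept column; linear beyond the boundary knots by
    construction.
    """
    x = np.atleast_1d(np.asarray(x, float))
    t = np.asarray(knots, float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        d = (cube(x - t[j])
             - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
             + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])) / scale
        cols.append(d)
    return np.column_stack(cols)


def rcs_design(x, knots: np.ndarray) -> np.ndarray:
    """Basis with a leading intercept column."""
    b = rcs_basis(x, knots)
    return np.column_stack([np.ones(b.shape[0]), b])


@dataclass
class MixedSplineFit:
    """Population-level predictor from the mixed-effects spline fit."""

    knots: KnotSet
    coefficients: np.ndarray  # [intercept, x, d_1, ...]
    random_intercept_sd: float
    residual_sd: float
    converged: bool
    used_fallback_ols: bool
    n_samples: int
    n_subjects: int

    def predict(self, s) -> np.ndarray:
        return rcs_design(s, self.knots.array) @ self.coefficients


def fit_mixed_spline(rate_samples, knots: KnotSet, reml: bool = False
                     ) -> MixedSplineFit:
    """Mixed model: annual change ~ RCS(baseline SBR) + (1 | subject).

    Maximum likelihood by default.  A singular (≈ zero) random-intercept
    variance falls back to an ordinary least-squares fit of the same
    fixed effects with a warning — the population curve is unchanged in
    that limit.  Genuine optimizer failure raises :class:`RateFitError`.
    """
    df = pd.DataFrame({
        "y": [s.annual_change for s in rate_samples],
        "x": [s.baseline_sbr for s in rate_samples],
        "subject": [s.subject_id for s in rate_samples],
    })
    X = rcs_design(df["x"].to_numpy(), knots.array)
    if len(df) <= X.shape[1]:
        raise RateFitError("fewer samples than fixed-effect parameters")
    model = sm.MixedLM(df["y"].to_numpy(), X, groups=df["subject"].to_numpy())
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)
        except np.linalg.LinAlgError:
            # Hessian is singular when the random-intercept variance sits on
            # the zero boundary; treat as the singular-variance case below.
            pass
        except Exception as e:  # noqa: BLE001 - optimizer failure surfaces here
            raise RateFitError(f"mixed-model optimization failed: {e}") from e
    if res is None:
        re_var = 0.0
        singular = True
    else:
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        singular = re_var < 1e-10
    if not singular and not res.converged:
        raise RateFitError(
            f"mixed-model did not converge (cov_re={re_var:.3g}, "
            f"scale={res.scale:.3g})"
        )
    if singular:
        warnings.warn(
            "random-intercept variance is singular; falling back to a "
            "fixed-effects-only fit", RuntimeWarning, stacklevel=2,
        )
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        coefs = np.asarray(ols.params, float)
        resid_sd = float(np.sqrt(ols.scale))
        return MixedSplineFit(
            knots=knots, coefficients=coefs, random_intercept_sd=0.0,
            residual_sd=resid_sd, converged=True, used_fallback_ols=True,
            n_samples=len(df), n_subjects=df["subject"].nunique(),
        )
    return MixedSplineFit(
        knots=knots,
        coefficients=np.asarray(res.fe_params, float),
        random_intercept_sd=float(np.sqrt(re_var)),
        residual_sd=float(np.sqrt(res.scale)),
        converged=bool(res.converged),
        used_fallback_ols=False,
        n_samples=len(df),
        n_subjects=df["subject"].nunique(),
    )


@dataclass
class RateFunction:
    """The fitted rate function f(S): the ODE right-hand side.

    Evaluable at any SBR ≥ 0; cubic between the boundary knots, linear
    outside them (restricted-spline tails).
    """

    knots: KnotSet
    coefficients: np.ndarray  # [intercept, x, d_1, ...]
    domain: tuple[float, float]  # range of training baseline SBRs
    basis: str = BASIS_TAG
    rmse: float = float("nan")

    def __call__(self, s):
        out = rcs_design(s, self.knots.array) @ self.coefficients
        return float(out[0]) if np.isscalar(s) else out

    def to_json(self) -> str:
        return json.dumps({
            "basis": self.basis,
            "placement_rule": self.knots.placement_rule,
            "knots": list(self.knots.knots),
            "coefficients": list(map(float, self.coefficients)),
            "domain": list(self.domain),
            "rmse": self.rmse,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RateFunction":
        d = json.loads(text)
        if d["basis"] != BASIS_TAG:
            raise ValueError(f"unknown basis convention {d['basis']!r}")
        return cls(
            knots=KnotSet(tuple(d["knots"]), d["placement_rule"]),
            coefficients=np.asarray(d["coefficients"], float),
            domain=tuple(d["domain"]),
            rmse=d.get("rmse", float("nan")),
        )


def fit_rcs(baselines, predicted_rates, knots: KnotSet) -> RateFunction:
    """Least-squares restricted cubic spline through (baseline, rate) pairs.

    This is the refit of the mixed model's population predictions that
    becomes the stored f(S); refitting an RCS-representable input
    reproduces it exactly (projection idempotence).
    """
    x = np.asarray(baselines, float)
    y = np.asarray(predicted_rates, float)
    X = rcs_design(x, knots.array)
    if x.size < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} points for {X.shape[1]} basis functions"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return RateFunction(
        knots=knots,
        coefficients=coef,
        domain=(float(x.min()), float(x.max())),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
    )


def evaluate_rate(f: RateFunction, s):
    """Pure evaluation of the fitted rate function at SBR level ``s``."""
    if np.any(np.asarray(s, float) < 0):
        raise ValueError("SBR level must be >= 0")
    return f(s)


def fit_rate_function(rate_samples, knots: KnotSet | None = None,
                      reml: bool = False, collapse_two_step: bool = False
                      ) -> tuple[RateFunction, MixedSplineFit]:
    """Knots → mixed spline → RCS refit, returning both stages.

    ``collapse_two_step`` skips the refit and wraps the mixed model's
    fixed effects directly (the two are identical up to rounding when
    the refit uses the training baselines).
    """
    baselines = np.array([s.baseline_sbr for s in rate_samples], float)
    if knots is None:
        knots = place_knots(baselines)
    mixed = fit_mixed_spline(rate_samples, knots, reml=reml)
    if collapse_two_step:
        f = RateFunction(
            knots=knots, coefficients=mixed.coefficients,
            domain=(float(baselines.min()), float(baselines.max())),
        )
        return f, mixed
    predicted = mixed.predict(baselines)
    f = fit_rcs(baselines, predicted, knots)
    return f, mixed
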