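"""Strategy-choice analysis: per-geometry OVER advantages, logistic choice
model, and the two-feature control-target consistency test.

For each obstacle geometry the *advantage* x of selecting the OVER strategy
is the absolute difference between the per-strategy means of a candidate
control-target variable, signed positive when OVER is favoured: lower cost
of transport (task or worst step, total or CoM), higher traversal speed, or
traversal speed closer to the approach speed.  The log odds of choosing OVER
are modelled as b0 + b1 * x by maximum likelihood (per-trial Bernoulli,
equivalently count-weighted binomial), with Wald standard errors, two-sided
normal tests and 95% CIs.

A candidate control target is *consistent* with the observed behaviour when
the fitted model has (i) a significantly positive slope b1 and (ii) an
intercept b0 whose 95% CI includes zero (no bias at zero advantage).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "CANDIDATES",
    "AdvantageRecord",
    "LogisticFit",
    "ControlTargetVerdict",
    "compute_advantage",
    "fit_logistic",
    "evaluate_control_target",
    "point_of_subjective_equality",
]

#: Candidate control targets. "cost-like" candidates favour OVER when OVER's
#: mean is lower; speed maximization favours OVER when OVER's mean is higher.
CANDIDATES = (
    "task_cot_tot",
    "step_cot_tot",
    "task_cot_com",
    "step_cot_com",
    "speed_max",
    "speed_conservation",
)
_HIGHER_IS_BETTER = {"speed_max"}


@dataclass
class AdvantageRecord:
    """Signed OVER advantage for one obstacle geometry and candidate."""

    candidate: str
    x: float
    obstacle: tuple[float, float] | None = None  # (depth_rel, length_rel)
    n_trials: int = 0
    n_over: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.x):
            raise ValueError("advantage must be finite")
        if not (0 <= self.n_over <= self.n_trials):
            raise ValueError("need 0 <= n_over <= n_trials")


def compute_advantage(
    candidate: str,
    mean_over: float,
    mean_in: float,
    obstacle: tuple[float, float] | None = None,
    n_trials: int = 0,
    n_over: int = 0,
) -> AdvantageRecord:
    """Signed advantage of selecting OVER from per-strategy candidate means.

    |x| is the absolute difference of the two means; the sign is positive
    when OVER has the lower cost (cost candidates), the higher speed
    (speed_max) or the smaller |approach - traversal| speed deviation
    (speed_conservation, whose candidate variable is that deviation).
    """
    if candidate not in CANDIDATES:
        raise ValueError(f"unknown candidate {candidate!r}; choose from {CANDIDATES}")
    if candidate in _HIGHER_IS_BETTER:
        x = mean_over - mean_in
    else:
        x = mean_in - mean_over
    return AdvantageRecord(candidate, float(x), obstacle, n_trials, n_over)


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of log-odds(OVER) = b0 + b1 * x."""

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    t_b0: float
    t_b1: float
    p_b0: float
    p_b1: float
    ci95_b0: tuple[float, float]
    ci95_b1: tuple[float, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    diagnostic: str = ""

    def predict(self, x):
        """Fitted selection probability p(x)."""
        return expit(self.b0 + self.b1 * np.asarray(x, dtype=float))

    @property
    def pse(self) -> float:
        return point_of_subjective_equality(self)


def _as_binomial_table(records) -> pd.DataFrame:
    """Normalise input (AdvantageRecords or a DataFrame of Bernoulli rows)
    into x / successes / failures columns."""
    if isinstance(records, pd.DataFrame):
        df = records
        if {"x", "chose_over"} <= set(df.columns):
            grp = df.groupby("x")["chose_over"].agg(["sum", "count"]).reset_index()
            return pd.DataFrame(
                {
                    "x": grp["x"],
                    "successes": grp["sum"].astype(float),
                    "failures": (grp["count"] - grp["sum"]).astype(float),
                }
            )
        raise ValueError("DataFrame input needs columns 'x' and 'chose_over'")
    rows = [
        (r.x, float(r.n_over), float(r.n_trials - r.n_over))
        for r in records
        if not r.flagged
    ]
    return pd.DataFrame(rows, columns=["x", "successes", "failures"])


def fit_logistic(records, tol: float = 1e-8) -> LogisticFit:
    """Fit the logistic choice model by maximum likelihood (IRLS).

    ``records`` is either a list of :class:`AdvantageRecord` (with choice
    counts) or a DataFrame with per-trial columns ``x`` and ``chose_over``.
    Perfect separation is reported through ``converged=False`` with a
    diagnostic, never as a silent result.
    """
    table = _as_binomial_table(records)
    if table.empty:
        raise ValueError("no usable records")
    if table["x"].nunique() < 2:
        raise ValueError("need at least 2 distinct advantage values")
    n_succ, n_fail = table["successes"].sum(), table["failures"].sum()
    if n_succ == 0 or n_fail == 0:
        raise ValueError("need at least one OVER and one IN choice overall")

    exog = sm.add_constant(table["x"].to_numpy())
    endog = table[["successes", "failures"]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        res = model.fit(tol=tol, maxiter=200)

    b0, b1 = (float(v) for v in res.params)
    se = np.asarray(res.bse, dtype=float)
    converged = bool(getattr(res, "converged", True))
    diagnostic = ""
    # diverging coefficients / exploding SEs indicate (quasi-)separation
    if (
        not np.all(np.isfinite(se))
        or np.max(np.abs(res.params)) > 1e3
        or np.max(se) > 1e2
    ):
        converged = False
        diagnostic = (
            "coefficients diverging: data are (quasi-)perfectly separated; "
            "maximum-likelihood estimates do not exist"
        )
    z = np.array([b0, b1]) / se
    p = 2.0 * norm.sf(np.abs(z))
    ci = [(est - 1.96 * s, est + 1.96 * s) for est, s in zip((b0, b1), se)]
    return LogisticFit(
        b0=b0,
        b1=b1,
        se_b0=float(se[0]),
        se_b1=float(se[1]),
        t_b0=float(z[0]),
        t_b1=float(z[1]),
        p_b0=float(p[0]),
        p_b1=float(p[1]),
        ci95_b0=tuple(map(float, ci[0])),
        ci95_b1=tuple(map(float, ci[1])),
        log_likelihood=float(res.llf),
        converged=converged,
        n_obs=int(n_succ + n_fail),
        diagnostic=diagnostic,
    )


@dataclass(frozen=True)
class ControlTargetVerdict:
    candidate: str
    feature_b1: bool  # significant positive slope
    feature_b0: bool  # no significant intercept (95% CI spans zero)

    @property
    def consistent(self) -> bool:
        return self.feature_b1 and self.feature_b0


def evaluate_control_target(
    fit: LogisticFit, candidate: str = "", alpha: float = 0.05
) -> ControlTargetVerdict:
    """Two-feature consistency test for one candidate control target:
    (i) b1 > 0 and significant at ``alpha``; (ii) the b0 95% CI contains 0."""
    if not fit.converged:
        raise ValueError(f"fit did not converge ({fit.diagnostic}); verdict undefined")
    feature_b1 = fit.b1 > 0 and fit.p_b1 < alpha
    feature_b0 = fit.ci95_b0[0] <= 0.0 <= fit.ci95_b0[1]
    return ControlTargetVerdict(candidate, feature_b1, feature_b0)


def point_of_subjective_equality(fit: LogisticFit) -> float:
    """Advantage at which the fitted selection probability is 0.5: -b0/b1."""
    if fit.b1 == 0:
        raise ValueError("PSE undefined for zero slope")
    return -fit.b0 / fit.b1
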