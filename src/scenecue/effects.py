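"""Fixed-effects regression of behavior on scene scores.

This stage is a declared fixed-effects simplification of mixed-model
analyses: two-level factors are sum-coded (+1/-1, so the intercept is the
grand mean and slopes are half the difference between levels), continuous
predictors are z-transformed within the analysis set, and inference is by
asymptotic Wald tests. Participant heterogeneity can be absorbed by
sum-coded participant indicator columns when requested.

Families:

* "linear"   — ordinary least squares (ratings).
* "logistic" — binomial GLM with logit link (binary responses).
* "probit"   — binomial GLM with probit link; the correctly specified model
  for responses generated by thresholding Gaussian evidence, so planted
  evidence-scale coefficients are recovered on their own scale.
* logistic with ``guess_rate`` g > 0 — the psychometric-function likelihood
  P(y=1) = g + (1-g) * logistic(eta), for forced-choice accuracy with a
  known chance floor (0.2 in a 5-AFC task); fitted by Fisher scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, t as t_dist

from .scores import z_transform

__all__ = [
    "DesignMatrix",
    "EffectsModel",
    "EffectsResults",
    "SeparationError",
    "build_design",
]

Z_975 = norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE diverges."""


@dataclass
class DesignMatrix:
    """Trial-by-column design with documented coding.

    Columns: intercept, sum-coded factors (+1 for the first sorted level,
    -1 for the second), z-scored continuous predictors, then requested
    interaction products, then optional participant indicators.
    """

    frame: pd.DataFrame
    factor_codings: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(float)


def _sum_code(series: pd.Series, name: str) -> tuple[np.ndarray, dict]:
    levels = sorted(pd.unique(series))
    if len(levels) != 2:
        raise ValueError(f"factor {name!r} must have exactly 2 levels, got {levels}")
    coding = {levels[0]: 1.0, levels[1]: -1.0}
    return series.map(coding).to_numpy(float), coding


def build_design(
    trials: pd.DataFrame,
    factors: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
    interactions: tuple[tuple[str, ...], ...] = (),
    include_participant: bool = False,
    participant_col: str = "participant",
) -> DesignMatrix:
    """Build the sum-contrast design matrix for a trial table.

    `interactions` are tuples of factor/continuous names; each interaction
    column (named "a:b") is the elementwise product of the already-coded
    component columns. Column order is deterministic: intercept, factors in
    the order given, continuous in the order given, interactions in the
    order given, participant indicators last.
    """
    referenced = set(factors) | set(continuous) | {n for terms in interactions for n in terms}
    missing = sorted(referenced - set(trials.columns))
    if missing:
        raise ValueError(f"design references missing columns: {missing}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(trials))}
    codings: dict[str, dict] = {}
    for f in factors:
        cols[f], codings[f] = _sum_code(trials[f], f)
    for c in continuous:
        cols[c] = z_transform(trials[c].to_numpy(float))
    for terms in interactions:
        for name in terms:
            if name not in cols:
                raise ValueError(f"interaction component {name!r} is not a declared factor "
                                 "or continuous predictor")
        label = ":".join(terms)
        prod = np.ones(len(trials))
        for name in terms:
            prod = prod * cols[name]
        cols[label] = prod
    frame = pd.DataFrame(cols, index=trials.index)

    if include_participant:
        ids = sorted(pd.unique(trials[participant_col]))
        if len(ids) > 1:
            base = pd.get_dummies(trials[participant_col]).astype(float)[ids]
            # sum-to-zero coding: last participant is -1 on every indicator
            ind = base.iloc[:, :-1].copy()
            ind.loc[base.iloc[:, -1] == 1.0, :] = -1.0
            ind.columns = [f"participant_{p}" for p in ids[:-1]]
            frame = pd.concat([frame, ind], axis=1)
    return DesignMatrix(frame, codings)


@dataclass
class EffectsResults:
    """Per-coefficient estimates with Wald inference.

    statistic is z (logistic/probit) or t (linear); conf_int() is the Wald
    interval beta +/- 1.96 * SE in both families.
    """

    params: pd.Series
    bse: pd.Series
    statistic: pd.Series
    pvalues: pd.Series
    llf: float
    family: str
    df_resid: int
    cov_params: pd.DataFrame
    design: DesignMatrix
    degenerate: bool = False

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def linear_trend(self, continuous: str, by_factor: str) -> pd.DataFrame:
        """Per-level slopes of `continuous` at each level of `by_factor`:
        slope(level coded +1) = b_cont + b_int, slope(-1) = b_cont - b_int,
        with SEs from the coefficient covariance. Their average is b_cont
        exactly (sum-coding identity).
        """
        inter = f"{by_factor}:{continuous}"
        if inter not in self.params.index:
            inter = f"{continuous}:{by_factor}"
        if inter not in self.params.index or continuous not in self.params.index:
            raise ValueError(f"fit lacks the {continuous} x {by_factor} interaction")
        coding = self.design.factor_codings.get(by_factor)
        if coding is None:
            raise ValueError(f"{by_factor!r} is not a coded factor in this design")
        b_c, b_i = self.params[continuous], self.params[inter]
        v_cc = self.cov_params.loc[continuous, continuous]
        v_ii = self.cov_params.loc[inter, inter]
        v_ci = self.cov_params.loc[continuous, inter]
        rows = []
        for level, code in coding.items():
            slope = b_c + code * b_i
            se = float(np.sqrt(v_cc + v_ii + 2 * code * v_ci))
            rows.append((level, code, slope, se, slope - Z_975 * se, slope + Z_975 * se))
        return pd.DataFrame(rows, columns=["level", "code", "slope", "se", "ci_lower", "ci_upper"])

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        stat_name = "t" if self.family == "linear" else "z"
        return pd.DataFrame({
            "beta": self.params, "se": self.bse, stat_name: self.statistic,
            "p": self.pvalues, "ci_lower": ci["lower"], "ci_upper": ci["upper"]})

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"EffectsModel results (family={self.family}, "
                 f"df_resid={self.df_resid}, llf={self.llf:.2f})"]
        if self.degenerate:
            lines.append("WARNING: degenerate fit (zero residual variance); SEs unreliable")
        lines.append(df.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


class EffectsModel:
    """Fixed-effects regression model over a prepared DesignMatrix.

    Construct directly from arrays, or with :meth:`from_dataframe` which
    builds the sum-contrast design from a trial table.
    """

    def __init__(self, endog, design: DesignMatrix, family: str = "logistic",
                 guess_rate: float = 0.0):
        if family not in ("logistic", "probit", "linear"):
            raise ValueError(f"unknown family {family!r}")
        if guess_rate and family != "logistic":
            raise ValueError("guess_rate is only meaningful for the logistic family")
        if not 0.0 <= guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")
        self.endog = np.asarray(endog, dtype=float)
        self.design = design
        self.family = family
        self.guess_rate = float(guess_rate)
        X = design.matrix
        if self.endog.shape[0] != X.shape[0]:
            raise ValueError("endog and design have different lengths")
        if family in ("logistic", "probit"):
            vals = np.unique(self.endog)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary families need a 0/1 response")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more observations than design columns")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, response: str,
                       factors=(), continuous=(), interactions=(),
                       family: str = "logistic", guess_rate: float = 0.0,
                       include_participant: bool = False) -> "EffectsModel":
        design = build_design(trials, tuple(factors), tuple(continuous),
                              tuple(tuple(t) for t in interactions),
                              include_participant=include_participant)
        return cls(trials[response].to_numpy(float), design, family, guess_rate)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> EffectsResults:
        if self.family == "linear":
            return self._fit_linear()
        if self.guess_rate > 0:
            return self._fit_guess_logistic()
        return self._fit_glm()

    def _results(self, params, bse, statistic, pvalues, llf, cov, df_resid,
                 degenerate=False) -> EffectsResults:
        names = self.design.names
        return EffectsResults(
            params=pd.Series(params, index=names),
            bse=pd.Series(bse, index=names),
            statistic=pd.Series(statistic, index=names),
            pvalues=pd.Series(pvalues, index=names),
            llf=float(llf), family=self.family, df_resid=int(df_resid),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            design=self.design, degenerate=degenerate)

    def _fit_linear(self) -> EffectsResults:
        res = sm.OLS(self.endog, self.design.matrix).fit()
        degenerate = res.ssr < 1e-12 * max(1, len(self.endog))
        if degenerate:
            stat = np.full_like(res.params, np.nan)
            p = np.full_like(res.params, np.nan)
        else:
            stat = res.tvalues
            p = 2 * t_dist.sf(np.abs(stat), res.df_resid)
        return self._results(res.params, res.bse, stat, p, res.llf,
                             res.cov_params(), res.df_resid, degenerate)

    def _fit_glm(self) -> EffectsResults:
        link = sm.families.links.Logit() if self.family == "logistic" else sm.families.links.Probit()
        model = sm.GLM(self.endog, self.design.matrix, family=sm.families.Binomial(link=link))
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # statsmodels PerfectSeparationError and kin
            if "separation" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise
        if np.max(np.abs(res.params)) > 30:
            raise SeparationError("diverging coefficients suggest perfect separation")
        stat = res.params / res.bse
        p = 2 * norm.sf(np.abs(stat))
        return self._results(res.params, res.bse, stat, p, res.llf,
                             res.cov_params(), res.df_resid)

    def _fit_guess_logistic(self, max_iter: int = 100, tol: float = 1e-10) -> EffectsResults:
        """Fisher scoring for P(y=1) = g + (1-g) * sigmoid(X beta)."""
        X = self.design.matrix
        y = self.endog
        g = self.guess_rate
        beta = np.zeros(X.shape[1])

        def loglike(b):
            pi = _sigmoid(X @ b)
            p = np.clip(g + (1 - g) * pi, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        ll = loglike(beta)
        for _ in range(max_iter):
            eta = X @ beta
            pi = _sigmoid(eta)
            p = np.clip(g + (1 - g) * pi, 1e-12, 1 - 1e-12)
            dp = (1 - g) * pi * (1 - pi)              # dp/deta
            grad = X.T @ ((y - p) * dp / (p * (1 - p)))
            if np.max(np.abs(grad)) < 1e-8 * len(y):
                break  # boundary solution: likelihood flat (data at the floor)
            w = dp**2 / (p * (1 - p))                 # Fisher weights
            info = X.T @ (X * w[:, None])
            step = _solve_info(info, grad)
            cap = np.max(np.abs(step))
            if cap > 2.0:                             # trust region
                step *= 2.0 / cap
            # damped update; stop when no meaningful improvement is possible
            # (boundary solutions with a flat likelihood stay finite)
            scale = 1.0
            for _ in range(30):
                new_ll = loglike(beta + scale * step)
                if new_ll >= ll:
                    break
                scale /= 2
            if new_ll < ll:
                break
            improvement = new_ll - ll
            beta = beta + scale * step
            ll = new_ll
            if improvement < tol * (abs(ll) + 1.0):
                break
        if np.max(np.abs(beta)) > 30:
            raise SeparationError("diverging coefficients suggest perfect separation")
        eta = X @ beta
        pi = _sigmoid(eta)
        p = np.clip(g + (1 - g) * pi, 1e-12, 1 - 1e-12)
        dp = (1 - g) * pi * (1 - pi)
        w = dp**2 / (p * (1 - p))
        info = X.T @ (X * w[:, None])
        cov = _solve_info(info, np.eye(X.shape[1]))
        bse = np.sqrt(np.diag(cov))
        stat = beta / bse
        pvals = 2 * norm.sf(np.abs(stat))
        return self._results(beta, bse, stat, pvals, ll, cov,
                             len(y) - X.shape[1])


def _solve_info(info: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve against the Fisher information, ridge-regularizing when the
    likelihood is flat (data at the guessing floor make the slope
    information vanish; estimates stay near zero with very wide SEs)."""
    try:
        return np.linalg.solve(info, rhs)
    except np.linalg.LinAlgError:
        bump = 1e-8 * max(1.0, np.trace(info) / info.shape[0])
        return np.linalg.solve(info + bump * np.eye(info.shape[0]), rhs)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out
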