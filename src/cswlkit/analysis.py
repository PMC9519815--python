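"""Chance-offset mixed logistic analysis of 4AFC test responses.

The response of interest is binary target selection in a four-alternative
test, so chance is 0.25.  Chance enters the linear predictor as a fixed
offset logit(0.25) = log(1/3); with the lower-probability set (PP-) as
reference level, the intercept's odds ratio measures PP- performance above
chance, the PP+ coefficient the change from that reference, and the product
of the two odds ratios the PP+ odds above chance.

Derived quantities use the latent-scale logistic residual variance
sigma^2 = pi^2/3: the adjusted ICC is sum(tau^2) / (sum(tau^2) + pi^2/3) and
the marginal/conditional R^2 follow the variance-decomposition definitions
for GLMMs (fixed-effect variance over total, and fixed-plus-random over
total).

Two dataset variants mirror the published analyses: "full" keeps both test
repetitions of every pair (up to 24 trials/participant), "halved" only each
pair's first test (12), removing within-test learning opportunities.  Before
modeling, trials with reaction times more than 3 SDs from the mean are
excluded (global scope by default; per-participant optional).

p-values are not reported by default; Wald/credible intervals on odds ratios
carry the inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from .pseudowords import PP_MINUS, PP_PLUS
from . import bayes, glmm

CHANCE = 0.25
SIGMA2_LOGISTIC = math.pi**2 / 3.0


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# RT exclusion and dataset construction

def exclude_rt_outliers(
    records: pd.DataFrame,
    k: float = 3.0,
    scope: Literal["global", "per_participant"] = "global",
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose RT lies more than ``k`` SDs from the mean (one pass).

    With fewer than two rows in a scope the SD is undefined and nothing is
    excluded there.  Returns (filtered, n_excluded).
    """
    if (records["rt_ms"] <= 0).any():
        raise AnalysisError("rt_ms must be positive")
    if not np.isfinite(k):
        return records.copy(), 0

    def keep_mask(rt: pd.Series) -> pd.Series:
        if len(rt) < 2:
            return pd.Series(True, index=rt.index)
        sd = rt.std(ddof=1)
        if sd == 0:
            return pd.Series(True, index=rt.index)
        return (rt - rt.mean()).abs() <= k * sd

    if scope == "global":
        mask = keep_mask(records["rt_ms"])
    elif scope == "per_participant":
        mask = records.groupby("participant_id", group_keys=False)["rt_ms"].apply(keep_mask)
        mask = mask.reindex(records.index)
    else:
        raise AnalysisError(f"unknown scope {scope!r}")
    filtered = records[mask].copy()
    return filtered, int((~mask).sum())


@dataclass
class AnalysisDataset:
    variant: Literal["full", "halved"]
    rows: pd.DataFrame
    n_excluded: int
    chance_level: float = CHANCE

    @property
    def offset(self) -> float:
        return float(logit(self.chance_level))


def make_datasets(
    records: pd.DataFrame,
    k: float = 3.0,
    scope: Literal["global", "per_participant"] = "global",
) -> tuple[AnalysisDataset, AnalysisDataset]:
    """Build the full and halved analysis datasets, each with its own RT
    exclusion pass."""
    required = {"participant_id", "set_label", "repetition", "probe_word", "correct", "rt_ms"}
    missing = required - set(records.columns)
    if missing:
        raise AnalysisError(f"response table missing columns: {sorted(missing)}")
    full_rows, n_full = exclude_rt_outliers(records, k, scope)
    halved_src = records[records["repetition"] == 1]
    halved_rows, n_half = exclude_rt_outliers(halved_src, k, scope)
    return (
        AnalysisDataset(variant="full", rows=full_rows, n_excluded=n_full),
        AnalysisDataset(variant="halved", rows=halved_rows, n_excluded=n_half),
    )


# ---------------------------------------------------------------------------
# results container

@dataclass(frozen=True)
class FixedEffect:
    estimate: float  # log-odds
    odds_ratio: float
    ci_low: float  # on the odds-ratio scale
    ci_high: float
    interval_kind: Literal["confidence", "credible"]


@dataclass
class GlmmResult:
    fixed: dict[str, FixedEffect]
    random: dict[str, float]  # grouping -> variance tau00
    sigma2_residual: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_obs: int
    method: str
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fixed": {
                k: {
                    "estimate": fe.estimate,
                    "odds_ratio": fe.odds_ratio,
                    "ci_low": fe.ci_low,
                    "ci_high": fe.ci_high,
                    "interval_kind": fe.interval_kind,
                }
                for k, fe in self.fixed.items()
            },
            "random": self.random,
            "sigma2_residual": self.sigma2_residual,
            "icc": self.icc,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "messages": self.messages,
        }


def _design_matrix(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    labels = set(rows["set_label"])
    if not labels <= {PP_PLUS, PP_MINUS}:
        raise AnalysisError(f"unexpected set labels {labels}")
    x = (rows["set_label"] == PP_PLUS).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(rows)), x])
    y = rows["correct"].to_numpy(dtype=float)
    return y, X


def fit_glmm_frequentist(dataset: AnalysisDataset) -> GlmmResult:
    """Mixed logistic fit with random intercepts for participants and stimuli
    (the pruned, converging frequentist specification), chance as offset,
    PP- as reference.  Wald 95% intervals on the odds-ratio scale."""
    rows = dataset.rows
    if rows["participant_id"].nunique() < 2 or rows["probe_word"].nunique() < 2:
        raise AnalysisError("need >= 2 participants and >= 2 stimuli")
    y, X = _design_matrix(rows)
    fit = glmm.fit_laplace(
        y,
        X,
        groups={
            "participants": rows["participant_id"].to_numpy(),
            "stimuli": rows["probe_word"].to_numpy(),
        },
        offset=dataset.offset,
    )
    z = 1.959963984540054
    fixed = {}
    for name, i in (("intercept_PPminus", 0), ("PPplus", 1)):
        est, se = float(fit.beta[i]), float(fit.beta_se[i])
        fixed[name] = FixedEffect(
            estimate=est,
            odds_ratio=math.exp(est),
            ci_low=math.exp(est - z * se),
            ci_high=math.exp(est + z * se),
            interval_kind="confidence",
        )
    taus = dict(fit.tau2)
    var_f = float(np.var(X[:, 1] * fit.beta[1]))
    r2m, r2c = r2_nakagawa(var_f, list(taus.values()))
    return GlmmResult(
        fixed=fixed,
        random=taus,
        sigma2_residual=SIGMA2_LOGISTIC,
        icc=icc_logistic(list(taus.values())),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=fit.converged,
        n_obs=fit.n_obs,
        method="laplace",
        messages=list(fit.messages),
    )


def fit_glmm_bayesian(
    dataset: AnalysisDataset,
    *,
    n_warmup: int = 600,
    n_draws: int = 1000,
    n_chains: int = 4,
    seed: int = 0,
) -> GlmmResult:
    """Bayesian fit of the maximal specification (stimulus deviations within
    participant), posterior medians with 95% credible intervals."""
    rows = dataset.rows
    if rows["participant_id"].nunique() < 2 or rows["probe_word"].nunique() < 2:
        raise AnalysisError("need >= 2 participants and >= 2 stimuli")
    y, X = _design_matrix(rows)
    fit = bayes.fit_mcmc(
        y,
        X[:, 1],
        dataset.offset,
        rows["participant_id"].to_numpy(),
        rows["probe_word"].to_numpy(),
        n_warmup=n_warmup,
        n_draws=n_draws,
        n_chains=n_chains,
        seed=seed,
    )
    fixed = {}
    for name, key in (("intercept_PPminus", "beta0"), ("PPplus", "beta1")):
        est = fit.median[key]
        fixed[name] = FixedEffect(
            estimate=est,
            odds_ratio=math.exp(est),
            ci_low=math.exp(fit.ci_low[key]),
            ci_high=math.exp(fit.ci_high[key]),
            interval_kind="credible",
        )
    taus = {
        "participants": fit.median["tau_participant"] ** 2,
        "stimuli_within_participant": fit.median["tau_cell"] ** 2,
    }
    var_f = float(np.var(X[:, 1] * fixed["PPplus"].estimate))
    r2m, r2c = r2_nakagawa(var_f, list(taus.values()))
    messages = list(fit.messages) + [
        f"rhat_{k}={v:.4f}" for k, v in fit.rhat.items() if not math.isnan(v)
    ]
    return GlmmResult(
        fixed=fixed,
        random=taus,
        sigma2_residual=SIGMA2_LOGISTIC,
        icc=icc_logistic(list(taus.values())),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=fit.converged,
        n_obs=len(rows),
        method="mcmc",
        messages=messages,
    )


# ---------------------------------------------------------------------------
# derived quantities

def combine_odds(intercept_or: float, ppplus_or: float) -> float:
    """Odds of choosing PP+ targets above chance: the intercept (PP- above
    chance) odds multiplied by the PP+ odds ratio."""
    if intercept_or <= 0 or ppplus_or <= 0:
        raise AnalysisError("odds ratios must be positive")
    return intercept_or * ppplus_or


def icc_logistic(
    tau_components: Sequence[float], sigma2: float = SIGMA2_LOGISTIC
) -> float:
    """Adjusted latent-scale intraclass correlation for logistic mixed models."""
    taus = [float(t) for t in tau_components]
    if any(t < 0 for t in taus) or sigma2 < 0:
        raise AnalysisError("variances must be >= 0")
    total = sum(taus)
    return total / (total + sigma2)


def r2_nakagawa(
    fixed_effect_variance: float,
    tau_components: Sequence[float],
    sigma2: float = SIGMA2_LOGISTIC,
) -> tuple[float, float]:
    """Marginal and conditional R^2 on the latent scale."""
    if fixed_effect_variance < 0 or any(t < 0 for t in tau_components) or sigma2 < 0:
        raise AnalysisError("variance inputs must be >= 0")
    tau = sum(float(t) for t in tau_components)
    denom = fixed_effect_variance + tau + sigma2
    return fixed_effect_variance / denom, (fixed_effect_variance + tau) / denom


# ---------------------------------------------------------------------------
# descriptive summaries

def accuracy_summary(
    dataset: AnalysisDataset, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Per-set mean accuracy with 95% percentile bootstrap intervals obtained
    by resampling participants with replacement."""
    rows = dataset.rows
    if rows["participant_id"].nunique() < 2:
        raise AnalysisError("need >= 2 participants to bootstrap")
    rng = np.random.default_rng(seed)
    out = []
    for label, grp in rows.groupby("set_label"):
        per_part = grp.groupby("participant_id")["correct"].mean()
        vals = per_part.to_numpy()
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boots = vals[idx].mean(axis=1)
        out.append(
            {
                "set_label": label,
                "mean_accuracy": float(vals.mean()),
                "ci_low": float(np.quantile(boots, 0.025)),
                "ci_high": float(np.quantile(boots, 0.975)),
                "n_participants": len(vals),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# power

@dataclass(frozen=True)
class PowerSpec:
    """One-sample t-test of mean accuracy against chance (0.25)."""

    effect_size_d: float
    n: int
    alpha: float = 0.05
    null_value: float = CHANCE

    def __post_init__(self) -> None:
        if self.n < 2:
            raise AnalysisError("n must be >= 2")
        if not 0 < self.alpha < 1:
            raise AnalysisError("alpha must be in (0, 1)")


def power_one_sample_t(spec: PowerSpec) -> float:
    """Exact two-sided power from the noncentral t distribution with
    noncentrality d * sqrt(n)."""
    from statsmodels.stats.power import TTestPower

    power = TTestPower().power(
        effect_size=spec.effect_size_d,
        nobs=spec.n,
        alpha=spec.alpha,
        alternative="two-sided",
    )
    return float(np.clip(power, 0.0, 1.0))
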