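"""Second-stage Bayesian regression of CAS parameters on immune predictors.

Each of the seven CAS parameters (standardized) is regressed on the six
centered-and-scaled immune-cell predictors — and, in the
confounder-adjusted model, on age, sex and body-composition terms — with
Normal(0, 3) priors on every coefficient.  The seven responses are fitted
as independent Gaussian linear models within a joint wrapper (residual
correlation among responses is not modelled).  Posteriors are summarised
in the SEXIT style: median, 95% highest-density interval, probability of
direction (pd) and the posterior mass outside a region of practical
equivalence (ps, ROPE = +/-0.1 response SDs).  Convergence is checked via
rank-normalized split R-hat and bulk effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .params import CAS_PARAM_NAMES
from .sampler import HMCConfig, LinearModelPosterior, sample_linear_model
from .synth import CONFOUNDER_COLUMNS, PREDICTOR_COLUMNS

__all__ = [
    "RegressionSpec",
    "PosteriorDraws",
    "standardize",
    "destandardize",
    "fit_multivariate_regression",
    "sexit_summary",
    "diagnostics",
]

#: condition number above which a collinearity warning is emitted
_COND_WARN = 30.0


@dataclass(frozen=True)
class RegressionSpec:
    """Configuration of the second-stage regression."""

    responses: Sequence[str] = CAS_PARAM_NAMES
    include_confounders: bool = False
    prior_sd: float = 3.0
    chains: int = 5
    warmup: int = 2000
    sampling: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.warmup < 500 or self.sampling < 500:
            raise ValueError("warmup and sampling must each be >= 500")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")

    @property
    def n_draws(self) -> int:
        return self.chains * self.sampling


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws for every coefficient of every response.

    ``draws[response][coefficient]`` is an array of shape
    (chains, sampling); coefficient names are ``"Intercept"``, the
    predictor/confounder column names, and ``"sigma"``.
    """

    draws: dict
    coef_names: list
    responses: list
    spec: RegressionSpec
    design: Optional[np.ndarray] = None
    observed: dict = field(default_factory=dict)
    standardization: dict = field(default_factory=dict)
    accept_rates: dict = field(default_factory=dict)

    def pooled(self, response: str, coefficient: str) -> np.ndarray:
        return self.draws[response][coefficient].reshape(-1)

    def n_draws_per_parameter(self) -> int:
        any_resp = next(iter(self.draws.values()))
        any_arr = next(iter(any_resp.values()))
        return int(any_arr.size)

    def to_arviz(self) -> "az.InferenceData":
        flat = {
            f"{resp}:{name}": arr
            for resp, coefs in self.draws.items()
            for name, arr in coefs.items()
        }
        return az.from_dict(posterior=flat)


def standardize(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    binary_columns: Sequence[str] = ("sex",),
):
    """Center and scale columns to mean 0, SD 1.

    Binary columns are passed through untouched (sex stays 0/1).  Returns
    the transformed table and a metadata dict ``{column: (mean, sd)}``
    holding the moments actually applied, for back-transformation.
    """
    out = table.copy()
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in binary_columns and pd.api.types.is_numeric_dtype(table[c])
        ]
    meta = {}
    for col in columns:
        if col in binary_columns:
            continue
        v = out[col].to_numpy(float)
        m, s = float(v.mean()), float(v.std(ddof=1))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {col!r} has zero standard deviation")
        out[col] = (v - m) / s
        meta[col] = (m, s)
    return out, meta


def destandardize(table: pd.DataFrame, meta: dict) -> pd.DataFrame:
    """Invert :func:`standardize` using its metadata."""
    out = table.copy()
    for col, (m, s) in meta.items():
        if col in out.columns:
            out[col] = out[col].to_numpy(float) * s + m
    return out


def _design_matrix(df: pd.DataFrame, include_confounders: bool):
    cols = list(PREDICTOR_COLUMNS)
    if include_confounders:
        cols += list(CONFOUNDER_COLUMNS)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    names = ["Intercept"] + cols
    return X, names


def fit_multivariate_regression(
    theta_table: pd.DataFrame,
    immune: pd.DataFrame,
    spec: RegressionSpec = RegressionSpec(),
) -> PosteriorDraws:
    """Fit the multivariate (7-response) Bayesian regression.

    ``theta_table`` holds per-subject CAS estimates (``subject_id`` plus
    the seven parameter columns); ``immune`` the raw predictor/covariate
    table.  Rows are aligned on ``subject_id`` and incomplete cases are
    dropped.  Continuous predictors and all responses are standardized
    internally, so coefficients are standardized effect sizes and the
    default ROPE of +/-0.1 is in response-SD units.
    """
    merged = theta_table.merge(immune, on="subject_id", how="inner")
    needed = list(spec.responses) + list(PREDICTOR_COLUMNS)
    if spec.include_confounders:
        needed += list(CONFOUNDER_COLUMNS)
    merged = merged.dropna(subset=needed)
    if len(merged) < 10:
        raise ValueError(f"too few complete cases: {len(merged)}")

    cont_cols = [c for c in needed if c != "sex"]
    std_table, meta = standardize(merged[["subject_id"] + needed], columns=cont_cols)

    X, coef_names = _design_matrix(std_table, spec.include_confounders)
    cond = float(np.linalg.cond(X))
    if cond > _COND_WARN:
        warnings.warn(
            f"design matrix condition number {cond:.1f} indicates collinear "
            "predictors; coefficients remain interpretable jointly, not marginally",
            stacklevel=2,
        )

    cfg = HMCConfig(chains=spec.chains, warmup=spec.warmup, sampling=spec.sampling)
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(spec.responses))
    draws: dict = {}
    observed: dict = {}
    accept: dict = {}
    for i, resp in enumerate(spec.responses):
        y = std_table[resp].to_numpy(float)
        post = LinearModelPosterior(X, y, prior_sd=spec.prior_sd)
        result = sample_linear_model(post, cfg, seed=int(seeds[i] % (2**31 - 1)))
        if result["accept_rate"] < 0.2:
            raise RuntimeError(
                f"sampling failed for response {resp!r}: acceptance rate "
                f"{result['accept_rate']:.2f}; no partial output returned"
            )
        arr = result["draws"]  # (chains, sampling, p + 1)
        coefs = {name: arr[:, :, j] for j, name in enumerate(coef_names)}
        coefs["sigma"] = np.exp(arr[:, :, -1])
        draws[resp] = coefs
        observed[resp] = y
        accept[resp] = result["accept_rate"]

    return PosteriorDraws(
        draws=draws,
        coef_names=coef_names + ["sigma"],
        responses=list(spec.responses),
        spec=spec,
        design=X,
        observed=observed,
        standardization=meta,
        accept_rates=accept,
    )


def _hdi(x: np.ndarray, prob: float = 0.95):
    """Shortest contiguous interval over the sorted draws holding ``prob``."""
    x = np.sort(x)
    n = x.size
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def _sexit_row(x: np.ndarray, rope_halfwidth: float) -> dict:
    pos = float(np.mean(x > 0))
    neg = float(np.mean(x < 0))
    pd_val = max(pos, neg)
    if pd_val == 0.0:  # all draws exactly zero
        pd_val = 0.5
    lo, hi = _hdi(x)
    return {
        "median": float(np.median(x)),
        "hdi_low": lo,
        "hdi_high": hi,
        "pd": pd_val,
        "ps": float(np.mean(np.abs(x) > rope_halfwidth)),
        "rope_halfwidth": rope_halfwidth,
    }


def sexit_summary(draws: PosteriorDraws, rope_halfwidth: float = 0.1) -> pd.DataFrame:
    """SEXIT report: one row per response x coefficient.

    With standardized responses the default ROPE half-width of 0.1 equals
    0.1 response SDs.  Requires at least 1,000 draws per coefficient.
    """
    if draws.n_draws_per_parameter() < 1000:
        raise ValueError("need >= 1,000 draws per coefficient for SEXIT summaries")
    rows = []
    for resp in draws.responses:
        for name in draws.coef_names:
            if name == "sigma":
                continue
            row = {"response": resp, "coefficient": name}
            row.update(_sexit_row(draws.pooled(resp, name), rope_halfwidth))
            rows.append(row)
    return pd.DataFrame(rows)


def diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 1000.0,
    n_ppc_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Convergence diagnostics and posterior predictive summary checks.

    Rank-normalized split R-hat and bulk effective sample size per
    parameter (via arviz); parameters breaching the thresholds are listed
    under ``"flagged"``.  The posterior predictive check compares mean, SD
    and quartiles of replicated responses against the observed ones.
    """
    any_resp = next(iter(draws.draws.values()))
    n_chains = next(iter(any_resp.values())).shape[0]
    if n_chains < 2:
        raise ValueError("R-hat is undefined for a single chain")

    idata = draws.to_arviz()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in rhat_ds.data_vars}
    ess = {k: float(ess_ds[k].values) for k in ess_ds.data_vars}
    flagged = sorted(
        [k for k, v in rhat.items() if v >= rhat_threshold]
        + [k for k, v in ess.items() if v <= ess_threshold]
    )

    ppc = {}
    if draws.design is not None and draws.observed:
        rng = np.random.default_rng(seed)
        X = draws.design
        for resp in draws.responses:
            y = draws.observed[resp]
            coef_mat = np.stack(
                [draws.pooled(resp, n) for n in draws.coef_names if n != "sigma"],
                axis=1,
            )
            sig = draws.pooled(resp, "sigma")
            pick = rng.integers(0, coef_mat.shape[0], n_ppc_draws)
            rep = coef_mat[pick] @ X.T + sig[pick, None] * rng.standard_normal(
                (n_ppc_draws, X.shape[0])
            )
            q = [0.25, 0.5, 0.75]
            ppc[resp] = {
                "observed": {
                    "mean": float(y.mean()),
                    "sd": float(y.std(ddof=1)),
                    "quantiles": [float(v) for v in np.quantile(y, q)],
                },
                "replicated": {
                    "mean": float(rep.mean()),
                    "sd": float(rep.std()),
                    "quantiles": [float(v) for v in np.quantile(rep, q)],
                },
            }

    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": max(rhat.values()),
        "min_ess": min(ess.values()),
        "flagged": flagged,
        "ppc": ppc,
        "accept_rates": dict(draws.accept_rates),
    }
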