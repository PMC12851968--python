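"""Synthetic RRi trajectories and cohorts with known ground truth.

The generator emulates a reference cohort of 81 community-dwelling older
adults undergoing a rest / 2-min step-test / 5-min recovery protocol with
continuous beat-interval recording, and immune phenotyping of B-cell
subsets by CD21/CD11c surface expression.  Cohort-level CAS parameter
means and the marginal means/SDs of the immune predictors default to that
cohort's published summary statistics, so simulated data carry the
statistical structure the downstream analysis assumes — while providing
the ground truth the real cohort cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import evaluate_model
from .params import CAS_PARAM_NAMES, CASParameters, ProtocolTiming
from .recording import MS_PER_MIN, RRiRecording

__all__ = [
    "PREDICTOR_COLUMNS",
    "CONFOUNDER_COLUMNS",
    "COHORT_CAS_MEANS",
    "COHORT_CAS_CI95",
    "cohort_cas_sds",
    "COHORT_MARGINALS",
    "CONFOUNDER_MARGINALS",
    "CohortTruth",
    "simulate_rri_trajectory",
    "inject_artifacts",
    "simulate_cohort",
]

#: Immune predictors (absolute counts per microlitre), in model order.
PREDICTOR_COLUMNS = (
    "lymphocytes",
    "b_total",
    "cd21p_cd11cn",  # CD21+CD11c-  naive / resting memory B cells
    "cd21p_cd11cp",  # CD21+CD11c+  activated memory B cells
    "cd21n_cd11cp",  # CD21-CD11c+  age-associated B cells (ABCs)
    "cd21n_cd11cn",  # CD21-CD11c-  putatively anergic B cells
)

#: Covariates adjusted for in the confounder model.
CONFOUNDER_COLUMNS = ("age", "sex", "fat_pct", "muscle_kg")

ALL_EFFECT_COLUMNS = PREDICTOR_COLUMNS + CONFOUNDER_COLUMNS

#: Cohort-level CAS parameter means (reference cohort, n = 81).
COHORT_CAS_MEANS = {
    "alpha": 884.77,  # ms
    "beta": 403.99,  # ms
    "c": 0.89,
    "lam": 3.01,  # min^-1
    "phi": 2.18,  # min^-1
    "tau": 6.89,  # min
    "delta": 2.50,  # min
}

#: 95% intervals on the cohort means (same source, n = 81).
COHORT_CAS_CI95 = {
    "alpha": (840.27, 925.77),
    "beta": (355.60, 451.58),
    "c": (0.84, 0.94),
    "lam": (2.57, 3.44),
    "phi": (1.63, 2.71),
    "tau": (6.66, 7.11),
    "delta": (2.28, 2.72),
}

_COHORT_N = 81
_Z975 = 1.959963984540054


def cohort_cas_sds(n: int = _COHORT_N) -> dict:
    """Between-subject SDs implied by the cohort-mean 95% intervals.

    Treats each interval as mean +/- 1.96 * SD / sqrt(n) and inverts for
    the SD.  These set the scale of between-subject variation in
    :func:`simulate_cohort`.
    """
    return {
        k: (hi - lo) / (2.0 * _Z975) * math.sqrt(n)
        for k, (lo, hi) in COHORT_CAS_CI95.items()
    }


#: Marginal (mean, SD) of the immune-count predictors, cells per uL.
COHORT_MARGINALS = {
    "lymphocytes": (70_686.04, 27_256.28),
    "b_total": (9_752.43, 5_513.14),
    "cd21p_cd11cn": (8_351.0, 4_994.0),
    "cd21p_cd11cp": (198.0, 139.0),
    "cd21n_cd11cp": (328.0, 218.0),
    "cd21n_cd11cn": (727.0, 488.0),
}

#: Confounder marginals: Gaussian (mean, SD) for continuous, P(male) for sex.
CONFOUNDER_MARGINALS = {
    "age": (70.60, 5.80),
    "fat_pct": (35.35, 8.77),
    "muscle_kg": (45.19, 8.53),
    "sex_p_male": 25.0 / 81.0,  # coded 0 = female, 1 = male
}

_MAX_REDRAWS = 100


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-min(x, 700.0)))
    z = math.exp(max(x, -700.0))
    return z / (1.0 + z)


def _curve(t: float, th) -> float:
    alpha, beta, c, lam, phi, tau, delta = th
    return (
        alpha
        - beta * _sigmoid(lam * (t - tau))
        + c * beta * _sigmoid(phi * (t - tau - delta))
    )


def simulate_rri_trajectory(
    params: CASParameters,
    protocol: ProtocolTiming = ProtocolTiming(),
    seed: int = 0,
    subject_id: str = "subject",
) -> RRiRecording:
    """Simulate a beat-by-beat RRi recording from the dual-logistic curve.

    Beats are generated sequentially from t = 0: the interval observed at
    beat time ``t`` is ``f(t | theta) + Normal(0, sigma)`` ms and the clock
    advances by that interval, so beat density itself tracks heart rate.
    Generation stops once the clock passes the protocol span.  Nonpositive
    draws (pathological ``sigma``) are redrawn up to a bounded number of
    times, then an error is raised.
    """
    span = protocol.total_duration
    if span <= params.tau + params.delta:
        raise ValueError(
            f"protocol span {span} min must exceed tau + delta = "
            f"{params.tau + params.delta} min"
        )
    th = params.as_array()
    sigma = params.sigma
    rng = np.random.default_rng(seed)
    times: list = []
    intervals: list = []
    t = 0.0
    noise_buf: np.ndarray = np.empty(0)
    buf_pos = 0
    while t < span:
        mean = _curve(t, th)
        interval = mean
        if sigma > 0:
            for attempt in range(_MAX_REDRAWS + 1):
                if buf_pos >= noise_buf.size:
                    noise_buf = rng.standard_normal(256)
                    buf_pos = 0
                interval = mean + sigma * noise_buf[buf_pos]
                buf_pos += 1
                if interval > 0:
                    break
            else:
                raise ValueError(
                    f"noise too large: could not draw a positive interval at "
                    f"t = {t:.3f} min (mean {mean:.1f} ms, sigma {sigma} ms)"
                )
        elif interval <= 0:
            raise ValueError(f"model mean nonpositive at t = {t:.3f} min")
        times.append(t)
        intervals.append(interval)
        t += interval / MS_PER_MIN
    return RRiRecording(
        np.array(times), np.array(intervals), subject_id=subject_id
    )


def inject_artifacts(
    rec: RRiRecording,
    ectopic_rate: float,
    magnitude_range: tuple = (0.3, 0.6),
    seed: int = 0,
):
    """Corrupt a recording with ectopic-like interval spikes.

    Each beat is independently corrupted with probability ``ectopic_rate``
    by multiplying its interval by ``1 - u`` or ``1 + u`` (alternating
    short/long across corrupted beats), with ``u`` uniform over
    ``magnitude_range``.  Beat times are left untouched: the corruption
    models a beat-detection artifact, not real physiology.

    Returns
    -------
    (RRiRecording, ndarray of bool)
        The corrupted recording and the ground-truth corruption mask.
    """
    if not 0 <= ectopic_rate < 0.5:
        raise ValueError(f"ectopic_rate must be in [0, 0.5), got {ectopic_rate}")
    lo, hi = magnitude_range
    if not (0 < lo <= 1 and 0 < hi <= 1 and lo <= hi):
        raise ValueError(f"magnitude fractions must lie in (0, 1], got {magnitude_range}")
    out = rec.copy()
    truth_mask = np.zeros(len(rec), bool)
    if ectopic_rate == 0:
        return out, truth_mask
    rng = np.random.default_rng(seed)
    hit = rng.random(len(rec)) < ectopic_rate
    idx = np.flatnonzero(hit)
    u = rng.uniform(lo, hi, idx.size)
    signs = np.where(np.arange(idx.size) % 2 == 0, -1.0, 1.0)  # short, long, ...
    out.intervals[idx] = out.intervals[idx] * (1.0 + signs * u)
    truth_mask[idx] = True
    return out, truth_mask


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    n_subjects: int
    true_coefficients: pd.DataFrame  # 7 CAS params x effect columns, SD units
    subject_parameters: list  # CASParameters per subject
    immune_table: pd.DataFrame
    seed: int
    cas_means: dict = field(default_factory=dict)
    cas_sds: dict = field(default_factory=dict)
    residual_sds: dict = field(default_factory=dict)

    def parameter_table(self) -> pd.DataFrame:
        rows = {
            k: [getattr(p, k) for p in self.subject_parameters]
            for k in CAS_PARAM_NAMES
        }
        df = pd.DataFrame(rows)
        df.insert(0, "subject_id", self.immune_table["subject_id"].to_numpy())
        return df


def _lognormal_moments(mean: float, sd: float) -> tuple:
    """(mu, sigma) of a log-normal with the requested mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("marginal means and SDs must be positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _coerce_coefficients(true_coefficients) -> pd.DataFrame:
    cols = list(ALL_EFFECT_COLUMNS)
    if true_coefficients is None:
        return pd.DataFrame(
            np.zeros((7, len(cols))), index=list(CAS_PARAM_NAMES), columns=cols
        )
    if isinstance(true_coefficients, pd.DataFrame):
        df = true_coefficients.reindex(
            index=list(CAS_PARAM_NAMES), columns=cols
        ).fillna(0.0)
        return df.astype(float)
    arr = np.asarray(true_coefficients, float)
    if arr.shape != (7, len(cols)):
        raise ValueError(
            f"effect matrix must be 7 x {len(cols)} "
            f"(CAS params x predictors+confounders), got {arr.shape}"
        )
    return pd.DataFrame(arr, index=list(CAS_PARAM_NAMES), columns=cols)


def simulate_cohort(
    n_subjects: int,
    true_coefficients=None,
    marginals: Optional[dict] = None,
    confounder_config: Optional[dict] = None,
    protocol: ProtocolTiming = ProtocolTiming(),
    seed: int = 0,
    sigma: float = 30.0,
    residual_scale: Optional[float] = None,
    simulate_recordings: bool = True,
):
    """Simulate a full cohort: immune tables, per-subject CAS, recordings.

    Immune counts are drawn from independent log-normal laws moment-matched
    to ``marginals`` (default: the reference-cohort values); confounders
    from Gaussian/Bernoulli laws per ``confounder_config``.  Each subject's
    CAS parameter ``k`` is::

        mean_k + SD_k * (sum_p coeff[k, p] * x_p) + Normal(0, resid_k)

    with ``x_p`` the standardized predictors/centered sex and ``SD_k`` the
    implied between-subject SD.  By default ``resid_k = SD_k *
    sqrt(max(0, 1 - sum_p coeff[k, p]^2))`` so the total between-subject SD
    equals ``SD_k`` and each requested coefficient is the population
    standardized effect the two-step pipeline estimates; pass
    ``residual_scale`` to force ``resid_k = residual_scale * SD_k`` instead.

    A deterministic mean vector violating the CAS invariants (e.g.
    ``alpha - beta <= 0``) raises an error naming the subject; residual
    draws landing outside the valid region are redrawn (truncation).

    Returns
    -------
    (CohortTruth, list of RRiRecording)
        Recordings are omitted (empty list) when ``simulate_recordings``
        is False.
    """
    coeff = _coerce_coefficients(true_coefficients)
    marg = dict(COHORT_MARGINALS)
    if marginals:
        marg.update(marginals)
    conf = dict(CONFOUNDER_MARGINALS)
    if confounder_config:
        conf.update(confounder_config)

    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    table = {"subject_id": subject_ids}
    for col in PREDICTOR_COLUMNS:
        mu, s = _lognormal_moments(*marg[col])
        table[col] = rng.lognormal(mu, s, n_subjects)
    table["age"] = rng.normal(*conf["age"], n_subjects)
    table["sex"] = (rng.random(n_subjects) < conf["sex_p_male"]).astype(float)
    table["fat_pct"] = rng.normal(*conf["fat_pct"], n_subjects)
    table["muscle_kg"] = rng.normal(*conf["muscle_kg"], n_subjects)
    immune = pd.DataFrame(table)

    # standardized design for the generator's linear map
    X = np.empty((n_subjects, len(ALL_EFFECT_COLUMNS)))
    for j, col in enumerate(ALL_EFFECT_COLUMNS):
        v = immune[col].to_numpy(float)
        if col == "sex":
            X[:, j] = v - v.mean()
        else:
            sd = v.std(ddof=1)
            X[:, j] = (v - v.mean()) / sd

    means = COHORT_CAS_MEANS
    sds = cohort_cas_sds()
    resid = {}
    for k in CAS_PARAM_NAMES:
        if residual_scale is not None:
            resid[k] = residual_scale * sds[k]
        else:
            resid[k] = sds[k] * math.sqrt(
                max(0.0, 1.0 - float((coeff.loc[k] ** 2).sum()))
            )

    eta = X @ coeff.to_numpy().T  # (n, 7) linear predictors in SD units
    mean_mat = np.array([means[k] for k in CAS_PARAM_NAMES]) + eta * np.array(
        [sds[k] for k in CAS_PARAM_NAMES]
    )
    resid_vec = np.array([resid[k] for k in CAS_PARAM_NAMES])

    span = protocol.total_duration

    def _ok(theta: np.ndarray) -> bool:
        # CAS invariants plus enough room in the protocol for the recovery
        return CASParameters.is_valid_vector(theta) and theta[5] + theta[6] < span

    subject_params = []
    for i in range(n_subjects):
        if not _ok(mean_mat[i]):
            raise ValueError(
                f"effect matrix produces an invalid mean CAS vector for "
                f"subject {subject_ids[i]}: {dict(zip(CAS_PARAM_NAMES, mean_mat[i]))}"
            )
        for _ in range(_MAX_REDRAWS):
            theta = mean_mat[i] + resid_vec * rng.standard_normal(7)
            if _ok(theta):
                break
        else:
            raise ValueError(
                f"could not draw a valid CAS vector for subject {subject_ids[i]}"
            )
        subject_params.append(CASParameters.from_array(theta, sigma=sigma))

    truth = CohortTruth(
        n_subjects=n_subjects,
        true_coefficients=coeff,
        subject_parameters=subject_params,
        immune_table=immune,
        seed=seed,
        cas_means=dict(means),
        cas_sds=sds,
        residual_sds=resid,
    )

    recordings = []
    if simulate_recordings:
        traj_seeds = rng.integers(0, 2**31 - 1, n_subjects)
        for i, p in enumerate(subject_params):
            recordings.append(
                simulate_rri_trajectory(
                    p, protocol, seed=int(traj_seeds[i]), subject_id=subject_ids[i]
                )
            )
    return truth, recordings
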