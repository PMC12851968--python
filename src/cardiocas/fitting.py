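"""Robust per-subject estimation of the CAS parameter vector.

The first analysis stage is a point-estimation problem: minimize a Huber
objective on the beat-interval residuals over the 7 model parameters,
within physiologic box constraints, using a bounded quasi-Newton optimizer
(L-BFGS-B) with analytic gradients and multi-start initialization.  The
Huber threshold is set adaptively to 1.345 times a robust estimate of the
beat-to-beat noise scale — the scaled MAD of residuals from a local
polynomial trend (1.345 is the standard 95%-efficiency constant) — and held
fixed during optimization.  The observation-noise SD ``sigma`` is
estimated post hoc as the scaled MAD of the final residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .model import evaluate_model, huber_loss, huber_psi, model_gradient
from .params import CAS_PARAM_NAMES, CASParameters, ParameterBounds, ProtocolTiming
from .preprocess import (
    MAD_GAUSSIAN_CONSTANT,
    FilterConfig,
    local_polynomial_trend,
    lowpass_zero_phase,
)
from .recording import RRiRecording

__all__ = ["CASFit", "initialize_parameters", "fit_cas", "HUBER_EFFICIENCY_CONSTANT"]

#: 95%-efficiency tuning constant for the Huber threshold, in robust SDs.
HUBER_EFFICIENCY_CONSTANT = 1.345


@dataclass
class CASFit:
    """Result of a robust CAS fit."""

    estimate: CASParameters
    loss: float
    converged: bool
    n_starts: int
    residual_scale: float
    n_beats_used: int
    huber_threshold: Optional[float]
    message: str = ""

    def as_row(self, subject_id: str = "subject") -> dict:
        row = {"subject_id": subject_id}
        row.update({k: getattr(self.estimate, k) for k in CAS_PARAM_NAMES})
        row.update(
            sigma=self.estimate.sigma,
            loss=self.loss,
            converged=self.converged,
            n_beats_used=self.n_beats_used,
        )
        return row


def _robust_scale(r: np.ndarray) -> float:
    return MAD_GAUSSIAN_CONSTANT * float(np.median(np.abs(r - np.median(r))))


def initialize_parameters(
    rec: RRiRecording,
    protocol: ProtocolTiming = ProtocolTiming(),
    bounds: Optional[ParameterBounds] = None,
) -> CASParameters:
    """Heuristic optimizer start from the cleaned recording.

    Baseline from the first-minute median; drop magnitude from the minimum
    of a smoothed copy of the series; drop onset from the steepest smoothed
    descent; recovery lag from the exercise duration; rates at 2 min^-1.
    """
    if rec.n_kept < 50:
        raise ValueError(f"need >= 50 kept beats to initialize, got {rec.n_kept}")
    if bounds is None:
        bounds = ParameterBounds.for_protocol(protocol)
    t = rec.kept_times
    y = rec.kept_intervals
    try:
        sm = lowpass_zero_phase(rec).intervals[~rec.artifact_mask]
    except ValueError:
        sm = y
    first_min = y[t <= t[0] + 1.0]
    alpha0 = float(np.median(first_min if first_min.size else y[:10]))
    beta0 = alpha0 - float(sm.min())
    if beta0 < 10.0:
        warnings.warn(
            f"degenerate drop magnitude at initialization (beta0 = {beta0:.1f} ms); "
            "flat series?",
            stacklevel=2,
        )
        beta0 = 10.0
    slope = np.gradient(sm, t)
    tau0 = float(t[int(np.argmin(slope))])
    theta0 = np.array(
        [alpha0, beta0, 0.8, 2.0, 2.0, tau0, protocol.exercise_duration]
    )
    theta0 = bounds.clip(theta0)
    # keep the nadir positive even for aggressive drop starts
    if theta0[0] - theta0[1] <= 0:
        theta0[1] = 0.9 * theta0[0]
    return CASParameters.from_array(theta0)


def _objective(theta, t, y, threshold):
    r = y - evaluate_model(t, theta)
    psi = huber_psi(r, threshold) if threshold is not None else r
    if threshold is not None:
        loss = huber_loss(r, threshold)
    else:
        loss = float(0.5 * r @ r)
    grad = -(psi @ model_gradient(t, theta))
    return loss, grad


def fit_cas(
    rec: RRiRecording,
    bounds: Optional[ParameterBounds] = None,
    n_starts: int = 5,
    seed: int = 0,
    protocol: ProtocolTiming = ProtocolTiming(),
    loss: str = "huber",
    jitter: float = 0.10,
) -> CASFit:
    """Box-constrained quasi-Newton fit of the dual-logistic curve.

    Only kept (unmasked) beats enter the objective.  ``loss`` may be
    ``"huber"`` (default) or ``"squared"`` for a plain least-squares fit
    with the same machinery (used e.g. to quantify the robustness gain).
    Deterministic for a given ``seed``.
    """
    if loss not in ("huber", "squared"):
        raise ValueError(f"unknown loss {loss!r}")
    if bounds is None:
        bounds = ParameterBounds.for_protocol(protocol)
    t = rec.kept_times
    y = rec.kept_intervals
    start0 = initialize_parameters(rec, protocol, bounds).as_array()

    threshold = None
    if loss == "huber":
        # Robust beat-to-beat noise scale from local-trend residuals: the
        # trend tracks the curve without committing to parameter values, so
        # the scale is not inflated by start-point model mismatch.
        scale0 = _robust_scale(y - local_polynomial_trend(y))
        threshold = max(HUBER_EFFICIENCY_CONSTANT * scale0, 1e-6)

    lo, hi = bounds.as_arrays()
    rng = np.random.default_rng(seed)
    starts = [start0]
    for _ in range(max(n_starts - 1, 0)):
        jittered = start0 * (1.0 + jitter * rng.standard_normal(7))
        starts.append(np.clip(jittered, lo, hi))

    best = None
    for x0 in starts:
        res = minimize(
            _objective,
            x0,
            args=(t, y, threshold),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = np.asarray(best.x, float)
    final_loss = float(best.fun)
    # projected gradient: ignore components pushing outside active bounds
    g = np.asarray(best.jac, float)
    pg = g.copy()
    at_lo = np.isclose(theta, lo) & (g > 0)
    at_hi = np.isclose(theta, hi) & (g < 0)
    pg[at_lo | at_hi] = 0.0
    grad_ok = bool(np.max(np.abs(pg)) <= 1e-3 * (1.0 + abs(final_loss)))
    converged = bool(best.success) and grad_ok and np.isfinite(final_loss)

    resid = y - evaluate_model(t, theta)
    sigma_hat = _robust_scale(resid)
    estimate = CASParameters.from_array(
        _repair_invariants(theta, lo, hi), sigma=sigma_hat
    )
    return CASFit(
        estimate=estimate,
        loss=final_loss,
        converged=converged,
        n_starts=len(starts),
        residual_scale=sigma_hat,
        n_beats_used=int(t.size),
        huber_threshold=threshold,
        message=str(best.message),
    )


def _repair_invariants(theta, lo, hi):
    """Nudge a boundary solution off invalid edges (lam or phi exactly 0)
    so it remains representable; box defaults keep rates >= 0.1 anyway."""
    theta = theta.copy()
    for i in (3, 4):  # lam, phi strictly positive
        if theta[i] <= 0:
            theta[i] = max(lo[i], 1e-6)
    if theta[0] - theta[1] <= 0:  # keep the nadir positive
        theta[1] = theta[0] - 1e-6
    return theta
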