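"""The dual-logistic RRi-vs-time model and the robust (Huber) objective.

The curve is the sum of a baseline and two opposing logistic transitions:
a drop of magnitude ``beta`` at time ``tau`` with rate ``lam``, and a
recovery of magnitude ``c * beta`` at time ``tau + delta`` with rate
``phi``::

    f(t) = alpha - beta * S(t; lam, tau) + c * beta * S(t; phi, tau + delta)

where ``S(t; r, t0) = 1 / (1 + exp(-r (t - t0)))`` is a rising smooth step.
Under this convention ``alpha`` is the resting baseline, the exercise nadir
approaches ``alpha - beta`` (for well-separated transitions) and the
post-recovery asymptote is ``alpha - beta * (1 - c)``.

An equivalent "reflected" form writes each phase with a *positive* rate
inside the exponential, ``alpha' + beta / (1 + exp(lam (t - tau))) - c *
beta / (1 + exp(phi (t - tau - delta)))``; the two forms coincide when
``alpha' = alpha - beta * (1 - c)`` (see :func:`evaluate_model_reflected`).
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.special import expit

from .params import CASParameters

__all__ = [
    "evaluate_model",
    "evaluate_model_reflected",
    "model_gradient",
    "huber_loss",
    "huber_psi",
]


def _theta(params: Union[CASParameters, np.ndarray]) -> np.ndarray:
    if isinstance(params, CASParameters):
        return params.as_array()
    return np.asarray(params, float)


def evaluate_model(t, params: Union[CASParameters, np.ndarray]) -> np.ndarray:
    """Predicted RRi (ms) at time(s) ``t`` (min).

    Vectorized over ``t``; exact limits are ``f(-inf) = alpha`` and
    ``f(+inf) = alpha - beta * (1 - c)``.
    """
    alpha, beta, c, lam, phi, tau, delta = _theta(params)
    t = np.asarray(t, float)
    s_drop = expit(lam * (t - tau))
    s_rec = expit(phi * (t - tau - delta))
    return alpha - beta * s_drop + c * beta * s_rec


def evaluate_model_reflected(t, params: Union[CASParameters, np.ndarray]) -> np.ndarray:
    """The same curve written with positive rates inside the exponentials.

    ``g(t) = a + beta/(1+e^{lam (t-tau)}) - c*beta/(1+e^{phi (t-tau-delta)})``
    with ``a = alpha - beta*(1-c)``.  Provided to document and test the
    bijection between the two sign conventions.
    """
    alpha, beta, c, lam, phi, tau, delta = _theta(params)
    t = np.asarray(t, float)
    a = alpha - beta * (1.0 - c)
    return (
        a
        + beta / (1.0 + np.exp(np.clip(lam * (t - tau), -700, 700)))
        - c * beta / (1.0 + np.exp(np.clip(phi * (t - tau - delta), -700, 700)))
    )


def model_gradient(t, params: Union[CASParameters, np.ndarray]) -> np.ndarray:
    """Jacobian of ``evaluate_model`` w.r.t. (alpha, beta, c, lam, phi,
    tau, delta); shape ``(len(t), 7)``."""
    alpha, beta, c, lam, phi, tau, delta = _theta(params)
    t = np.atleast_1d(np.asarray(t, float))
    s1 = expit(lam * (t - tau))
    s2 = expit(phi * (t - tau - delta))
    d1 = s1 * (1.0 - s1)  # dS/d(argument)
    d2 = s2 * (1.0 - s2)
    g = np.empty((t.size, 7))
    g[:, 0] = 1.0
    g[:, 1] = -s1 + c * s2
    g[:, 2] = beta * s2
    g[:, 3] = -beta * d1 * (t - tau)
    g[:, 4] = c * beta * d2 * (t - tau - delta)
    g[:, 5] = beta * lam * d1 - c * beta * phi * d2
    g[:, 6] = -c * beta * phi * d2
    return g


def huber_psi(residuals: np.ndarray, threshold: float) -> np.ndarray:
    """Derivative of the Huber rho: r on the quadratic branch, clipped at
    +/- threshold on the linear branches."""
    return np.clip(residuals, -threshold, threshold)


def huber_loss(residuals: np.ndarray, threshold: float) -> float:
    """Sum of the Huber rho over residuals (ms).

    rho(r) = r^2 / 2 for |r| <= threshold, else
    threshold * (|r| - threshold / 2).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    r = np.abs(np.asarray(residuals, float))
    quad = r <= threshold
    out = np.where(quad, 0.5 * r * r, threshold * (r - 0.5 * threshold))
    return float(out.sum())
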