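"""RRi cleaning: ectopic-beat rejection and zero-phase low-pass filtering.

Ectopic beats are flagged by fitting a local polynomial regression to the
interval-vs-beat-index signal and excluding beats whose residuals exceed a
multiple (default 2) of the residual median absolute deviation.  Smoothing
uses a zero-phase Butterworth low-pass filter applied in the beat-index
domain, where the series is uniformly sampled by construction.

The default pipeline order is spike rejection first, filtering afterwards
on the kept beats: a linear-phase smoother applied to a series still
containing ectopic spikes would smear each spike across its neighbours and
hide it from the MAD rule.  The reverse order is available via
``preprocess(..., order="filter_first")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .recording import RRiRecording

__all__ = [
    "FilterConfig",
    "EctopicConfig",
    "lowpass_zero_phase",
    "remove_ectopic",
    "local_polynomial_trend",
    "mad_outlier_flags",
    "preprocess",
    "MAD_GAUSSIAN_CONSTANT",
]

#: Consistency constant making the MAD estimate sigma under Gaussian noise.
MAD_GAUSSIAN_CONSTANT = 1.4826022185056018


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth low-pass design on the beat-index axis.

    ``cutoff`` is a normalized frequency in (0, 1) relative to the
    beat-index Nyquist (0.5 cycles/beat).  The default (order 3, cutoff
    0.10) suppresses beat-to-beat fluctuation while passing the
    minute-scale exercise/recovery trend.
    """

    order: int = 3
    cutoff: float = 0.10

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not 0 < self.cutoff < 1:
            raise ValueError(f"cutoff must lie in (0, 1), got {self.cutoff}")


@dataclass(frozen=True)
class EctopicConfig:
    """Local-regression / MAD outlier rule.

    ``span`` is the fraction of the series entering each local fit;
    ``mad_multiplier`` the rejection threshold in MAD units (default 2);
    ``mad_scaled`` applies the 1.4826 Gaussian consistency constant so
    "twice the MAD" corresponds to roughly 2 sigma under Gaussian noise.
    """

    span: float = 0.25
    mad_multiplier: float = 2.0
    mad_scaled: bool = True
    degree: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError(f"span must lie in (0, 1], got {self.span}")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be > 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


def lowpass_zero_phase(rec: RRiRecording, cfg: FilterConfig = FilterConfig()) -> RRiRecording:
    """Zero-phase Butterworth low-pass of the kept intervals.

    The filter runs forward then backward (``filtfilt``) so the net phase
    shift is zero; endpoints are handled by reflective padding.  Masked
    beats are left at their original values; beat times are unchanged.
    """
    keep = ~rec.artifact_mask
    x = rec.intervals[keep]
    b, a = butter(cfg.order, cfg.cutoff)
    padlen = 3 * max(len(a), len(b))
    min_len = max(3 * cfg.order + 1, padlen + 1)
    if x.size < min_len:
        raise ValueError(
            f"series too short for zero-phase filtering: {x.size} usable "
            f"beats, need at least {min_len} for order {cfg.order}"
        )
    smoothed = filtfilt(b, a, x, padtype="even")
    out = rec.copy()
    out.intervals[keep] = smoothed
    return out


def local_polynomial_trend(
    y: np.ndarray,
    span: float = 0.25,
    degree: int = 2,
    max_anchors: int = 400,
) -> np.ndarray:
    """Tricube-weighted local polynomial trend of ``y`` vs its index.

    For long series the fit is evaluated at ``max_anchors`` evenly spaced
    anchor indices and linearly interpolated in between; the trend varies
    on a scale much wider than the anchor spacing, so the interpolation
    error is negligible.
    """
    y = np.asarray(y, float)
    n = y.size
    if n < 2 * (degree + 1):
        raise ValueError(f"series too short for local regression: {n} points")
    window = max(int(np.ceil(span * n)), 2 * (degree + 1))
    window = min(window, n)
    x = np.arange(n, dtype=float)
    if n <= max_anchors:
        anchors = x.astype(int)
    else:
        anchors = np.unique(np.linspace(0, n - 1, max_anchors).round().astype(int))
    fitted = np.empty(anchors.size)
    half = window // 2
    for j, i in enumerate(anchors):
        lo = max(0, min(i - half, n - window))
        idx = slice(lo, lo + window)
        dx = x[idx] - x[i]
        dmax = np.abs(dx).max()
        w = (1.0 - np.minimum(np.abs(dx) / (dmax * 1.0001), 1.0) ** 3) ** 3
        sw = np.sqrt(w)
        design = np.vander(dx / dmax, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[j] = coef[0]
    if anchors.size == n:
        return fitted
    return np.interp(x, anchors.astype(float), fitted)


def mad_outlier_flags(
    residuals: np.ndarray, multiplier: float = 2.0, scaled: bool = True
) -> np.ndarray:
    """The MAD rejection rule on a residual vector.

    Flags ``|r| > multiplier * MAD(r)`` (MAD about the residual median,
    optionally scaled by 1.4826).  When the MAD is exactly zero — at
    least half the residuals identical — only nonzero residuals are
    flagged.
    """
    r = np.asarray(residuals, float)
    mad = float(np.median(np.abs(r - np.median(r))))
    if scaled:
        mad *= MAD_GAUSSIAN_CONSTANT
    if mad == 0.0:
        return np.abs(r) > 0.0
    return np.abs(r) > multiplier * mad


def remove_ectopic(rec: RRiRecording, cfg: EctopicConfig = EctopicConfig()):
    """Flag ectopic beats by the local-regression residual / MAD rule.

    Residuals are taken from a single-pass local polynomial fit over the
    currently kept beats.  Beat ``k`` is flagged iff ``|r_k| >
    mad_multiplier * MAD(r)`` (MAD optionally scaled by 1.4826).  When the
    residual MAD is exactly zero, only beats with nonzero residuals are
    flagged.  Flagged beats are excluded (mask set), never interpolated.

    Returns
    -------
    (RRiRecording, ndarray of bool)
        Recording with an updated artifact mask and the full-length mask
        of newly removed beats.
    """
    keep = ~rec.artifact_mask
    if keep.sum() < 20:
        raise ValueError(
            f"too few usable beats for ectopic detection: {int(keep.sum())} < 20"
        )
    y = rec.intervals[keep]
    trend = local_polynomial_trend(y, span=cfg.span, degree=cfg.degree)
    flagged = mad_outlier_flags(
        y - trend, multiplier=cfg.mad_multiplier, scaled=cfg.mad_scaled
    )
    if flagged.all():
        raise ValueError("all beats flagged as ectopic: signal unusable")
    removed_mask = np.zeros(len(rec), bool)
    removed_mask[np.flatnonzero(keep)[flagged]] = True
    out = rec.copy()
    out.artifact_mask |= removed_mask
    return out, removed_mask


def preprocess(
    rec: RRiRecording,
    filter_cfg: FilterConfig = FilterConfig(),
    ectopic_cfg: EctopicConfig = EctopicConfig(),
    order: str = "ectopic_first",
):
    """Full cleaning pass: ectopic rejection and zero-phase smoothing.

    Returns the cleaned recording and a report dict (beat counts, removal
    fraction, config echo).
    """
    if order not in ("ectopic_first", "filter_first"):
        raise ValueError(f"unknown order {order!r}")
    n0 = rec.n_beats
    if order == "ectopic_first":
        cleaned, removed = remove_ectopic(rec, ectopic_cfg)
        cleaned = lowpass_zero_phase(cleaned, filter_cfg)
    else:
        cleaned = lowpass_zero_phase(rec, filter_cfg)
        cleaned, removed = remove_ectopic(cleaned, ectopic_cfg)
    report = {
        "subject_id": rec.subject_id,
        "n_beats": int(n0),
        "n_removed": int(removed.sum()),
        "removal_fraction": float(removed.sum() / max(n0, 1)),
        "order": order,
        "filter": {"order": filter_cfg.order, "cutoff": filter_cfg.cutoff},
        "ectopic": {
            "span": ectopic_cfg.span,
            "mad_multiplier": ectopic_cfg.mad_multiplier,
            "mad_scaled": ectopic_cfg.mad_scaled,
            "degree": ectopic_cfg.degree,
        },
    }
    return cleaned, report
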