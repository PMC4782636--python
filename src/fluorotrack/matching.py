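"""Exhaustive-search integer-pixel template matching.

Used twice per frame: to register the background reference against the raw
frame, and to register the tumor reference against the background-subtracted
tumor estimate.  Similarity is scored only over jointly valid pixels (and an
optional ROI), averaged so that candidate displacements with different
amounts of in-frame overlap remain comparable.  Both metrics are oriented so
that *lower is better*: SSD is the mean squared difference, NCC is the
negated normalized cross-correlation.

The exhaustive search is evaluated with an FFT-based masked correlation that
computes the exact per-displacement sums over jointly valid pixels for every
lag at once; :func:`match_score` evaluates the same quantity directly for a
single displacement and serves as the independent slow path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .image_model import Displacement, IntensityImage, Region, shift_image

__all__ = [
    "MatchConfig",
    "RegistrationError",
    "match_score",
    "best_displacement",
    "match_background",
    "match_tumor",
]

_EPS = 1e-12
# relative tolerance for grouping numerically tied scores before tie-breaking
_TIE_RTOL = 1e-6


class RegistrationError(RuntimeError):
    """Raised when no candidate displacement has any valid overlap."""


@dataclass
class MatchConfig:
    """Configuration of the exhaustive displacement search.

    search_radius
        Half-width of the square search window (pixels); the window holds
        ``(2r+1)**2`` candidates centered on the warm-start displacement.
    roi
        Optional region restricting the scored pixels (target coordinates);
        ``None`` scores the whole frame.
    metric
        ``"ssd"`` (mean squared difference) or ``"ncc"`` (negated normalized
        cross-correlation); both minimized.
    min_overlap
        Minimum number of jointly valid pixels for a candidate to be scored.
    """

    search_radius: int = 20
    roi: Region | None = None
    metric: Literal["ssd", "ncc"] = "ssd"
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.search_radius < 0:
            raise ValueError("search_radius must be >= 0")
        if self.metric not in ("ssd", "ncc"):
            raise ValueError("metric must be 'ssd' or 'ncc'")


def _target_mask(target: IntensityImage, cfg: MatchConfig) -> np.ndarray:
    mask = target.valid
    if cfg.roi is not None:
        if cfg.roi.mask.shape != target.shape:
            raise ValueError("roi shape must match target")
        mask = mask & cfg.roi.mask
    return mask


def match_score(
    reference: IntensityImage,
    target: IntensityImage,
    d: Displacement,
    cfg: MatchConfig,
) -> float:
    """Score a single candidate displacement (lower is better).

    Shifts ``reference`` by ``d`` and compares it with ``target`` over the
    jointly valid (and in-ROI) pixels.  Returns ``+inf`` when fewer than
    ``cfg.min_overlap`` pixels overlap.
    """
    if reference.shape != target.shape:
        raise ValueError("reference and target must share shape")
    shifted = shift_image(reference, d)
    joint = shifted.valid & _target_mask(target, cfg)
    n = int(joint.sum())
    if n < max(cfg.min_overlap, 1):
        return float("inf")
    r = shifted.values[joint]
    t = target.values[joint]
    if cfg.metric == "ssd":
        return float(np.mean((r - t) ** 2))
    rm, tm = r - r.mean(), t - t.mean()
    den = np.sqrt(float(rm @ rm) * float(tm @ tm))
    if den <= _EPS:
        return 0.0
    return -float(rm @ tm) / den


def _conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # full cross-correlation table: result[m-1+v, n-1+u] = sum a(y,x) b(y-v, x-u)
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def _score_map(
    reference: IntensityImage, target: IntensityImage, cfg: MatchConfig
) -> tuple[np.ndarray, int, int]:
    """Masked SSD/NCC score for every lag, via FFT correlation sums."""
    R, T = reference.values, target.values
    Rm = reference.valid.astype(np.float64)
    Tm = _target_mask(target, cfg).astype(np.float64)
    Rv, Tv = R * Rm, T * Tm

    N = np.rint(_conv(Tm, Rm))
    s_rr = _conv(Tm, Rv * Rv)
    s_tt = _conv(Tv * Tv, Rm)
    s_rt = _conv(Tv, Rv)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cfg.metric == "ssd":
            score = (s_rr - 2.0 * s_rt + s_tt) / N
        else:
            s_r = _conv(Tm, Rv)
            s_t = _conv(Tv, Rm)
            num = s_rt - s_r * s_t / N
            var_r = np.maximum(s_rr - s_r * s_r / N, 0.0)
            var_t = np.maximum(s_tt - s_t * s_t / N, 0.0)
            den = np.sqrt(var_r * var_t)
            score = np.where(den > _EPS, -num / den, 0.0)
    score = np.where(N >= max(cfg.min_overlap, 1), score, np.inf)
    m, n = target.shape
    return score, m, n


def best_displacement(
    reference: IntensityImage,
    target: IntensityImage,
    cfg: MatchConfig,
    center: Displacement = Displacement(0, 0),
) -> Displacement:
    """Exhaustive minimizer over the square window centered on ``center``.

    Ties (scores equal within a small relative tolerance) are broken by the
    smallest Euclidean distance to ``center``, then lexicographically by
    ``(v, u)``.
    """
    if reference.shape != target.shape:
        raise ValueError("reference and target must share shape")
    score, m, n = _score_map(reference, target, cfg)
    r = cfg.search_radius
    us = np.arange(center.u - r, center.u + r + 1)
    vs = np.arange(center.v - r, center.v + r + 1)
    # lags beyond the full-correlation table have no overlap at all
    uu = us[(us >= -(n - 1)) & (us <= n - 1)]
    vv = vs[(vs >= -(m - 1)) & (vs <= m - 1)]
    if uu.size == 0 or vv.size == 0:
        raise RegistrationError("search window entirely out of range")
    sub = score[np.ix_(m - 1 + vv, n - 1 + uu)]
    smin = np.min(sub)
    if not np.isfinite(smin):
        raise RegistrationError("no candidate displacement has valid overlap")
    tol = _TIE_RTOL * max(1.0, abs(smin))
    tie_v, tie_u = np.nonzero(sub <= smin + tol)
    cand_u = uu[tie_u]
    cand_v = vv[tie_v]
    dist2 = (cand_u - center.u) ** 2 + (cand_v - center.v) ** 2
    order = np.lexsort((cand_u, cand_v, dist2))
    k = order[0]
    return Displacement(int(cand_u[k]), int(cand_v[k]))


def match_background(
    frame: IntensityImage,
    bg_ref: IntensityImage,
    cfg: MatchConfig,
    prev: Displacement = Displacement(0, 0),
) -> Displacement:
    """Register the background reference against the raw frame.

    The ROI (whole frame by default) is assumed large relative to the tumor,
    so the tumor's contribution to the score is negligible.
    """
    return best_displacement(bg_ref, frame, cfg, center=prev)


def match_tumor(
    tumor_est: IntensityImage,
    tumor_ref: IntensityImage,
    cfg: MatchConfig,
    prev: Displacement = Displacement(0, 0),
) -> Displacement:
    """Register the tumor reference against the background-subtracted estimate.

    Only pixels where the shifted tumor reference is valid *and positive* are
    scored, so empty surroundings of the compact reference do not dilute the
    metric.
    """
    support = tumor_ref.valid & (tumor_ref.values > 0)
    if not support.any():
        raise RegistrationError("tumor reference has empty support")
    masked_ref = IntensityImage(tumor_ref.values, support, tumor_ref.spacing_mm)
    return best_displacement(masked_ref, tumor_est, cfg, center=prev)
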