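"""Dynamic decomposition of a fluoroscopic sequence into tumor + background.

Each frame I(t) is modelled as the superimposition of a translating tumor
component and a translating background component, each produced by warping a
time-invariant *reference* image:

    I(x, y, t) = I_ar(x - u(t), y - v(t)) + I_br(x - u_b(t), y - v_b(t))

The single-frame split is ill posed; accumulating the constraint over the
sequence regularizes it.  Per frame the solver (i) registers the background
reference against the frame, (ii) registers the tumor reference against the
background-subtracted estimate, then (iii) runs a short inner loop that
updates the tumor reference by steepest descent on the quadratic residual
objective J(t) = 1/2 * sum(e^2) and rewrites the background reference exactly
so the recomposition error returns to zero.  The tracked position is the
center of mass of the binarized warped tumor component, differenced against
the frame-1 reference position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import (
    Displacement,
    IntensityImage,
    LostTargetError,
    Region,
    binarize,
    center_of_mass,
    shift_image,
)
from .matching import MatchConfig, RegistrationError, match_background, match_tumor

__all__ = [
    "SolverConfig",
    "DecompositionState",
    "TrackingResult",
    "initialize_references",
    "residual",
    "objective",
    "update_tumor_reference",
    "update_background_reference",
    "estimate_position",
    "track_sequence",
]


@dataclass
class SolverConfig:
    """Solver parameters for the per-frame decomposition update.

    eta
        Steepest-descent step size on the tumor reference.  Default 0.7: large
        enough that the flat constant initialization acquires the true tumor
        contrast within a few motion events, which the sequential scheme needs
        in order to lock on before unexplained motion is absorbed into the
        background reference; small step sizes cannot bootstrap (see the
        methods note).
    n_inner
        Maximum inner iterations K per frame (default 2).  Because the
        background update is exact, the residual is zero from the second
        iteration on; K mainly matters for alternative background updates.
    rel_threshold
        Relative binarization threshold for the centroid readout, as a
        fraction of the maximum intensity of the warped tumor component.
    clamp_nonnegative
        Clamp the tumor reference at zero after each update (the tumor is an
        additive attenuation component).
    support_dilation_px
        Tumor-reference pixels may receive mass only within this dilation
        band of the current positive support, keeping the reference compact.
    adaptive_eta
        Optional safeguard: if an update increased J, retry that frame's
        update with the step halved.
    """

    eta: float = 0.7
    n_inner: int = 2
    rel_threshold: float = 0.5
    clamp_nonnegative: bool = True
    support_dilation_px: int = 3
    adaptive_eta: bool = False

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if self.n_inner < 1:
            raise ValueError("n_inner must be >= 1")
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must lie in (0, 1)")


@dataclass
class DecompositionState:
    """Mutable solver state: both references and the current displacements."""

    tumor_ref: IntensityImage
    bg_ref: IntensityImage
    d_tumor: Displacement = Displacement(0, 0)
    d_bg: Displacement = Displacement(0, 0)
    frame_index: int = 1
    ref_centroid: tuple[float, float] = (0.0, 0.0)


@dataclass
class TrackingResult:
    """Per-frame trajectory plus the final decomposition.

    Displacements are relative to the frame-1 reference position.  ``u_px`` /
    ``v_px`` come from the sub-pixel centroid readout; ``match_*`` are the
    integer matcher outputs.
    """

    u_px: np.ndarray
    v_px: np.ndarray
    u_mm: np.ndarray
    v_mm: np.ndarray
    match_u_px: np.ndarray
    match_v_px: np.ndarray
    bg_u_px: np.ndarray
    bg_v_px: np.ndarray
    objective_trace: list[list[float]]
    tumor_ref: IntensityImage
    bg_ref: IntensityImage
    spacing_mm: float
    method_label: str = "dynamic-decomposition"
    failure: tuple[int, str] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.u_px)

    def displacements_px(self) -> np.ndarray:
        return np.column_stack([self.u_px, self.v_px])


def initialize_references(
    first_frame: IntensityImage, outline: Region, I0: float = 1.0
) -> DecompositionState:
    """Initialize both references from the first frame and a manual outline.

    The tumor reference is the constant ``I0`` inside the outline and 0
    outside; the background reference is the first frame minus that initial
    tumor image.  The tumor location in the first frame is the reference
    position with zero displacement.
    """
    if outline.mask.shape != first_frame.shape:
        raise ValueError("outline shape must match frame")
    if outline.n_pixels == 0:
        raise ValueError("initial outline is empty")
    if I0 <= 0:
        warnings.warn(
            "I0 <= 0 gives a tumor reference with empty support; matching "
            "cannot lock on",
            stacklevel=2,
        )
    tumor_vals = np.where(outline.mask, float(I0), 0.0)
    tumor_ref = IntensityImage(tumor_vals, None, first_frame.spacing_mm)
    bg_ref = IntensityImage(
        first_frame.values - tumor_vals, first_frame.valid.copy(), first_frame.spacing_mm
    )
    state = DecompositionState(tumor_ref=tumor_ref, bg_ref=bg_ref)
    if I0 > 0:
        state.ref_centroid = center_of_mass(binarize(tumor_ref, 0.5))
    return state


def residual(frame: IntensityImage, state: DecompositionState) -> IntensityImage:
    """Estimation error e(t) = warped tumor ref - (frame - warped background ref)."""
    ta = shift_image(state.tumor_ref, state.d_tumor)
    tb = shift_image(state.bg_ref, state.d_bg)
    valid = ta.valid & tb.valid & frame.valid
    vals = np.where(valid, ta.values - (frame.values - tb.values), 0.0)
    return IntensityImage(vals, valid, frame.spacing_mm)


def objective(e: IntensityImage) -> float:
    """Quadratic objective J = 1/2 * sum of squared residuals over valid pixels."""
    return 0.5 * float(np.sum(e.values[e.valid] ** 2))


def update_tumor_reference(
    state: DecompositionState, e: IntensityImage, cfg: SolverConfig
) -> DecompositionState:
    """One steepest-descent step on the tumor reference.

    Differentiating J through the warp places the gradient at the *reference*
    coordinates: the residual is shifted back by the negated tumor
    displacement before scaling by -eta.  Updates are confined to a dilation
    band around the current positive support, and the reference is clamped
    non-negative when configured.
    """
    back = shift_image(e, -state.d_tumor)
    upd = back.valid.copy()
    if cfg.support_dilation_px >= 0:
        support = state.tumor_ref.values > 0
        if support.any():
            band = ndimage.binary_dilation(
                support, iterations=max(cfg.support_dilation_px, 1)
            )
            upd &= band
    new_vals = state.tumor_ref.values.copy()
    new_vals[upd] -= cfg.eta * back.values[upd]
    if cfg.clamp_nonnegative:
        np.maximum(new_vals, 0.0, out=new_vals)
    state.tumor_ref = IntensityImage(
        new_vals, state.tumor_ref.valid, state.tumor_ref.spacing_mm
    )
    return state


def update_background_reference(
    state: DecompositionState, frame: IntensityImage
) -> DecompositionState:
    """Exact background rewrite: keep the recomposition error at zero.

    Every frame pixel jointly valid with the warped tumor reference writes
    ``frame - warped_tumor`` back to its background-reference location;
    reference pixels with no corresponding in-frame location keep their
    previous values (and their previous validity).
    """
    ta = shift_image(state.tumor_ref, state.d_tumor)
    diff_valid = frame.valid & ta.valid
    diff = IntensityImage(
        np.where(diff_valid, frame.values - ta.values, 0.0),
        diff_valid,
        frame.spacing_mm,
    )
    back = shift_image(diff, -state.d_bg)
    new_vals = np.where(back.valid, back.values, state.bg_ref.values)
    new_valid = state.bg_ref.valid | back.valid
    state.bg_ref = IntensityImage(new_vals, new_valid, state.bg_ref.spacing_mm)
    return state


def estimate_position(
    state: DecompositionState, cfg: SolverConfig, spacing_mm: float | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Centroid readout of the warped, binarized tumor component.

    Returns ``((u_px, v_px), (u_mm, v_mm))`` relative to the frame-1
    reference centroid.
    """
    if spacing_mm is None:
        spacing_mm = state.tumor_ref.spacing_mm
    ta = shift_image(state.tumor_ref, state.d_tumor)
    region = binarize(ta, cfg.rel_threshold)
    if not region.mask.any():
        raise LostTargetError("binarized tumor component is empty")
    xc, yc = center_of_mass(region)
    u = xc - state.ref_centroid[0]
    v = yc - state.ref_centroid[1]
    return (u, v), (u * spacing_mm, v * spacing_mm)


def _frame_step(
    frame: IntensityImage,
    state: DecompositionState,
    cfg: SolverConfig,
    mcfg: MatchConfig,
) -> list[float]:
    """Run one full frame update in place; returns the inner J trace."""
    state.d_bg = match_background(frame, state.bg_ref, mcfg, prev=state.d_bg)
    tb = shift_image(state.bg_ref, state.d_bg)
    est = IntensityImage(
        np.where(frame.valid & tb.valid, frame.values - tb.values, 0.0),
        frame.valid & tb.valid,
        frame.spacing_mm,
    )
    state.d_tumor = match_tumor(est, state.tumor_ref, mcfg, prev=state.d_tumor)

    j_trace: list[float] = []
    for _ in range(cfg.n_inner):
        e = residual(frame, state)
        j_before = objective(e)
        j_trace.append(j_before)
        if cfg.adaptive_eta:
            saved = state.tumor_ref.copy()
            update_tumor_reference(state, e, cfg)
            if objective(residual(frame, state)) > j_before:
                state.tumor_ref = saved
                half = SolverConfig(
                    eta=cfg.eta / 2.0,
                    n_inner=cfg.n_inner,
                    rel_threshold=cfg.rel_threshold,
                    clamp_nonnegative=cfg.clamp_nonnegative,
                    support_dilation_px=cfg.support_dilation_px,
                )
                update_tumor_reference(state, e, half)
        else:
            update_tumor_reference(state, e, cfg)
        update_background_reference(state, frame)
    return j_trace


def track_sequence(
    frames: list[IntensityImage],
    outline: Region,
    cfg: SolverConfig | None = None,
    mcfg: MatchConfig | None = None,
    I0: float = 1.0,
) -> TrackingResult:
    """Track the tumor through a sequence by recursive decomposition.

    On a registration failure or lost target at frame t the result covers
    frames 1..t-1 and carries an error record instead of raising.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    cfg = cfg or SolverConfig()
    mcfg = mcfg or MatchConfig()
    spacing = frames[0].spacing_mm
    state = initialize_references(frames[0], outline, I0=I0)

    u_px: list[float] = []
    v_px: list[float] = []
    match_u: list[int] = []
    match_v: list[int] = []
    bg_u: list[int] = []
    bg_v: list[int] = []
    j_all: list[list[float]] = []
    failure: tuple[int, str] | None = None

    for t, frame in enumerate(frames, start=1):
        if frame.shape != frames[0].shape:
            raise ValueError(f"frame {t} shape {frame.shape} differs from frame 1")
        state.frame_index = t
        try:
            j_all.append(_frame_step(frame, state, cfg, mcfg))
            (du, dv), _ = estimate_position(state, cfg, spacing)
        except (RegistrationError, LostTargetError) as exc:
            failure = (t, str(exc))
            break
        u_px.append(du)
        v_px.append(dv)
        match_u.append(state.d_tumor.u)
        match_v.append(state.d_tumor.v)
        bg_u.append(state.d_bg.u)
        bg_v.append(state.d_bg.v)

    u = np.asarray(u_px)
    v = np.asarray(v_px)
    return TrackingResult(
        u_px=u,
        v_px=v,
        u_mm=u * spacing,
        v_mm=v * spacing,
        match_u_px=np.asarray(match_u, dtype=int),
        match_v_px=np.asarray(match_v, dtype=int),
        bg_u_px=np.asarray(bg_u, dtype=int),
        bg_v_px=np.asarray(bg_v, dtype=int),
        objective_trace=j_all,
        tumor_ref=state.tumor_ref,
        bg_ref=state.bg_ref,
        spacing_mm=spacing,
        failure=failure,
    )
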