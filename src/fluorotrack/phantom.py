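"""Synthetic chest-phantom generator with exported ground truth.

Emulates a fluoroscopic phantom experiment: a static (or slowly translating)
structured background — rib-like bands, vessel-like curves and a smooth
gradient — additively superimposed with a compact tumor blob that translates
along a quasi-periodic respiratory trace.  Defaults render 100 frames of
600 x 250 pixels at 0.26 mm/pixel sampled every 0.033 s, with a 9.42 mm
peak-to-peak craniocaudal excursion and a smaller lateral component.

The real-valued motion trace is rounded to integer pixels at render time
(matching the integer warp model); both traces are exported so sub-pixel
tracking error against the continuous trace is measurable.  The rib bands of
the default background exceed the tumor's peak intensity inside the tumor's
motion corridor, which is exactly the condition under which direct template
matching on the raw frames locks onto background structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import Displacement, IntensityImage, Region, binarize, shift_image

__all__ = [
    "TumorSpec",
    "BackgroundSpec",
    "MotionSpec",
    "PhantomConfig",
    "PhantomGroundTruth",
    "make_motion_trace",
    "make_tumor_image",
    "make_confounded_background",
    "render_sequence",
    "rough_outline",
]


@dataclass
class TumorSpec:
    """Compact blob superimposed on the background.

    ``center_xy`` defaults to the frame center; radii are the ellipse
    half-axes in pixels along (x, y); ``profile`` is a hard ``disk``/ellipse
    or a ``smoothed`` ellipse (Gaussian-blurred indicator, ``smooth_px``).
    """

    center_xy: tuple[float, float] | None = None
    radii_px: tuple[float, float] = (12.0, 9.0)
    peak: float = 2.5
    profile: str = "disk"  # "disk" | "smoothed"
    smooth_px: float = 1.0


@dataclass
class BackgroundSpec:
    """Parametric chest-like clutter: base level + gradient + bands + vessels.

    Intensities are on the same arbitrary attenuation scale as the tumor: the
    constant tumor initialization is I0 = 1, and the tumor peak (default 2.5)
    sits within a small factor of it, which the sequential decomposition
    needs in order to bootstrap (see the methods note).  The rib-like bands
    exceed the tumor peak so that raw-frame matching is confounded.
    """

    base: float = 0.5
    gradient: float = 0.3
    n_bands: int = 4
    band_contrast: float = 3.0
    band_width_px: float = 6.0
    band_angle_deg: float = 8.0
    n_vessels: int = 3
    vessel_contrast: float = 0.12
    vessel_width_px: float = 3.0
    # fine-scale static anatomical texture (lung markings); this is what makes
    # whole-frame background registration insensitive to the small tumor
    texture_contrast: float = 0.04
    texture_corr_px: float = 1.5


@dataclass
class MotionSpec:
    """Quasi-periodic 2-D trace: per-axis peak-to-peak amplitude in mm.

    The craniocaudal (y) waveform defaults to sin^4 (longer end-exhale
    dwell), the lateral (x) one to a plain sine; a recorded trace can be
    supplied as a CSV with columns ``u_mm,v_mm`` via ``trace_csv``.
    """

    p2p_mm: tuple[float, float] = (3.0, 9.42)  # (lateral x, craniocaudal y)
    period_s: float = 2.5
    waveform: tuple[str, str] = ("sin", "sin4")  # per axis; or "csv"
    phase_rad: tuple[float, float] = (0.0, 0.0)
    drift_mm_per_s: tuple[float, float] = (0.0, 0.0)
    # measured-trace jitter (cardiac motion + marker localization noise), as in
    # traces recorded by a real-time tracking system; part of the ground truth
    jitter_sd_mm: float = 0.0
    trace_csv: str | None = None


@dataclass
class PhantomConfig:
    frame_shape: tuple[int, int] = (250, 600)  # (rows m, cols n)
    spacing_mm: float = 0.26
    n_frames: int = 100
    dt_s: float = 0.033
    tumor: TumorSpec = field(default_factory=TumorSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    bg_motion_p2p_mm: tuple[float, float] = (0.0, 0.0)
    bg_motion_period_s: float = 10.0
    noise_sd: float = 0.01
    seed: int = 0

    def tumor_center(self) -> tuple[float, float]:
        if self.tumor.center_xy is not None:
            return self.tumor.center_xy
        m, n = self.frame_shape
        return (n / 2.0, m / 2.0)


@dataclass
class PhantomGroundTruth:
    """True components and the true displacement trace of a rendered sequence."""

    tumor: IntensityImage
    background: IntensityImage
    trace_px: np.ndarray  # (T, 2) real-valued (u, v) in pixels
    trace_int_px: np.ndarray  # (T, 2) integer trace actually rendered
    trace_mm: np.ndarray
    config: PhantomConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(1, len(self.trace_px) + 1),
                "u_px": self.trace_px[:, 0],
                "v_px": self.trace_px[:, 1],
                "u_mm": self.trace_mm[:, 0],
                "v_mm": self.trace_mm[:, 1],
            }
        )


def _waveform(name: str, t: np.ndarray, period: float, phase: float) -> np.ndarray:
    w = 2.0 * np.pi * t / period + phase
    if name == "sin":
        return np.sin(w)
    if name == "sin4":
        return np.sin(w / 2.0) ** 4
    raise ValueError(f"unknown waveform {name!r}")


def make_motion_trace(cfg: PhantomConfig) -> np.ndarray:
    """Real-valued per-frame displacement (u, v) in pixels, frame 1 at (0, 0).

    The trace is rescaled so the sampled peak-to-peak range per axis equals
    the configured value exactly; a zero amplitude yields a zero trace.
    """
    mo = cfg.motion
    T = cfg.n_frames
    t = np.arange(T) * cfg.dt_s
    if mo.trace_csv is not None or "csv" in mo.waveform:
        if mo.trace_csv is None:
            raise ValueError("waveform 'csv' requires motion.trace_csv")
        df = pd.read_csv(mo.trace_csv)
        if not {"u_mm", "v_mm"}.issubset(df.columns):
            raise ValueError("recorded trace CSV must have columns u_mm,v_mm")
        if len(df) < T:
            raise ValueError(
                f"recorded trace has {len(df)} rows, need {T}"
            )
        mm = df[["u_mm", "v_mm"]].to_numpy(dtype=float)[:T]
        mm = mm - mm[0]
        return mm / cfg.spacing_mm

    mm = np.zeros((T, 2))
    for ax in range(2):
        p2p = mo.p2p_mm[ax]
        if p2p <= 0:
            continue
        s = _waveform(mo.waveform[ax], t, mo.period_s, mo.phase_rad[ax])
        s = s + mo.drift_mm_per_s[ax] * t
        rng = s.max() - s.min()
        if rng <= 0:
            continue
        s = s * (p2p / rng)
        mm[:, ax] = s - s[0]
    if mo.jitter_sd_mm > 0:
        jrng = np.random.default_rng(cfg.seed + 2)
        jit = jrng.normal(0.0, mo.jitter_sd_mm, size=mm.shape)
        jit[0] = 0.0
        mm = mm + jit
    return mm / cfg.spacing_mm


def make_tumor_image(cfg: PhantomConfig) -> IntensityImage:
    """Full-frame image of the tumor blob at its reference position."""
    m, n = cfg.frame_shape
    cx, cy = cfg.tumor_center()
    rx, ry = cfg.tumor.radii_px
    yy, xx = np.mgrid[0:m, 0:n]
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    vals = np.where(inside, cfg.tumor.peak, 0.0)
    if cfg.tumor.profile == "smoothed":
        vals = ndimage.gaussian_filter(vals, cfg.tumor.smooth_px)
        vals[vals < 1e-3 * cfg.tumor.peak] = 0.0
    elif cfg.tumor.profile != "disk":
        raise ValueError(f"unknown tumor profile {cfg.tumor.profile!r}")
    return IntensityImage(vals, None, cfg.spacing_mm)


def make_confounded_background(cfg: PhantomConfig) -> IntensityImage:
    """Structured background with rib-like bands crossing the tumor corridor.

    At least one band center is placed inside the tumor's craniocaudal motion
    corridor, and with the default contrasts the local background excursion
    there exceeds the tumor's peak intensity, confounding direct matching.
    """
    m, n = cfg.frame_shape
    bg = cfg.background
    rng = np.random.default_rng(cfg.seed + 1)
    yy, xx = np.mgrid[0:m, 0:n].astype(float)

    vals = bg.base + bg.gradient * (xx / max(n - 1, 1) + yy / max(m - 1, 1)) / 2.0

    cx, cy = cfg.tumor_center()
    half_corridor = (cfg.motion.p2p_mm[1] / cfg.spacing_mm) / 2.0
    theta = np.deg2rad(bg.band_angle_deg)
    if bg.n_bands > 0 and bg.band_contrast > 0:
        # band centers spread over the frame height, one pinned near the tumor
        centers = list(np.linspace(0.15 * m, 0.85 * m, bg.n_bands))
        centers[int(np.argmin(np.abs(np.asarray(centers) - cy)))] = cy + rng.uniform(
            -0.5 * half_corridor, 0.5 * half_corridor
        )
        for i, yc in enumerate(centers):
            tilt = theta * (1 if i % 2 == 0 else -1)
            dist = (yy - yc) * np.cos(tilt) - (xx - n / 2.0) * np.sin(tilt)
            vals += bg.band_contrast * np.exp(-0.5 * (dist / bg.band_width_px) ** 2)
    if bg.n_vessels > 0 and bg.vessel_contrast > 0:
        for _ in range(bg.n_vessels):
            x0 = rng.uniform(0.1 * n, 0.9 * n)
            amp = rng.uniform(5.0, 20.0)
            freq = rng.uniform(1.0, 3.0)
            path = x0 + amp * np.sin(2 * np.pi * freq * yy / m)
            vals += bg.vessel_contrast * np.exp(
                -0.5 * ((xx - path) / bg.vessel_width_px) ** 2
            )
    if bg.texture_contrast > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((m, n)), bg.texture_corr_px)
        tex /= max(tex.std(), 1e-12)
        vals += bg.texture_contrast * tex
        vals -= min(vals.min(), 0.0)  # keep attenuation non-negative
    return IntensityImage(vals, None, cfg.spacing_mm)


def render_sequence(
    cfg: PhantomConfig | None = None,
) -> tuple[list[IntensityImage], PhantomGroundTruth]:
    """Render the phantom sequence and its ground truth.

    frame(t) = background (+ optional background shift) + tumor shifted by
    the rounded trace + Gaussian noise.  Raises if the tumor leaves the frame
    entirely at any time, naming the offending frame.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    trace = make_motion_trace(cfg)
    trace_int = np.rint(trace).astype(int)
    tumor = make_tumor_image(cfg)
    background = make_confounded_background(cfg)

    bg_trace_int = np.zeros_like(trace_int)
    if any(a > 0 for a in cfg.bg_motion_p2p_mm):
        bg_cfg = PhantomConfig(
            frame_shape=cfg.frame_shape,
            spacing_mm=cfg.spacing_mm,
            n_frames=cfg.n_frames,
            dt_s=cfg.dt_s,
            motion=MotionSpec(
                p2p_mm=cfg.bg_motion_p2p_mm,
                period_s=cfg.bg_motion_period_s,
                waveform=("sin", "sin"),
            ),
        )
        bg_trace_int = np.rint(make_motion_trace(bg_cfg)).astype(int)

    frames: list[IntensityImage] = []
    for t in range(cfg.n_frames):
        d = Displacement(int(trace_int[t, 0]), int(trace_int[t, 1]))
        shifted = shift_image(tumor, d)
        if not (shifted.values > 0).any():
            raise ValueError(f"tumor left the frame entirely at frame {t + 1}")
        bg_t = background
        if bg_trace_int[t].any():
            db = Displacement(int(bg_trace_int[t, 0]), int(bg_trace_int[t, 1]))
            bg_t = shift_image(background, db)
        vals = bg_t.values + shifted.values
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, size=vals.shape)
        frames.append(IntensityImage(vals, bg_t.valid.copy(), cfg.spacing_mm))

    truth = PhantomGroundTruth(
        tumor=tumor,
        background=background,
        trace_px=trace,
        trace_int_px=trace_int,
        trace_mm=trace * cfg.spacing_mm,
        config=cfg,
    )
    return frames, truth


def rough_outline(truth: PhantomGroundTruth, dilate_px: int = 4) -> Region:
    """Oversized initial outline: the true tumor support dilated by a few px.

    Mimics a rough manual contour drawn around the tumor on the first frame.
    """
    support = binarize(truth.tumor, 0.5).mask
    if dilate_px > 0:
        support = ndimage.binary_dilation(support, iterations=dilate_px)
    return Region(support)
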