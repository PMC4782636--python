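"""Tracking and extraction error metrics, plus the no-decomposition baseline.

Two metrics: the mean Euclidean tracking error e_p (mm) between an estimated
and a true displacement trace, and the quadratic extraction error
J_a = 1/2 * sum((extracted - truth)^2) between the extracted tumor component
and the true tumor image.  The baseline tracker applies the same exhaustive
template matching directly to the raw frames, with the frame-1 patch inside
the outline's bounding box as the template — no decomposition — and serves
as the comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import TrackingResult
from .image_model import Displacement, IntensityImage, Region
from .matching import MatchConfig, best_displacement

__all__ = [
    "ErrorReport",
    "tracking_error_ep",
    "per_frame_error_mm",
    "extraction_error_Ja",
    "baseline_track",
    "compare_report",
]


@dataclass
class ErrorReport:
    """Per-sequence tracking error summary for one method."""

    e_p_mm: float
    per_frame_error_mm: np.ndarray
    method_label: str = ""
    case_label: str = ""
    J_a_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_frame_error_mm = np.asarray(self.per_frame_error_mm, dtype=float)
        if len(self.per_frame_error_mm) and not np.isclose(
            self.e_p_mm, self.per_frame_error_mm.mean()
        ):
            raise ValueError("e_p_mm must equal the mean per-frame error")


def _as_trace(trace) -> np.ndarray:
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("trace must be an (T, 2) array of (u, v)")
    return arr


def per_frame_error_mm(measured, truth, spacing_mm: float) -> np.ndarray:
    """Euclidean distance per frame between two pixel traces, in mm."""
    a, b = _as_trace(measured), _as_trace(truth)
    if len(a) != len(b):
        raise ValueError(f"trace length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("traces must have at least one frame")
    return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1]) * spacing_mm


def tracking_error_ep(measured, truth, spacing_mm: float) -> float:
    """Mean Euclidean tracking error e_p over the sequence, in mm."""
    return float(per_frame_error_mm(measured, truth, spacing_mm).mean())


def extraction_error_Ja(
    extracted: IntensityImage, truth: IntensityImage, per_pixel: bool = False
) -> float:
    """Quadratic extraction error between tumor component and ground truth.

    J_a = 1/2 * sum((extracted - truth)^2) over jointly valid pixels;
    divided by the pixel count when ``per_pixel`` is true.
    """
    if extracted.shape != truth.shape:
        raise ValueError("shape mismatch")
    joint = extracted.valid & truth.valid
    diff = extracted.values[joint] - truth.values[joint]
    j = 0.5 * float(diff @ diff)
    if per_pixel:
        n = int(joint.sum())
        if n == 0:
            raise ValueError("no jointly valid pixels")
        j /= n
    return j


def baseline_track(
    frames: list[IntensityImage],
    outline: Region,
    mcfg: MatchConfig | None = None,
) -> TrackingResult:
    """Direct template matching on the raw frames, without decomposition.

    The template is the raw frame-1 patch inside the bounding box of the
    outline; each frame is matched against it with the search warm-started at
    the previous displacement.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if outline.mask.shape != frames[0].shape:
        raise ValueError("outline shape must match frames")
    rows, cols = np.nonzero(outline.mask)
    if rows.size == 0:
        raise ValueError("initial outline is empty")
    mcfg = mcfg or MatchConfig()
    bbox = np.zeros(frames[0].shape, dtype=bool)
    bbox[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1] = True
    template = IntensityImage(
        frames[0].values, frames[0].valid & bbox, frames[0].spacing_mm
    )
    spacing = frames[0].spacing_mm
    prev = Displacement(0, 0)
    us, vs = [], []
    for frame in frames:
        prev = best_displacement(template, frame, mcfg, center=prev)
        us.append(prev.u)
        vs.append(prev.v)
    u = np.asarray(us, dtype=float)
    v = np.asarray(vs, dtype=float)
    zeros = np.zeros(len(frames), dtype=int)
    return TrackingResult(
        u_px=u,
        v_px=v,
        u_mm=u * spacing,
        v_mm=v * spacing,
        match_u_px=u.astype(int),
        match_v_px=v.astype(int),
        bg_u_px=zeros,
        bg_v_px=zeros.copy(),
        objective_trace=[],
        tumor_ref=template,
        bg_ref=template,
        spacing_mm=spacing,
        method_label="template-matching (no decomposition)",
    )


def compare_report(reports: list[ErrorReport]) -> pd.DataFrame:
    """Per-case and mean +/- SD summary table, one row per method.

    The SD column uses the n-1 (sample) formula.  The table is
    CSV-serializable: columns are the case labels followed by ``mean`` and
    ``sd``.
    """
    if len(reports) == 0:
        raise ValueError("need at least one report")
    by_method: dict[str, list[ErrorReport]] = {}
    for r in reports:
        by_method.setdefault(r.method_label, []).append(r)
    rows = {}
    all_cases: list[str] = []
    for label, reps in by_method.items():
        cases = {}
        for i, r in enumerate(reps, start=1):
            name = r.case_label or f"case{i}"
            cases[name] = r.e_p_mm
            if name not in all_cases:
                all_cases.append(name)
        vals = np.array(list(cases.values()), dtype=float)
        cases["mean"] = float(vals.mean())
        cases["sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows[label] = cases
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=all_cases + ["mean", "sd"])
    df.index.name = "method"
    return df
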