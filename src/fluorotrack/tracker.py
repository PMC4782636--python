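"""Model / results interface over the decomposition and baseline trackers.

``DynamicDecompositionTracker`` and ``TemplateMatchingTracker`` are built
from a frame sequence plus an initial outline; ``fit()`` runs the tracker
and returns a :class:`TrackingResults` carrying the per-frame trajectory,
the objective trace, the final references, a ``summary()`` table and
plotting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation
from .decomposition import SolverConfig, TrackingResult, track_sequence
from .image_model import IntensityImage, Region
from .matching import MatchConfig

__all__ = ["DynamicDecompositionTracker", "TemplateMatchingTracker", "TrackingResults"]


class TrackingResults:
    """Fitted tracking trajectory with diagnostics.

    Attributes
    ----------
    result : TrackingResult
        The underlying per-frame records.
    """

    def __init__(self, result: TrackingResult, model) -> None:
        self.result = result
        self.model = model

    @property
    def n_frames(self) -> int:
        return self.result.n_frames

    @property
    def displacements_px(self) -> np.ndarray:
        return self.result.displacements_px()

    @property
    def tumor_reference(self) -> IntensityImage:
        return self.result.tumor_ref

    @property
    def background_reference(self) -> IntensityImage:
        return self.result.bg_ref

    def to_dataframe(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            {
                "frame": np.arange(1, r.n_frames + 1),
                "u_px": r.u_px,
                "v_px": r.v_px,
                "u_mm": r.u_mm,
                "v_mm": r.v_mm,
                "bg_u_px": r.bg_u_px,
                "bg_v_px": r.bg_v_px,
            }
        )

    def tracking_error_vs(self, truth_trace_px) -> float:
        """Mean Euclidean error e_p (mm) against a ground-truth pixel trace."""
        return evaluation.tracking_error_ep(
            self.displacements_px, truth_trace_px, self.result.spacing_mm
        )

    def summary(self) -> str:
        r = self.result
        lines = [
            "Tracking results",
            "=" * 54,
            f"method:           {r.method_label}",
            f"frames processed: {r.n_frames}",
            f"pixel pitch:      {r.spacing_mm:g} mm",
        ]
        if r.n_frames:
            lines += [
                "displacement range (mm): "
                f"u [{r.u_mm.min():+.2f}, {r.u_mm.max():+.2f}]  "
                f"v [{r.v_mm.min():+.2f}, {r.v_mm.max():+.2f}]",
            ]
        if r.objective_trace:
            j0 = r.objective_trace[0][0]
            jT = r.objective_trace[-1][0]
            lines.append(f"objective J(t), first/last frame: {j0:.4g} / {jT:.4g}")
        if r.failure is not None:
            lines.append(f"FAILED at frame {r.failure[0]}: {r.failure[1]}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_trajectory(self, ax=None, truth_trace_px=None):
        """Plot u(t), v(t) in mm; optionally overlay a ground-truth trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.result
        t = np.arange(1, r.n_frames + 1)
        ax.plot(t, r.u_mm, label="u (lateral)")
        ax.plot(t, r.v_mm, label="v (craniocaudal)")
        if truth_trace_px is not None:
            truth = np.asarray(truth_trace_px, dtype=float) * r.spacing_mm
            ax.plot(t, truth[: len(t), 0], "k--", lw=0.8, label="u truth")
            ax.plot(t, truth[: len(t), 1], "k:", lw=0.8, label="v truth")
        ax.set_xlabel("frame")
        ax.set_ylabel("displacement [mm]")
        ax.legend(fontsize="small")
        return ax


class _BaseTracker:
    def __init__(
        self,
        frames: list[IntensityImage],
        outline: Region | np.ndarray,
        matching: MatchConfig | None = None,
    ) -> None:
        self.frames = list(frames)
        self.outline = outline if isinstance(outline, Region) else Region(outline)
        self.matching = matching or MatchConfig()

    @classmethod
    def from_arrays(cls, stack: np.ndarray, outline_mask: np.ndarray, spacing_mm: float = 1.0, **kw):
        """Build from a (T, m, n) array stack and a boolean outline mask."""
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3:
            raise ValueError("stack must be (T, m, n)")
        frames = [IntensityImage(f, None, spacing_mm) for f in stack]
        return cls(frames, Region(outline_mask), **kw)


class DynamicDecompositionTracker(_BaseTracker):
    """Markerless tracker: recursive tumor/background intensity decomposition.

    Parameters
    ----------
    frames : list of IntensityImage
    outline : Region or bool array
        Initial tumor outline on the first frame.
    solver : SolverConfig
        Step size, inner iterations, binarization threshold.
    matching : MatchConfig
        Exhaustive-search window and metric.
    intensity_init : float
        Constant initial intensity inside the outline (default 1).
    """

    def __init__(
        self,
        frames,
        outline,
        solver: SolverConfig | None = None,
        matching: MatchConfig | None = None,
        intensity_init: float = 1.0,
    ) -> None:
        super().__init__(frames, outline, matching)
        self.solver = solver or SolverConfig()
        self.intensity_init = intensity_init

    def fit(self) -> TrackingResults:
        result = track_sequence(
            self.frames,
            self.outline,
            cfg=self.solver,
            mcfg=self.matching,
            I0=self.intensity_init,
        )
        return TrackingResults(result, self)


class TemplateMatchingTracker(_BaseTracker):
    """Comparison baseline: direct matching on the raw frames, no decomposition."""

    def fit(self) -> TrackingResults:
        result = evaluation.baseline_track(self.frames, self.outline, self.matching)
        return TrackingResults(result, self)
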