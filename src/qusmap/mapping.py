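"""Sliding-window parametric imaging.

Each estimator runs over a square-in-mm sliding window (side = a multiple
of the pulse length; 4 PL for HK-log10(alpha), 3 PL for Nakagami-m, 1 PL
for hNSE) with 50% overlap; the per-window value sits at the window
center, the window-center grid is interpolated back to the full envelope
size by a bicubic spline (edge values held outside the center hull), and
the full-size map is min-max normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .config import AcquisitionConfig, ParameterError
from .envelope import EnvelopeFrame
from .estimators import hnse_estimate, nakagami_moment_estimate
from .homodyned_k import (
    DEFAULT_ALPHA_MAX,
    EstimationError,
    HKTheoryTable,
    hk_xu_estimate,
)

logger = logging.getLogger(__name__)

#: window side lengths in pulse lengths, per parameter
WSL_PULSE_LENGTHS = {"hk_log10_alpha": 4.0, "nakagami_m": 3.0, "hnse": 1.0}

MAX_MISSING_FRACTION = 0.05


def window_size_from_pulse_lengths(
    wsl_pl: float, config: AcquisitionConfig
) -> tuple[int, int]:
    """Window size in (rows, cols) for a square window of wsl_pl pulse lengths."""
    if wsl_pl <= 0:
        raise ParameterError("window side length must be positive")
    side_mm = wsl_pl * config.pulse_length_mm
    rows = max(2, int(np.floor(side_mm / config.axial_spacing_mm + 0.5)))
    cols = max(2, int(np.floor(side_mm / config.lateral_pitch_mm + 0.5)))
    if rows > config.n_samples or cols > config.n_lines:
        raise ParameterError("window larger than the frame")
    return rows, cols


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window geometry: size, 50% stride and center coordinates."""

    wsl_pulse_lengths: float
    window_rows: int
    window_cols: int
    stride_rows: int
    stride_cols: int
    row_anchors: np.ndarray
    col_anchors: np.ndarray

    @classmethod
    def for_frame(
        cls, wsl_pl: float, config: AcquisitionConfig, shape: tuple[int, int]
    ) -> "WindowGrid":
        rows, cols = window_size_from_pulse_lengths(wsl_pl, config)
        stride_r = max(1, int(np.floor(rows / 2 + 0.5)))
        stride_c = max(1, int(np.floor(cols / 2 + 0.5)))
        row_anchors = np.arange(0, shape[0] - rows + 1, stride_r)
        col_anchors = np.arange(0, shape[1] - cols + 1, stride_c)
        if len(row_anchors) == 0 or len(col_anchors) == 0:
            raise ParameterError("window larger than the frame")
        return cls(
            wsl_pulse_lengths=wsl_pl,
            window_rows=rows,
            window_cols=cols,
            stride_rows=stride_r,
            stride_cols=stride_c,
            row_anchors=row_anchors,
            col_anchors=col_anchors,
        )

    @property
    def row_centers(self) -> np.ndarray:
        return self.row_anchors + (self.window_rows - 1) / 2.0

    @property
    def col_centers(self) -> np.ndarray:
        return self.col_anchors + (self.window_cols - 1) / 2.0


@dataclass
class ParametricMap:
    """One QUS parameter at the three stages: window grid, full size, normalized."""

    parameter_name: str
    window_grid: WindowGrid
    grid_values: np.ndarray
    full_values: np.ndarray | None = None
    normalized_values: np.ndarray | None = None
    n_missing: int = 0


def slide_window_map(
    env: EnvelopeFrame, estimator, grid: WindowGrid, parameter_name: str = ""
) -> ParametricMap:
    """Apply ``estimator(window_samples) -> float`` on every window.

    Estimator failures become missing values, in-filled from the nearest
    valid window (aborts if more than 5% of windows fail).
    """
    data = env.data
    values = np.full((len(grid.row_anchors), len(grid.col_anchors)), np.nan)
    for i, r in enumerate(grid.row_anchors):
        for j, c in enumerate(grid.col_anchors):
            window = data[r : r + grid.window_rows, c : c + grid.window_cols]
            try:
                values[i, j] = estimator(window)
            except (EstimationError, ArithmeticError):
                pass
    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if n_missing == values.size:
        raise EstimationError(f"all {parameter_name} windows failed")
    if n_missing:
        if n_missing > MAX_MISSING_FRACTION * values.size:
            raise EstimationError(
                f"{n_missing}/{values.size} {parameter_name} windows failed "
                f"(> {MAX_MISSING_FRACTION:.0%})"
            )
        logger.info(
            "%s map: in-filling %d/%d missing windows",
            parameter_name, n_missing, values.size,
        )
        _, idx = ndimage.distance_transform_edt(missing, return_indices=True)
        values = values[tuple(idx)]
    return ParametricMap(
        parameter_name=parameter_name,
        window_grid=grid,
        grid_values=values,
        n_missing=n_missing,
    )


def interpolate_to_full(pmap: ParametricMap, env_shape: tuple[int, int]) -> ParametricMap:
    """Bicubic spline through window centers, clamped outside the center hull."""
    grid = pmap.grid_values
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ParameterError("need at least a 2x2 window grid to interpolate")
    rc = pmap.window_grid.row_centers
    cc = pmap.window_grid.col_centers
    kx = min(3, len(rc) - 1)
    ky = min(3, len(cc) - 1)
    spline = RectBivariateSpline(rc, cc, grid, kx=kx, ky=ky)
    rows = np.clip(np.arange(env_shape[0], dtype=float), rc[0], rc[-1])
    cols = np.clip(np.arange(env_shape[1], dtype=float), cc[0], cc[-1])
    full = spline(rows, cols)
    return replace(pmap, full_values=full)


def normalize_map(pmap: ParametricMap) -> ParametricMap:
    """Min-max normalize the full-size map to [0, 1] (per frame, per parameter)."""
    if pmap.full_values is None:
        raise ParameterError("interpolate_to_full must run before normalization")
    v = pmap.full_values
    vmin, vmax = v.min(), v.max()
    if not vmax > vmin:
        raise EstimationError("degenerate map: max equals min")
    return replace(pmap, normalized_values=(v - vmin) / (vmax - vmin))


# ---------------------------------------------------------------------------
# Per-parameter estimator factories and the three-map pipeline
# ---------------------------------------------------------------------------

def make_hk_estimator(table: HKTheoryTable, alpha_max: float = DEFAULT_ALPHA_MAX):
    def estimate(window) -> float:
        return hk_xu_estimate(window, table=table, alpha_max=alpha_max).log10_alpha

    return estimate


def make_nakagami_estimator():
    def estimate(window) -> float:
        return nakagami_moment_estimate(window).m

    return estimate


def make_hnse_estimator(frame_min: float, frame_max: float):
    def estimate(window) -> float:
        return hnse_estimate(window, frame_min, frame_max)

    return estimate


def compute_parametric_maps(
    env: EnvelopeFrame, table: HKTheoryTable
) -> dict[str, ParametricMap]:
    """The three normalized maps [hk_log10_alpha, nakagami_m, hnse] of a frame."""
    config = env.config
    estimators = {
        "hk_log10_alpha": make_hk_estimator(table),
        "nakagami_m": make_nakagami_estimator(),
        "hnse": make_hnse_estimator(float(env.data.min()), float(env.data.max())),
    }
    maps = {}
    for name, estimator in estimators.items():
        grid = WindowGrid.for_frame(WSL_PULSE_LENGTHS[name], config, env.shape)
        pmap = slide_window_map(env, estimator, grid, parameter_name=name)
        pmap = interpolate_to_full(pmap, env.shape)
        maps[name] = normalize_map(pmap)
    return maps


def save_map_png(pmap: ParametricMap, path) -> None:
    """Pseudo-color (blue-to-red) PNG export of the normalized map."""
    import imageio.v3 as iio
    from matplotlib import colormaps

    if pmap.normalized_values is None:
        raise ParameterError("normalize_map must run before export")
    rgba = colormaps["jet"](pmap.normalized_values)
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))
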