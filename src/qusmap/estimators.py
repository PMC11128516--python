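"""Nakagami and entropy estimators for envelope sample sets.

The Nakagami shape parameter m is the method-of-moments plug-in
m = (E[A^2])^2 / Var(A^2) with population (divide-by-N) moments; m < 1
marks pre-Rayleigh envelope statistics (sparse or clustered scatterers),
m = 1 the Rayleigh regime of fully developed speckle.

hNSE is the Shannon entropy (base 2) of the probability-distribution
histogram of envelope values after *frame-level* min-max normalization,
so every sliding window shares the fixed bin limits [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ParameterError
from .homodyned_k import EstimationError

HNSE_BINS = 60


@dataclass(frozen=True)
class NakagamiParams:
    m: float
    omega: float


def nakagami_moment_estimate(envelope_samples) -> NakagamiParams:
    """Moment-based Nakagami fit: m = (mean I)^2 / popvar(I), Omega = mean I."""
    a = np.asarray(envelope_samples, dtype=float).ravel()
    if a.size < 2:
        raise EstimationError("need at least 2 envelope samples")
    if np.any(a < 0):
        raise EstimationError("envelope samples must be nonnegative")
    intensity = a * a
    mean_i = intensity.mean()
    var_i = np.mean((intensity - mean_i) ** 2)
    if var_i <= 0 or mean_i <= 0:
        raise EstimationError("constant envelope: Nakagami m undefined")
    return NakagamiParams(m=float(mean_i**2 / var_i), omega=float(mean_i))


def hnse_estimate(
    envelope_window,
    frame_min: float,
    frame_max: float,
    bins: int = HNSE_BINS,
) -> float:
    """Histogram Shannon entropy (log2) of a window on fixed [0, 1] bins.

    Window values are mapped through the *frame's* min/max so all windows
    of one frame share bin limits; result lies in [0, log2(bins)].
    """
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    if not frame_max > frame_min:
        raise EstimationError("frame_max must exceed frame_min")
    w = np.asarray(envelope_window, dtype=float).ravel()
    if w.size == 0:
        raise EstimationError("empty window")
    r = (w - frame_min) / (frame_max - frame_min)
    counts, _ = np.histogram(np.clip(r, 0.0, 1.0), bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / w.size
    return float(-(p * np.log2(p)).sum())
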