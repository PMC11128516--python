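"""Envelope extraction and B-mode display.

The envelope of each scan line is the magnitude of its analytic signal
(Hilbert transform along the axial axis).  B-mode is the log-compressed,
grayscale-mapped envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .config import AcquisitionConfig, ParameterError
from .simulate import RFFrame


@dataclass
class EnvelopeFrame:
    """Nonnegative analytic-signal magnitude of an RF frame."""

    data: np.ndarray
    config: AcquisitionConfig
    truth_mask: np.ndarray | None = None
    provenance: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def compute_envelope(rf: RFFrame) -> EnvelopeFrame:
    """Magnitude of the per-line analytic signal; shape preserved."""
    data = np.asarray(rf.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ParameterError("RF frame contains NaN or Inf")
    env = np.abs(hilbert(data, axis=0))
    return EnvelopeFrame(
        data=env, config=rf.config, truth_mask=rf.truth_mask, provenance="hilbert"
    )


def compute_bmode(env: EnvelopeFrame, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Log-compress to [-DR, 0] dB and map linearly to [0, 1] grayscale."""
    if dynamic_range_db <= 0:
        raise ParameterError("dynamic range must be positive")
    data = env.data
    peak = data.max()
    if peak <= 0:
        raise ParameterError("all-zero envelope has no reference maximum")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(data / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    return db / dynamic_range_db + 1.0


def save_bmode_png(env: EnvelopeFrame, path, dynamic_range_db: float = 40.0) -> None:
    import imageio.v3 as iio

    gray = compute_bmode(env, dynamic_range_db)
    iio.imwrite(path, (np.round(gray * 255)).astype(np.uint8))
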