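"""Mouse hemodynamic response model and event-regressor construction.

Mouse BOLD responses peak much earlier than the canonical human response;
the default double-gamma kernel peaks at 1 s and has died out by 8 s.
Both the BOLD simulator and the GLM build their regressors through
:func:`event_regressor`, so a signal planted by the simulator is exactly
representable by the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist


class HRFConfigurationError(ValueError):
    pass


@dataclass
class HRFModel:
    """Double-gamma impulse response, parameterized by peak timing.

    ``time_to_peak`` and ``undershoot_delay`` are the modes (s) of the
    positive and negative gamma lobes; ``peak_dispersion`` is the shared
    gamma scale (s); ``undershoot_ratio`` scales the negative lobe.
    """

    kind: str = "double_gamma"
    time_to_peak: float = 1.0
    peak_dispersion: float = 0.3
    undershoot_delay: float = 3.0
    undershoot_ratio: float = 0.2
    duration: float = 8.0
    sample_rate: float = 10.0  # Hz of the fine convolution grid

    def __post_init__(self) -> None:
        if self.kind != "double_gamma":
            raise HRFConfigurationError(f"unknown HRF kind {self.kind!r}")
        if min(self.time_to_peak, self.peak_dispersion, self.duration, self.sample_rate) <= 0:
            raise HRFConfigurationError("HRF timing parameters must be positive")
        if self.undershoot_delay <= self.time_to_peak:
            raise HRFConfigurationError(
                "undershoot_delay must come after time_to_peak "
                f"({self.undershoot_delay} <= {self.time_to_peak})"
            )
        if self.undershoot_ratio < 0:
            raise HRFConfigurationError("undershoot_ratio must be >= 0")


def default_mouse_hrf(**overrides) -> HRFModel:
    return HRFModel(**overrides)


def hrf_kernel(model: HRFModel) -> np.ndarray:
    """Sampled kernel on the fine grid, peak-normalized so max(kernel) = 1."""
    t = np.arange(0.0, model.duration, 1.0 / model.sample_rate)
    scale = model.peak_dispersion
    # gamma pdf mode is (shape-1)*scale; pin the modes at the requested times
    shape_pos = model.time_to_peak / scale + 1.0
    kernel = gamma_dist.pdf(t, shape_pos, scale=scale)
    if model.undershoot_ratio > 0:
        shape_neg = model.undershoot_delay / scale + 1.0
        under = gamma_dist.pdf(t, shape_neg, scale=scale)
        kernel = kernel - model.undershoot_ratio * under / under.max() * kernel.max()
    peak = kernel.max()
    if not np.isfinite(peak) or peak <= 0:
        raise HRFConfigurationError("kernel has no positive peak; check parameters")
    return kernel / peak


def event_regressor(
    onsets: np.ndarray,
    weights,
    kernel: np.ndarray,
    sample_rate: float,
    n_volumes: int,
    tr: float,
) -> np.ndarray:
    """Convolve a weighted zero-duration stick train and resample at the TR.

    Events are placed on a fine grid (``sample_rate``) to honor sub-TR onset
    jitter, convolved with ``kernel`` (sampled on the same grid), and read
    out at volume times ``i * tr``.
    """
    onsets = np.asarray(onsets, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), onsets.shape)
    scan_len = n_volumes * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() >= scan_len):
        bad = onsets[(onsets < 0) | (onsets >= scan_len)][0]
        raise ValueError(f"event onset {bad:.2f} s lies outside the {scan_len:.2f} s scan")
    n_fine = int(np.ceil(scan_len * sample_rate)) + 1
    sticks = np.zeros(n_fine)
    idx = np.round(onsets * sample_rate).astype(int)
    np.add.at(sticks, np.minimum(idx, n_fine - 1), weights)
    conv = np.convolve(sticks, kernel)[:n_fine]
    vol_idx = np.round(np.arange(n_volumes) * tr * sample_rate).astype(int)
    return conv[vol_idx]
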