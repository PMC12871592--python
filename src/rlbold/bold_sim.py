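"""Synthetic volumetric BOLD data with a planted decision-variable signal.

Stands in for the study's in-vivo imaging: 4-D volumes at TR 2.5 s whose
ROI voxels carry the HRF-convolved, decision-variable-weighted stick train
at a known amplitude, plus structured nuisance (slow cosine drift, a
shared global fluctuation, motion-correlated signal), AR(1) Gaussian
noise, and optional frame-displacement spikes.  Every generative value is
returned in a ground-truth record so recovery can be tested end to end.

The default grid is a desk-scale 16 x 16 x 8 volume rather than the
acquisition matrix; geometry, noise structure and the HRF are all
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import TaskSchedule
from .hemodynamics import (  # noqa: F401  (re-exported module surface)
    HRFConfigurationError,
    HRFModel,
    default_mouse_hrf,
    event_regressor,
    hrf_kernel,
)

MOTION_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
)

#: rotation-to-arc conversion radius (mm) in the frame-displacement sum
FD_ROTATION_RADIUS_MM = 5.0


@dataclass
class VolumeSeries:
    """4-D BOLD array (x, y, z, time) with its repetition time and geometry."""

    data: np.ndarray
    tr: float = 2.5
    voxel_size: Tuple[float, float, float] = (0.2, 0.2, 0.3)  # mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4-D array, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self):
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.data, affine)
        img.header.set_zooms(tuple(self.voxel_size) + (self.tr,))
        return img

    @classmethod
    def from_nifti(cls, img) -> "VolumeSeries":
        zooms = img.header.get_zooms()
        return cls(
            data=np.asarray(img.get_fdata()),
            tr=float(zooms[3]),
            voxel_size=tuple(float(z) for z in zooms[:3]),
        )


@dataclass
class NuisanceTable:
    """Per-volume nuisance series: global, ventricle, motion (+derivatives), FD."""

    global_signal: np.ndarray
    ventricle_signal: np.ndarray
    motion: np.ndarray  # (n_volumes, 6): translations mm, rotations rad

    def __post_init__(self) -> None:
        self.global_signal = np.asarray(self.global_signal, dtype=float)
        self.ventricle_signal = np.asarray(self.ventricle_signal, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        n = len(self.global_signal)
        if len(self.ventricle_signal) != n or self.motion.shape != (n, 6):
            raise ValueError("nuisance series lengths disagree")

    @property
    def n_volumes(self) -> int:
        return len(self.global_signal)

    @property
    def motion_derivatives(self) -> np.ndarray:
        d = np.diff(self.motion, axis=0, prepend=self.motion[:1])
        return d

    @property
    def fd(self) -> np.ndarray:
        return frame_displacement(self.motion)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.motion, columns=list(MOTION_COLUMNS))
        df.insert(0, "ventricle_signal", self.ventricle_signal)
        df.insert(0, "global_signal", self.global_signal)
        deriv = self.motion_derivatives
        for j, col in enumerate(MOTION_COLUMNS):
            df[f"{col}_derivative1"] = deriv[:, j]
        df["framewise_displacement"] = self.fd
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NuisanceTable":
        return cls(
            global_signal=df["global_signal"].to_numpy(),
            ventricle_signal=df["ventricle_signal"].to_numpy(),
            motion=df[list(MOTION_COLUMNS)].to_numpy(),
        )


@dataclass
class ROIEffect:
    voxels: np.ndarray  # (n, 3) integer indices
    amplitude: float  # signal units per unit decision variable

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[1] != 3:
            raise ValueError("voxel indices must be (n, 3)")


@dataclass
class EffectMap:
    rois: Dict[str, ROIEffect]

    def validate(self, shape: Tuple[int, int, int]) -> None:
        seen = set()
        for name, roi in self.rois.items():
            for v in map(tuple, roi.voxels):
                if not all(0 <= v[d] < shape[d] for d in range(3)):
                    raise ValueError(f"ROI {name!r} voxel {v} outside volume {shape}")
                if v in seen:
                    raise ValueError(f"ROI voxel {v} assigned to more than one ROI")
                seen.add(v)

    def mask(self, name: str, shape: Tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        idx = self.rois[name].voxels
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return m


@dataclass
class NoiseConfig:
    sigma: float = 1.0  # AR(1) innovation SD, signal units
    ar_coef: float = 0.3
    drift_amplitude: float = 0.0  # low-order cosine drift
    n_drift_terms: int = 3
    global_amplitude: float = 0.0  # shared fluctuation picked up per voxel
    motion_amplitude: float = 0.0  # motion-correlated signal per voxel
    motion_step_sd: float = 0.002  # random-walk step of translations (mm)
    rotation_step_sd: float = 0.0004  # and rotations (rad)
    fd_spike_volumes: Tuple[int, ...] = ()
    fd_spike_size: float = 0.3  # mm translation jump at each spike


def frame_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-style framewise displacement with a 5-mm rotation arc radius.

    ``FD_t = sum |d trans| + 5 mm * sum |d rot|``; the first volume gets 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + FD_ROTATION_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def simulate_bold(
    schedule: TaskSchedule,
    dv_series: np.ndarray,
    effects: EffectMap,
    shape: Tuple[int, int, int] = (16, 16, 8),
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
    *,
    hrf: Optional[HRFModel] = None,
    tr: float = 2.5,
    n_volumes: Optional[int] = None,
    baseline: float = 100.0,
):
    """Generate one run of synthetic BOLD plus its nuisance table.

    ROI voxels carry ``amplitude x (dv-weighted stick train * HRF)``; all
    voxels share the structured nuisance and AR(1) noise dictated by
    ``noise``.  Returns ``(VolumeSeries, NuisanceTable, truth)`` where
    ``truth`` records every generative quantity.
    """
    noise = noise or NoiseConfig()
    hrf = hrf or default_mouse_hrf()
    effects.validate(shape)
    onsets = np.array([t.onset for t in schedule.trials])
    dv_series = np.asarray(dv_series, dtype=float)
    if len(dv_series) != len(onsets):
        raise ValueError(
            f"dv series length {len(dv_series)} != trial count {len(onsets)}"
        )
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets.max() + 20.0) / tr)) if onsets.size else 8
    kernel = hrf_kernel(hrf)
    regressor = event_regressor(
        onsets, dv_series, kernel, hrf.sample_rate, n_volumes, tr
    )

    rng = np.random.default_rng(seed)
    t_vol = np.arange(n_volumes)

    # motion random walk with optional FD spike jumps
    steps = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    steps[:, :3] *= noise.motion_step_sd
    steps[:, 3:] *= noise.rotation_step_sd
    steps[0] = 0.0
    for v in noise.fd_spike_volumes:
        if not 0 <= v < n_volumes:
            raise ValueError(f"fd spike volume {v} outside run of {n_volumes}")
        steps[v, 0] += noise.fd_spike_size
    motion = np.cumsum(steps, axis=0)

    def ar1(n: int) -> np.ndarray:
        e = rng.normal(0.0, 1.0, size=n)
        out = np.empty(n)
        prev = 0.0
        for i in range(n):
            prev = noise.ar_coef * prev + e[i]
            out[i] = prev
        return out * np.sqrt(1.0 - noise.ar_coef**2)

    global_signal = ar1(n_volumes)
    ventricle_signal = ar1(n_volumes)
    drift = np.zeros(n_volumes)
    for k in range(1, noise.n_drift_terms + 1):
        drift += np.cos(np.pi * k * t_vol / max(n_volumes - 1, 1)) / k
    nuisance = NuisanceTable(global_signal, ventricle_signal, motion)

    data = np.full(shape + (n_volumes,), baseline)
    if noise.sigma > 0:
        nois = rng.normal(0.0, 1.0, size=shape + (n_volumes,))
        if noise.ar_coef:
            for i in range(1, n_volumes):
                nois[..., i] += noise.ar_coef * nois[..., i - 1]
            nois *= np.sqrt(1.0 - noise.ar_coef**2)
        data = data + noise.sigma * nois
    if noise.drift_amplitude:
        data = data + noise.drift_amplitude * drift
    loadings_g = rng.normal(1.0, 0.2, size=shape)
    loadings_m = rng.normal(0.0, 1.0, size=shape + (6,))
    if noise.global_amplitude:
        data = data + noise.global_amplitude * loadings_g[..., None] * global_signal
    if noise.motion_amplitude:
        data = data + noise.motion_amplitude * np.einsum(
            "xyzj,tj->xyzt", loadings_m, motion
        )
    for name, roi in effects.rois.items():
        idx = roi.voxels
        data[idx[:, 0], idx[:, 1], idx[:, 2], :] += roi.amplitude * regressor

    volume = VolumeSeries(data=data, tr=tr)
    truth = {
        "seed": seed,
        "tr": tr,
        "shape": list(shape),
        "n_volumes": n_volumes,
        "baseline": baseline,
        "amplitudes": {k: r.amplitude for k, r in effects.rois.items()},
        "roi_voxels": {k: r.voxels.tolist() for k, r in effects.rois.items()},
        "regressor": regressor,
        "onsets": onsets,
        "dv": dv_series,
    }
    return volume, nuisance, truth


def save_ground_truth(truth: dict, path) -> None:
    out = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
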