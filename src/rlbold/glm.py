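"""First-level GLM: design assembly, voxelwise OLS, subject contrasts.

Task events enter as zero-duration sticks at stimulus onset convolved with
the mouse HRF; the decision variable enters as a parametric modulator
(mean-centered over trials before stick weighting).  Nuisance regressors
follow the study convention: global signal, ventricle signal, six motion
parameters and their first derivatives, a run constant for every run
except the last, and one spike regressor per volume whose framewise
displacement exceeds the voxel size (0.2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .behavior import TaskSchedule
from .bold_sim import NuisanceTable, VolumeSeries
from .hemodynamics import HRFModel, default_mouse_hrf, event_regressor, hrf_kernel

FD_THRESHOLD_MM = 0.2  # scrub volumes moving more than one voxel


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    frame: pd.DataFrame  # (n_volumes, n_regressors), named columns
    groups: Dict[str, List[str]]  # column-group name -> column names
    flags: List[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> List[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)


@dataclass
class GLMResult:
    coefficients: Dict[str, np.ndarray]  # column name -> 3-D map
    residual_variance: np.ndarray
    df: int
    design: DesignMatrix


@dataclass
class ContrastMap:
    data: np.ndarray
    contrast: np.ndarray
    df: int


def _check_rank(frame: pd.DataFrame, allow_zero: Sequence[str]) -> None:
    X = frame.to_numpy(dtype=float)
    nonzero = [c for c in frame.columns if c not in allow_zero]
    Xnz = frame[nonzero].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xnz)
    if rank < Xnz.shape[1]:
        # locate offending columns via pivoted QR
        _, r, piv = qr(Xnz, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xnz.shape) * np.finfo(float).eps
        bad = [nonzero[piv[i]] for i in range(len(nonzero)) if i >= rank or diag[i] < tol]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design(
    schedule: TaskSchedule,
    *,
    dv_series: Optional[np.ndarray] = None,
    condition_labels: Optional[Sequence[str]] = None,
    nuisance: Optional[NuisanceTable] = None,
    hrf: Optional[HRFModel] = None,
    tr: float = 2.5,
    n_volumes: Optional[int] = None,
    mode: str = "dv_modulator",
    fd_threshold: float = FD_THRESHOLD_MM,
    orthogonalize_modulator: bool = False,
    intercept: bool = True,
) -> DesignMatrix:
    """Assemble a first-level design for one run.

    ``dv_modulator`` mode produces one unmodulated onset regressor plus the
    mean-centered decision-variable modulator; ``condition_events`` mode
    produces one convolved regressor per outcome class present in
    ``condition_labels`` (Hit / FA / CR / Miss).
    """
    hrf = hrf or default_mouse_hrf()
    onsets = np.array([t.onset for t in schedule.trials])
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets.max() + 20.0) / tr))
    kernel = hrf_kernel(hrf)
    cols: Dict[str, np.ndarray] = {}
    groups: Dict[str, List[str]] = {"task": [], "nuisance": [], "spikes": [],
                                    "run_constants": [], "intercept": []}
    flags: List[str] = []

    if mode == "dv_modulator":
        if dv_series is None:
            raise ValueError("dv_series is required in dv_modulator mode")
        dv_series = np.asarray(dv_series, dtype=float)
        if len(dv_series) != len(onsets):
            raise ValueError(
                f"dv length {len(dv_series)} != trial count {len(onsets)}"
            )
        task = event_regressor(onsets, 1.0, kernel, hrf.sample_rate, n_volumes, tr)
        centered = dv_series - dv_series.mean()
        mod = event_regressor(onsets, centered, kernel, hrf.sample_rate, n_volumes, tr)
        if np.allclose(mod, 0.0):
            flags.append("dv_modulator is all zeros after mean-centering")
        if orthogonalize_modulator and not np.allclose(task, 0.0):
            mod = mod - task * (mod @ task) / (task @ task)
        cols["task_onsets"] = task
        cols["dv_modulator"] = mod
        groups["task"] = ["task_onsets", "dv_modulator"]
    elif mode == "condition_events":
        if condition_labels is None:
            raise ValueError("condition_labels are required in condition_events mode")
        condition_labels = list(condition_labels)
        if len(condition_labels) != len(onsets):
            raise ValueError("one condition label per trial is required")
        for cond in sorted(set(condition_labels)):
            sel = np.array([c == cond for c in condition_labels])
            reg = event_regressor(
                onsets[sel], 1.0, kernel, hrf.sample_rate, n_volumes, tr
            )
            cols[f"cond_{cond}"] = reg
            groups["task"].append(f"cond_{cond}")
    else:
        raise ValueError(f"unknown design mode {mode!r}")

    if nuisance is not None:
        if nuisance.n_volumes != n_volumes:
            raise ValueError(
                f"nuisance table covers {nuisance.n_volumes} volumes, "
                f"design needs {n_volumes}"
            )
        cols["global_signal"] = nuisance.global_signal
        cols["ventricle_signal"] = nuisance.ventricle_signal
        for j, name in enumerate(
            ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
        ):
            cols[name] = nuisance.motion[:, j]
            cols[f"{name}_derivative1"] = nuisance.motion_derivatives[:, j]
        groups["nuisance"] = [
            "global_signal", "ventricle_signal",
            *[n for j, name in enumerate(("trans_x", "trans_y", "trans_z",
                                          "rot_x", "rot_y", "rot_z"))
              for n in (name, f"{name}_derivative1")],
        ]
        fd = nuisance.fd
        for v in np.flatnonzero(fd > fd_threshold):
            spike = np.zeros(n_volumes)
            spike[v] = 1.0
            cols[f"fd_spike_{v}"] = spike
            groups["spikes"].append(f"fd_spike_{v}")

    if intercept:
        cols["intercept"] = np.ones(n_volumes)
        groups["intercept"] = ["intercept"]

    frame = pd.DataFrame(cols)
    zero_cols = [c for c in frame.columns if np.allclose(frame[c], 0.0)]
    _check_rank(frame, allow_zero=zero_cols)
    return DesignMatrix(frame=frame, groups=groups, flags=flags)


def fit_glm(volume: VolumeSeries, design: DesignMatrix) -> GLMResult:
    """Voxelwise ordinary least squares of the data on the design."""
    X = design.matrix
    if volume.n_volumes != X.shape[0]:
        raise ValueError(
            f"volume has {volume.n_volumes} time points, design {X.shape[0]}"
        )
    shape = volume.shape
    Y = volume.data.reshape(-1, X.shape[0]).T  # (time, voxels)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - int(rank)
    var = (resid**2).sum(axis=0) / max(df, 1)
    coefficients = {
        name: beta[j].reshape(shape) for j, name in enumerate(design.columns)
    }
    return GLMResult(
        coefficients=coefficients,
        residual_variance=var.reshape(shape),
        df=df,
        design=design,
    )


def subject_contrast(result: GLMResult, contrast) -> ContrastMap:
    """Voxelwise dot product of coefficient maps with a contrast vector.

    ``contrast`` may be a vector over all design columns or the name of a
    single column (coefficient 1 on it, 0 elsewhere); the default use is
    the ``dv_modulator`` column.
    """
    names = result.design.columns
    if isinstance(contrast, str):
        vec = np.zeros(len(names))
        vec[names.index(contrast)] = 1.0
    else:
        vec = np.asarray(contrast, dtype=float)
        if len(vec) != len(names):
            raise ValueError(
                f"contrast length {len(vec)} != {len(names)} regressors"
            )
    data = np.zeros(result.residual_variance.shape)
    for w, name in zip(vec, names):
        if w:
            data = data + w * result.coefficients[name]
    return ContrastMap(data=data, contrast=vec, df=result.df)


def concatenate_sessions(
    volumes: Sequence[VolumeSeries], designs: Sequence[DesignMatrix]
):
    """Stack runs into a single GLM: time-stacked data and task/nuisance
    columns, block run constants for every run except the last, one shared
    intercept, and per-run spike columns kept one-hot."""
    if len(volumes) != len(designs) or not volumes:
        raise ValueError("need one design per volume series")
    shape = volumes[0].shape
    tr = volumes[0].tr
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError(f"voxel grid mismatch: {v.shape} vs {shape}")
    shared = [c for c in designs[0].columns
              if c != "intercept" and not c.startswith("fd_spike_")]
    for d in designs[1:]:
        also = [c for c in d.columns
                if c != "intercept" and not c.startswith("fd_spike_")]
        if also != shared:
            raise ValueError("designs have inconsistent column naming")

    lengths = [d.n_volumes for d in designs]
    total = sum(lengths)
    cols: Dict[str, np.ndarray] = {}
    for c in shared:
        cols[c] = np.concatenate([d.frame[c].to_numpy() for d in designs])
    offset = 0
    groups: Dict[str, List[str]] = {"task": designs[0].groups.get("task", []),
                                    "nuisance": designs[0].groups.get("nuisance", []),
                                    "spikes": [], "run_constants": [],
                                    "intercept": ["intercept"]}
    for r, d in enumerate(designs):
        for c in d.columns:
            if c.startswith("fd_spike_"):
                full = np.zeros(total)
                full[offset : offset + lengths[r]] = d.frame[c].to_numpy()
                name = f"run{r}_{c}"
                cols[name] = full
                groups["spikes"].append(name)
        if r < len(designs) - 1:
            const = np.zeros(total)
            const[offset : offset + lengths[r]] = 1.0
            cols[f"run_const_{r}"] = const
            groups["run_constants"].append(f"run_const_{r}")
        offset += lengths[r]
    cols["intercept"] = np.ones(total)

    frame = pd.DataFrame(cols)
    zero_cols = [c for c in frame.columns if np.allclose(frame[c], 0.0)]
    _check_rank(frame, allow_zero=zero_cols)
    stacked_design = DesignMatrix(frame=frame, groups=groups)
    stacked_volume = VolumeSeries(
        data=np.concatenate([v.data for v in volumes], axis=3),
        tr=tr,
        voxel_size=volumes[0].voxel_size,
    )
    return stacked_volume, stacked_design
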