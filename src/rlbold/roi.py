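"""ROI time-course characterization: FIR deconvolution, AUC, exact paired tests.

The mean series over an ROI mask is modeled with a finite-impulse-response
basis — one delta column per time bin per outcome condition (Hit / FA /
CR / Miss) — with onsets shifted 5 s earlier so the pre-trial baseline is
part of the estimated response.  A session's response magnitude is
summarized as the baseline-corrected mean coefficient over post-onset
bins (AUC), and conditions are compared with exact small-sample paired
tests (Wilcoxon signed-rank by full enumeration; sign test by binomial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

from .bold_sim import VolumeSeries

CONDITIONS = ("Hit", "FA", "CR", "Miss")


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} has no voxels")


@dataclass
class FIRResult:
    bin_times: np.ndarray  # seconds relative to odor onset (negative = baseline)
    coefficients: Dict[str, np.ndarray]  # condition -> per-bin coefficient
    n_events: Dict[str, int]
    tr: float


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_informative: int
    method: str


def extract_roi_series(volume: VolumeSeries, mask: ROIMask) -> np.ndarray:
    """Per-volume spatial mean over the ROI voxels."""
    if mask.mask.shape != volume.shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} does not match volume {volume.shape}"
        )
    return volume.data[mask.mask].mean(axis=0)


def _bin_column_index(onset: float, bin_time: float, tr: float) -> int:
    return int(round((onset + bin_time) / tr))


def fit_fir(
    series: np.ndarray,
    events: Dict[str, Sequence[float]],
    tr: float,
    pre_shift: float = 5.0,
    window: float = 15.0,
    nuisance: Optional[np.ndarray] = None,
) -> FIRResult:
    """Least-squares FIR estimate per condition with a pre-onset shift.

    Bins run from ``-pre_shift`` to ``+window`` in steps of the TR; each
    event contributes a 1 in the design column of its (condition, bin) at
    the volume nearest ``onset + bin_time``.  An intercept (and optional
    nuisance columns) is always included.
    """
    series = np.asarray(series, dtype=float)
    n_vol = len(series)
    if window < tr:
        raise ValueError("window must be at least one TR")
    n_bins = int(round((pre_shift + window) / tr))
    bin_times = -pre_shift + tr * np.arange(n_bins)
    cols: List[np.ndarray] = []
    names: List[tuple] = []
    n_events: Dict[str, int] = {}
    for cond, onsets in events.items():
        onsets = np.asarray(onsets, dtype=float)
        if onsets.size and (onsets.min() < 0 or onsets.max() >= n_vol * tr):
            raise ValueError(f"{cond} event outside the scan")
        n_events[cond] = len(onsets)
        for j, bt in enumerate(bin_times):
            col = np.zeros(n_vol)
            for onset in onsets:
                v = _bin_column_index(onset, bt, tr)
                if 0 <= v < n_vol:
                    col[v] += 1.0
            cols.append(col)
            names.append((cond, j))
    X = np.column_stack(cols + [np.ones(n_vol)])
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_vol:
            nuisance = nuisance.T
        X = np.column_stack([X, nuisance])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "FIR design is rank deficient (overlapping event windows); "
            "use fewer bins, a shorter window, or longer inter-trial intervals"
        )
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    coefficients = {cond: np.zeros(n_bins) for cond in events}
    for b, (cond, j) in zip(beta, names):
        coefficients[cond][j] = b
    return FIRResult(
        bin_times=bin_times, coefficients=coefficients, n_events=n_events, tr=tr
    )


def auc(
    fir: FIRResult,
    condition: str,
    integration_window: Optional[float] = None,
    baseline_correct: bool = True,
) -> float:
    """Mean post-onset FIR coefficient, minus the mean pre-onset baseline."""
    if condition not in fir.coefficients:
        raise KeyError(f"condition {condition!r} not in FIR result")
    coefs = fir.coefficients[condition]
    post = fir.bin_times >= 0
    if integration_window is not None:
        post &= fir.bin_times < integration_window
    if not post.any():
        raise ValueError("no post-onset bins in the integration window")
    value = float(coefs[post].mean())
    if baseline_correct:
        pre = fir.bin_times < 0
        if pre.any():
            value -= float(coefs[pre].mean())
    return value


def _exact_wilcoxon(diff: np.ndarray) -> PairedTestResult:
    nz = diff[diff != 0.0]  # zero differences dropped before ranking
    m = len(nz)
    if m == 0:
        return PairedTestResult(0.0, 1.0, 0, "wilcoxon_signed_rank")
    ranks = rankdata(np.abs(nz))  # midranks on ties
    w_pos = float(ranks[nz > 0].sum())
    total = float(ranks.sum())
    if m <= 20:
        # full enumeration of the 2^m sign assignments
        signs = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        w_all = signs @ ranks
        p_low = np.mean(w_all <= w_pos + 1e-12)
        p_high = np.mean(w_all >= w_pos - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:  # normal approximation for large n
        mu = total / 2.0
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        from scipy.stats import norm

        z = (w_pos - mu) / sd
        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return PairedTestResult(w_pos, float(p), m, "wilcoxon_signed_rank")


def _exact_sign_test(diff: np.ndarray) -> PairedTestResult:
    nz = diff[diff != 0.0]
    m = len(nz)
    if m == 0:
        return PairedTestResult(0.0, 1.0, 0, "sign_test")
    k = int((nz > 0).sum())
    p = min(1.0, 2.0 * min(binom.cdf(k, m, 0.5), binom.sf(k - 1, m, 0.5)))
    return PairedTestResult(float(k), float(p), m, "sign_test")


def paired_compare(
    x: Sequence[float], y: Sequence[float], method: str = "wilcoxon_signed_rank"
) -> PairedTestResult:
    """Exact paired comparison of two conditions (x - y differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two paired samples of equal length >= 2")
    diff = x - y
    if method == "wilcoxon_signed_rank":
        return _exact_wilcoxon(diff)
    if method == "sign_test":
        return _exact_sign_test(diff)
    raise ValueError(f"unknown method {method!r}")


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (optional helper for post-hoc families)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def condition_auc_table(
    fir_results: Dict, conditions: Sequence[str] = CONDITIONS
) -> pd.DataFrame:
    """Tidy (subject, session, condition, auc) table for external statistics.

    ``fir_results`` maps subject -> session -> FIRResult; conditions absent
    from a given session are emitted with a missing (NaN) AUC.
    """
    rows = []
    for subject, sessions in fir_results.items():
        for session, fir in sessions.items():
            for cond in conditions:
                value = (
                    auc(fir, cond) if cond in fir.coefficients else np.nan
                )
                rows.append(
                    {
                        "subject": subject,
                        "session": session,
                        "condition": cond,
                        "auc": value,
                    }
                )
    return pd.DataFrame(rows, columns=["subject", "session", "condition", "auc"])
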