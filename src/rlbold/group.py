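"""Group-level inference over subject contrast maps.

Two routes, mirroring the parametric and nonparametric arms of small-n
neuroimaging group analysis:

* a one-sample t map with Bonferroni voxelwise family-wise-error control
  and a cluster-extent filter, and
* an exhaustive sign-flip permutation test: under the null the subject
  contrast maps are symmetric about zero, so all ``2^n`` sign assignments
  are equally likely; for each assignment a variance-smoothed pseudo-t map
  is thresholded at the cluster-defining threshold and the maximum
  suprathreshold cluster size (STCS) recorded.  The corrected p-value of
  an observed cluster is the fraction of assignments whose maximum STCS
  reaches its size, the observed labeling included (so p >= 1 / 2^n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class StatMap:
    data: np.ndarray
    kind: str  # t | pseudo_t
    df: int
    n_subjects: int


@dataclass
class Cluster:
    voxels: np.ndarray  # (size, 3)
    size: int
    peak_stat: float
    peak_voxel: Tuple[int, int, int]
    corrected_p: Optional[float] = None


@dataclass
class ClusterSet:
    clusters: List[Cluster]
    threshold: float
    connectivity: int
    critical_stcs: Optional[int] = None
    n_permutations: Optional[int] = None

    def __len__(self) -> int:
        return len(self.clusters)

    def significant(self, alpha: float = 0.05) -> List[Cluster]:
        return [
            c for c in self.clusters
            if c.corrected_p is not None and c.corrected_p <= alpha
        ]


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 4:
        raise ValueError("expected a sequence of 3-D maps")
    return arr


def one_sample_t(maps: Sequence[np.ndarray], mask: Optional[np.ndarray] = None) -> StatMap:
    """Voxelwise one-sample t statistic, t = mean / (sd / sqrt(n)), df = n-1.

    Voxels with zero variance across subjects (or outside the mask) are NaN.
    """
    arr = _stack(maps)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("one-sample t needs at least two subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    if mask is not None:
        t = np.where(mask, t, np.nan)
    return StatMap(data=t, kind="t", df=n - 1, n_subjects=n)


def enumerate_sign_flips(
    n_subjects: int,
    cap: int = 20,
    seed: Optional[int] = None,
    n_random: int = 10_000,
) -> np.ndarray:
    """All 2^n sign assignments (+1/-1), identity first.

    Beyond ``cap`` subjects exhaustive enumeration is replaced by
    ``n_random`` seeded random assignments (identity still first).
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if n_subjects <= cap:
        n_perm = 2**n_subjects
        bits = (np.arange(n_perm)[:, None] >> np.arange(n_subjects)) & 1
        return 1 - 2 * bits  # assignment 0 is all +1 (the identity)
    rng = np.random.default_rng(seed)
    signs = 1 - 2 * rng.integers(0, 2, size=(n_random, n_subjects))
    signs[0] = 1
    return signs


def _smooth_in_mask(img: np.ndarray, sigma_vox, mask: np.ndarray) -> np.ndarray:
    """Gaussian smoothing renormalized within the mask, 3-SD truncation."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(img * m, sigma_vox, truncate=3.0)
    den = ndimage.gaussian_filter(m, sigma_vox, truncate=3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(mask, out, 0.0)


def pseudo_t_map(
    maps: Sequence[np.ndarray],
    fwhm: float,
    voxel_size=(0.2, 0.2, 0.3),
    mask: Optional[np.ndarray] = None,
) -> StatMap:
    """t-like statistic whose denominator uses the smoothed variance image.

    ``fwhm`` is in mm and is converted to voxels per axis; ``fwhm = 0``
    reduces exactly to :func:`one_sample_t` (NaN handling aside: zero
    variance also yields NaN here).
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    arr = _stack(maps)
    n = arr.shape[0]
    if mask is None:
        mask = np.ones(arr.shape[1:], dtype=bool)
    if fwhm == 0:
        t = one_sample_t(maps, mask=mask)
        return StatMap(data=t.data, kind="pseudo_t", df=n - 1, n_subjects=n)
    mean = arr.mean(axis=0)
    var = arr.var(axis=0, ddof=1)
    sigma_vox = tuple(fwhm / (FWHM_TO_SIGMA * vs) for vs in voxel_size)
    var_s = _smooth_in_mask(var, sigma_vox, mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var_s / n)
    t[var_s <= 0] = np.nan
    t = np.where(mask, t, np.nan)
    return StatMap(data=t, kind="pseudo_t", df=n - 1, n_subjects=n)


def cluster_extract(
    stat: np.ndarray, threshold: float, connectivity: int = 18
) -> ClusterSet:
    """Connected components of {stat > threshold} under 6/18/26-connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    data = np.asarray(stat, dtype=float)
    supra = np.nan_to_num(data, nan=-np.inf) > threshold
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        vals = data[labels == lab]
        k = int(np.argmax(vals))
        clusters.append(
            Cluster(
                voxels=vox,
                size=len(vox),
                peak_stat=float(vals[k]),
                peak_voxel=tuple(int(x) for x in vox[k]),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters=clusters, threshold=threshold, connectivity=connectivity)


def _max_cluster_size(supra: np.ndarray, structure) -> int:
    labels, n_lab = ndimage.label(supra, structure=structure)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def snpm_cluster_test(
    maps: Sequence[np.ndarray],
    defining_threshold: float = 6.0,
    variance_fwhm: float = 0.5,
    connectivity: int = 18,
    alpha: float = 0.05,
    voxel_size=(0.2, 0.2, 0.3),
    mask: Optional[np.ndarray] = None,
    cap: int = 20,
    seed: Optional[int] = None,
) -> ClusterSet:
    """Exhaustive sign-flip permutation test with STCS correction.

    Recomputes the variance-smoothed pseudo-t map for every sign
    assignment (exhaustive when ``2^n <= 2^cap``), records the maximum
    suprathreshold cluster size, and assigns each observed cluster the
    corrected p-value ``#(max STCS >= size) / n_permutations``.  The
    critical STCS is the smallest size whose corrected p is <= alpha.
    """
    arr = _stack(maps)
    n, shape = arr.shape[0], arr.shape[1:]
    if n < 2:
        raise ValueError("need at least two subjects")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    signs = enumerate_sign_flips(n, cap=cap, seed=seed)
    n_perm = signs.shape[0]
    structure = _STRUCTURES[connectivity]

    flat = arr.reshape(n, -1)
    sumsq = (flat**2).sum(axis=0)  # invariant under sign flips
    sigma_vox = tuple(variance_fwhm / (FWHM_TO_SIGMA * vs) for vs in voxel_size)
    smooth_var = variance_fwhm > 0
    flat_mask = mask.ravel()

    max_sizes = np.zeros(n_perm, dtype=int)
    observed: Optional[ClusterSet] = None
    for p in range(n_perm):
        mean = (signs[p] @ flat) / n
        var = (sumsq - n * mean**2) / (n - 1)
        var = var.reshape(shape)
        if smooth_var:
            var = _smooth_in_mask(var, sigma_vox, mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean.reshape(shape) / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        t = np.where(mask, t, 0.0)
        if p == 0:
            observed = cluster_extract(t, defining_threshold, connectivity)
        max_sizes[p] = _max_cluster_size(t > defining_threshold, structure)

    assert observed is not None
    for c in observed.clusters:
        c.corrected_p = float(np.mean(max_sizes >= c.size))
    # smallest cluster size controlling FWE at alpha
    critical = None
    for s in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= s) <= alpha:
            critical = s
            break
    observed.critical_stcs = critical
    observed.n_permutations = n_perm
    return observed


def parametric_fwe(
    stat: StatMap,
    alpha: float = 0.05,
    voxel_extent: int = 5,
    mask: Optional[np.ndarray] = None,
    connectivity: int = 18,
):
    """Bonferroni voxelwise FWE threshold plus a cluster-extent filter.

    Surviving voxels form connected components; components smaller than
    ``voxel_extent`` are removed.  ``alpha >= 1`` degenerates to no
    voxelwise threshold (all in-mask voxels enter the extent filter).
    Returns ``(thresholded map, ClusterSet of survivors)``.
    """
    if stat.df < 1:
        raise ValueError("df must be >= 1")
    data = np.asarray(stat.data, dtype=float)
    if mask is None:
        mask = np.isfinite(data)
    n_vox = int(mask.sum())
    if alpha >= 1.0:
        thr = -np.inf
    else:
        thr = float(t_dist.isf(alpha / max(n_vox, 1), stat.df))
    supra = np.where(mask, np.nan_to_num(data, nan=-np.inf), -np.inf) > thr
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    keep = np.zeros_like(supra)
    clusters = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        if sel.sum() >= voxel_extent:
            keep |= sel
            vox = np.argwhere(sel)
            vals = data[sel]
            k = int(np.argmax(vals))
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=int(sel.sum()),
                    peak_stat=float(vals[k]),
                    peak_voxel=tuple(int(x) for x in vox[k]),
                )
            )
    out = np.where(keep, data, np.nan)
    cs = ClusterSet(clusters=sorted(clusters, key=lambda c: -c.size),
                    threshold=thr, connectivity=connectivity)
    return out, cs
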