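"""Per-voxel texture feature maps over the lesion.

For every lesion voxel a cubic window (side ``2*kernel_radius + 1``,
intersected with the lesion mask) yields 10 first-order statistics and 10
grey-level co-occurrence (GLCM) statistics, per modality.  With both raw
intensities appended this gives the 42-dimensional voxel feature vector that
feeds habitat clustering: 2 modalities x (10 + 10) window features + T2 and
ADC values themselves.

GLCM details: intensities are discretised into ``n_bins`` equal-width bins
over the *lesion-wide* range (so neighbouring windows share a level scale
and the features are invariant to increasing affine intensity maps);
co-occurrences are collected symmetrically at distance 1 over the 13 unique
3-D directions and pooled ("merged") into one matrix per window.  Windows
with no valid voxel pair (isolated voxels) are flagged and take the GLCM
values of the nearest valid voxel.

The sliding-window kernels are numba-compiled; a naive per-voxel
re-enumeration is kept in the test suite as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .image import VolumePair, masked_coords

FIRST_ORDER_NAMES = (
    "mean", "variance", "std", "skewness", "kurtosis",
    "energy", "entropy", "min", "max", "range",
)
GLCM_NAMES = (
    "contrast", "correlation", "joint_energy", "joint_entropy", "idm",
    "difference_average", "cluster_shade", "cluster_prominence",
    "maximum_probability", "autocorrelation",
)


def feature_names() -> list[str]:
    """The fixed, ordered 42 voxel-feature column names."""
    names = []
    for m in ("t2", "adc"):
        names += [f"{m}_fo_{s}" for s in FIRST_ORDER_NAMES]
        names += [f"{m}_glcm_{s}" for s in GLCM_NAMES]
    names += ["t2_intensity", "adc_intensity"]
    return names


N_VOXEL_FEATURES = 42


@dataclass
class VoxelFeatureMatrix:
    """Stacked per-voxel feature vectors for one or more patients."""

    matrix: np.ndarray            # (n_voxels, 42)
    coords: np.ndarray            # (n_voxels, 3) voxel indices
    patient_ids: np.ndarray       # (n_voxels,) strings
    names: list[str]
    flagged: np.ndarray           # voxels whose GLCM row was imputed

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != N_VOXEL_FEATURES:
            raise ValueError("voxel feature matrix must have 42 columns")
        if np.isnan(self.matrix).any():
            raise ValueError("voxel feature matrix contains NaN")


def directions_3d() -> np.ndarray:
    """The 13 unique distance-1 offsets of the 26-neighbourhood."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    dirs.append((dx, dy, dz))
    return np.array(dirs, dtype=np.int64)


def directions_2d() -> np.ndarray:
    """The 4 unique in-plane (dz = 0) distance-1 offsets."""
    d = directions_3d()
    return d[d[:, 2] == 0]


def discretise(values: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Equal-width discretisation into levels 1..n_bins over [min, max].

    Constant input maps to level 1 everywhere.  The binning range is the
    full input range (lesion-wide), not any local window's.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretise an empty array")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.ones(values.shape, dtype=np.int64)
    lev = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(lev, 1, n_bins)


def window_first_order(values: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """The 10 first-order statistics of one window (reference path).

    Population variance; skewness/excess-kurtosis 0 by convention when the
    variance vanishes; entropy in bits over an ``n_bins`` equal-width
    histogram of the window's own values.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty window")
    mean = v.mean()
    var = v.var()
    std = np.sqrt(var)
    if var > 0:
        skew = np.mean((v - mean) ** 3) / var ** 1.5
        kurt = np.mean((v - mean) ** 4) / var ** 2 - 3.0
    else:
        skew = kurt = 0.0
    energy = float(np.mean(v ** 2))
    lev = discretise(v, n_bins)
    counts = np.bincount(lev, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / v.size
    entropy = float(-np.sum(p * np.log2(p)))
    return np.array(
        [mean, var, std, skew, kurt, energy, entropy, v.min(), v.max(),
         v.max() - v.min()]
    )


def glcm_statistics(p: np.ndarray) -> np.ndarray:
    """The 10 GLCM statistics of a normalised co-occurrence matrix.

    Levels are taken as 1..N (matrix indices + 1).  When the marginal
    variance vanishes (single occupied level) correlation is defined as 1.
    """
    p = np.asarray(p, dtype=np.float64)
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    if sx * sy > 0:
        corr = float(np.sum(p * (ii - mux) * (jj - muy)) / (sx * sy))
    else:
        corr = 1.0
    joint_energy = float(np.sum(p ** 2))
    nz = p[p > 0]
    joint_entropy = float(-np.sum(nz * np.log2(nz)))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    diff_avg = float(np.sum(p * np.abs(ii - jj)))
    shade = float(np.sum(p * (ii + jj - mux - muy) ** 3))
    prom = float(np.sum(p * (ii + jj - mux - muy) ** 4))
    maxprob = float(p.max())
    autocorr = float(np.sum(p * ii * jj))
    return np.array(
        [contrast, corr, joint_energy, joint_entropy, idm, diff_avg,
         shade, prom, maxprob, autocorr]
    )


def window_glcm(levels_window: np.ndarray, n_bins: int,
                mask_window: np.ndarray | None = None,
                dirs: np.ndarray | None = None) -> np.ndarray:
    """GLCM statistics of one 3-D window (reference path).

    Symmetric co-occurrence at distance 1, pooled over ``dirs`` (default all
    13 3-D directions); pairs with either endpoint outside the mask are
    dropped.  Raises if the window produces no valid pair.
    """
    lev = np.asarray(levels_window)
    msk = np.ones(lev.shape, bool) if mask_window is None else np.asarray(mask_window, bool)
    dirs = directions_3d() if dirs is None else dirs
    counts = np.zeros((n_bins, n_bins))
    for dx, dy, dz in dirs:
        for x in range(lev.shape[0]):
            for y in range(lev.shape[1]):
                for z in range(lev.shape[2]):
                    nx, ny, nz_ = x + dx, y + dy, z + dz
                    if not (0 <= nx < lev.shape[0] and 0 <= ny < lev.shape[1]
                            and 0 <= nz_ < lev.shape[2]):
                        continue
                    if msk[x, y, z] and msk[nx, ny, nz_]:
                        a, b = lev[x, y, z] - 1, lev[nx, ny, nz_] - 1
                        counts[a, b] += 1
                        counts[b, a] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("window yields no valid co-occurrence pair")
    return glcm_statistics(counts / total)


@njit(cache=True)
def _glcm_stats_jit(counts, out):  # pragma: no cover - exercised via wrapper
    n = counts.shape[0]
    total = 0.0
    for a in range(n):
        for b in range(n):
            total += counts[a, b]
    if total <= 0:
        return False
    mux = 0.0
    for a in range(n):
        rowsum = 0.0
        for b in range(n):
            rowsum += counts[a, b]
        mux += (a + 1) * rowsum / total
    sx2 = 0.0
    for a in range(n):
        rowsum = 0.0
        for b in range(n):
            rowsum += counts[a, b]
        sx2 += (a + 1 - mux) ** 2 * rowsum / total
    contrast = 0.0
    corr_num = 0.0
    joint_energy = 0.0
    joint_entropy = 0.0
    idm = 0.0
    diff_avg = 0.0
    shade = 0.0
    prom = 0.0
    maxprob = 0.0
    autocorr = 0.0
    for a in range(n):
        for b in range(n):
            c = counts[a, b]
            if c <= 0:
                continue
            p = c / total
            d = a - b
            s = (a + 1) + (b + 1) - 2.0 * mux
            contrast += p * d * d
            corr_num += p * (a + 1 - mux) * (b + 1 - mux)
            joint_energy += p * p
            joint_entropy -= p * np.log2(p)
            idm += p / (1.0 + d * d)
            diff_avg += p * abs(d)
            shade += p * s ** 3
            prom += p * s ** 4
            if p > maxprob:
                maxprob = p
            autocorr += p * (a + 1) * (b + 1)
    corr = 1.0 if sx2 <= 0 else corr_num / sx2
    out[0] = contrast
    out[1] = corr
    out[2] = joint_energy
    out[3] = joint_entropy
    out[4] = idm
    out[5] = diff_avg
    out[6] = shade
    out[7] = prom
    out[8] = maxprob
    out[9] = autocorr
    return True


@njit(cache=True)
def _voxel_kernel(values, levels, mask, coords, radius, n_bins, dirs):
    """Window first-order + GLCM features for every listed voxel."""
    n = coords.shape[0]
    sx, sy, sz = mask.shape
    out = np.zeros((n, 20))
    valid = np.ones(n, np.bool_)
    counts = np.zeros((n_bins, n_bins))
    hist = np.zeros(n_bins + 1)
    stats = np.zeros(10)
    for row in range(n):
        cx, cy, cz = coords[row, 0], coords[row, 1], coords[row, 2]
        x0, x1 = max(cx - radius, 0), min(cx + radius, sx - 1)
        y0, y1 = max(cy - radius, 0), min(cy + radius, sy - 1)
        z0, z1 = max(cz - radius, 0), min(cz + radius, sz - 1)
        # ---- first order (two-pass central moments) ----
        cnt = 0
        s1 = 0.0
        vmin = 1e300
        vmax = -1e300
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    if mask[x, y, z]:
                        v = values[x, y, z]
                        s1 += v
                        cnt += 1
                        if v < vmin:
                            vmin = v
                        if v > vmax:
                            vmax = v
        mean = s1 / cnt
        m2 = 0.0
        m3 = 0.0
        m4 = 0.0
        energy = 0.0
        for i in range(n_bins + 1):
            hist[i] = 0.0
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    if mask[x, y, z]:
                        v = values[x, y, z]
                        d = v - mean
                        m2 += d * d
                        m3 += d * d * d
                        m4 += d * d * d * d
                        energy += v * v
                        # window-local equal-width histogram for entropy
                        if vmax > vmin:
                            b = int((v - vmin) / (vmax - vmin) * n_bins) + 1
                            if b > n_bins:
                                b = n_bins
                        else:
                            b = 1
                        hist[b] += 1.0
        var = m2 / cnt
        std = np.sqrt(var)
        if var > 0:
            skew = (m3 / cnt) / var ** 1.5
            kurt = (m4 / cnt) / (var * var) - 3.0
        else:
            skew = 0.0
            kurt = 0.0
        entropy = 0.0
        for i in range(1, n_bins + 1):
            if hist[i] > 0:
                p = hist[i] / cnt
                entropy -= p * np.log2(p)
        out[row, 0] = mean
        out[row, 1] = var
        out[row, 2] = std
        out[row, 3] = skew
        out[row, 4] = kurt
        out[row, 5] = energy / cnt
        out[row, 6] = entropy
        out[row, 7] = vmin
        out[row, 8] = vmax
        out[row, 9] = vmax - vmin
        # ---- GLCM ----
        for a in range(n_bins):
            for b in range(n_bins):
                counts[a, b] = 0.0
        for k in range(dirs.shape[0]):
            dx, dy, dz = dirs[k, 0], dirs[k, 1], dirs[k, 2]
            for x in range(x0, x1 + 1):
                for y in range(y0, y1 + 1):
                    for z in range(z0, z1 + 1):
                        nx = x + dx
                        ny = y + dy
                        nz = z + dz
                        if nx < x0 or nx > x1 or ny < y0 or ny > y1 or nz < z0 or nz > z1:
                            continue
                        if mask[x, y, z] and mask[nx, ny, nz]:
                            a = levels[x, y, z] - 1
                            b = levels[nx, ny, nz] - 1
                            counts[a, b] += 1.0
                            counts[b, a] += 1.0
        ok = _glcm_stats_jit(counts, stats)
        if ok:
            for i in range(10):
                out[row, 10 + i] = stats[i]
        else:
            valid[row] = False
    return out, valid


def compute_voxel_features(
    pair: VolumePair,
    kernel_radius: int = 2,
    n_bins: int = 16,
    mode: str = "3d",
) -> VoxelFeatureMatrix:
    """Compute the 42-column voxel feature matrix of one lesion.

    ``mode="2d"`` restricts the co-occurrence directions to the axial plane;
    the window itself stays 3-D.
    """
    if not pair.lesion_mask.any():
        raise ValueError("empty lesion mask")
    coords = masked_coords(pair.lesion_mask)
    dirs = directions_3d() if mode == "3d" else directions_2d()
    mask = np.ascontiguousarray(pair.lesion_mask)
    blocks = []
    flagged = np.zeros(len(coords), bool)
    for vol in (pair.t2, pair.adc):
        vals = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        levels = np.zeros(pair.shape, dtype=np.int64)
        levels[coords[:, 0], coords[:, 1], coords[:, 2]] = discretise(vals, n_bins)
        feats, valid = _voxel_kernel(
            np.ascontiguousarray(vol, dtype=np.float64), levels, mask,
            coords.astype(np.int64), kernel_radius, n_bins, dirs,
        )
        if not valid.all():
            feats = _fill_invalid_glcm(feats, valid, coords)
            flagged |= ~valid
        blocks.append(feats)
    raw_t2 = pair.t2[coords[:, 0], coords[:, 1], coords[:, 2]]
    raw_adc = pair.adc[coords[:, 0], coords[:, 1], coords[:, 2]]
    matrix = np.column_stack(blocks + [raw_t2, raw_adc])
    return VoxelFeatureMatrix(
        matrix=matrix,
        coords=coords,
        patient_ids=np.full(len(coords), pair.patient_id, dtype=object),
        names=feature_names(),
        flagged=flagged,
    )


def _fill_invalid_glcm(feats: np.ndarray, valid: np.ndarray,
                       coords: np.ndarray) -> np.ndarray:
    """Copy GLCM columns from the nearest valid voxel into flagged rows."""
    feats = feats.copy()
    good = np.flatnonzero(valid)
    bad = np.flatnonzero(~valid)
    if len(good) == 0:
        return feats  # nothing to copy from; zeros stand
    for row in bad:
        d = np.sum((coords[good] - coords[row]) ** 2, axis=1)
        feats[row, 10:20] = feats[good[np.argmin(d)], 10:20]
    return feats


def stack_voxel_features(matrices: list[VoxelFeatureMatrix]) -> VoxelFeatureMatrix:
    """Concatenate per-patient voxel matrices into one pooled matrix."""
    if not matrices:
        raise ValueError("no matrices to stack")
    return VoxelFeatureMatrix(
        matrix=np.vstack([m.matrix for m in matrices]),
        coords=np.vstack([m.coords for m in matrices]),
        patient_ids=np.concatenate([m.patient_ids for m in matrices]),
        names=matrices[0].names,
        flagged=np.concatenate([m.flagged for m in matrices]),
    )
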