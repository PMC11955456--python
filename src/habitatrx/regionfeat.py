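"""Region-level radiomics over whole lesions and habitat subregions.

A native implementation of a documented subset of the seven standard
texture/shape feature families (first-order, 2-D and 3-D shape, GLCM,
GLRLM, GLSZM, GLDM, NGTDM), following the usual IBSI-style definitions:
fixed-bin-count discretisation (default 32 levels over the region's own
range), distance-1 co-occurrence and run matrices merged over the 13 unique
3-D directions, 26-connected zones and dependence neighbourhoods.  An
``extractor=`` hook on :func:`build_feature_tables` lets a full external
IBSI extractor be swapped in for the native one.

Shape features are computed once per region (modality-independent); texture
and first-order families are computed per modality (T2, ADC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .image import VolumePair
from .voxelfeat import directions_3d, discretise, glcm_statistics

NGTDM_COARSENESS_CAP = 1e6

FIRSTORDER = (
    "mean", "median", "variance", "skewness", "kurtosis", "energy",
    "entropy", "min", "max", "range", "p10", "p90", "iqr", "rms",
)
GLCM = (
    "contrast", "correlation", "joint_energy", "joint_entropy", "idm",
    "difference_average", "cluster_shade", "cluster_prominence",
    "maximum_probability", "autocorrelation",
)
GLRLM = ("sre", "lre", "gln", "rln", "rp", "lglre", "hglre", "srlgle")
GLSZM = ("sae", "lae", "gln", "zsn", "zp", "lglze", "hglze")
GLDM = ("sde", "lde", "gln", "dn", "lgle", "hgle", "dependence_entropy")
NGTDM = ("coarseness", "contrast", "busyness", "complexity", "strength")
SHAPE3D = (
    "volume", "surface_area", "sphericity", "max_diameter",
    "major_axis", "minor_axis", "least_axis", "elongation", "flatness",
)
SHAPE2D = ("area", "perimeter", "circularity", "max_diameter",
           "major_axis", "minor_axis")


class RegionTooSmallError(ValueError):
    """Raised when a region has too few voxels for stable texture features."""


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_region(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    mean = v.mean()
    var = v.var()
    if var > 0:
        skew = float(np.mean((v - mean) ** 3) / var ** 1.5)
        kurt = float(np.mean((v - mean) ** 4) / var ** 2 - 3.0)
    else:
        skew = kurt = 0.0
    lev = discretise(v, n_bins)
    counts = np.bincount(lev, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / v.size
    return {
        "mean": float(mean),
        "median": float(np.median(v)),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(v ** 2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "rms": float(np.sqrt(np.mean(v ** 2))),
    }


# ---------------------------------------------------------------------------
# grey-level matrices (all on a level box: int array, 0 = outside region)
# ---------------------------------------------------------------------------

def _level_box(values_box: np.ndarray, mask_box: np.ndarray, n_bins: int) -> np.ndarray:
    lev = np.zeros(mask_box.shape, dtype=np.int64)
    lev[mask_box] = discretise(values_box[mask_box], n_bins)
    return lev


def glcm_region(level_box: np.ndarray, n_bins: int) -> dict[str, float]:
    """Merged symmetric distance-1 co-occurrence statistics of a region."""
    counts = np.zeros((n_bins, n_bins))
    for dx, dy, dz in directions_3d():
        a = level_box[max(dx, 0) or None: min(dx, 0) or None,
                      max(dy, 0) or None: min(dy, 0) or None,
                      max(dz, 0) or None: min(dz, 0) or None]
        b = level_box[max(-dx, 0) or None: min(-dx, 0) or None,
                      max(-dy, 0) or None: min(-dy, 0) or None,
                      max(-dz, 0) or None: min(-dz, 0) or None]
        ok = (a > 0) & (b > 0)
        if ok.any():
            np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
            np.add.at(counts, (b[ok] - 1, a[ok] - 1), 1.0)
    total = counts.sum()
    if total == 0:
        stats = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0])
    else:
        stats = glcm_statistics(counts / total)
    return dict(zip(GLCM, (float(s) for s in stats)))


@njit(cache=True)
def _glrlm_kernel(levels, dirs, n_bins, max_len):  # pragma: no cover
    sx, sy, sz = levels.shape
    mat = np.zeros((n_bins, max_len))
    for k in range(dirs.shape[0]):
        dx, dy, dz = dirs[k, 0], dirs[k, 1], dirs[k, 2]
        for x in range(sx):
            for y in range(sy):
                for z in range(sz):
                    g = levels[x, y, z]
                    if g == 0:
                        continue
                    px, py, pz = x - dx, y - dy, z - dz
                    if (0 <= px < sx and 0 <= py < sy and 0 <= pz < sz
                            and levels[px, py, pz] == g):
                        continue  # not a run start
                    length = 1
                    nx, ny, nz = x + dx, y + dy, z + dz
                    while (0 <= nx < sx and 0 <= ny < sy and 0 <= nz < sz
                           and levels[nx, ny, nz] == g):
                        length += 1
                        nx += dx
                        ny += dy
                        nz += dz
                    if length > max_len:
                        length = max_len
                    mat[g - 1, length - 1] += 1.0
    return mat


def glrlm_region(level_box: np.ndarray, n_bins: int) -> dict[str, float]:
    """Run-length statistics merged over the 13 directions."""
    max_len = max(level_box.shape) * 2
    mat = _glrlm_kernel(level_box, directions_3d(), n_bins, max_len)
    n_runs = mat.sum()
    n_vox = int((level_box > 0).sum())
    if n_runs == 0:
        return {k: 0.0 for k in GLRLM}
    i = np.arange(1, n_bins + 1)[:, None].astype(float)
    j = np.arange(1, max_len + 1)[None, :].astype(float)
    return {
        "sre": float(np.sum(mat / j ** 2) / n_runs),
        "lre": float(np.sum(mat * j ** 2) / n_runs),
        "gln": float(np.sum(mat.sum(axis=1) ** 2) / n_runs),
        "rln": float(np.sum(mat.sum(axis=0) ** 2) / n_runs),
        "rp": float(n_runs / (n_vox * len(directions_3d()))),
        "lglre": float(np.sum(mat / i ** 2) / n_runs),
        "hglre": float(np.sum(mat * i ** 2) / n_runs),
        "srlgle": float(np.sum(mat / (i ** 2 * j ** 2)) / n_runs),
    }


def glszm_region(level_box: np.ndarray, n_bins: int) -> dict[str, float]:
    """Size-zone statistics with 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    sizes: list[tuple[int, int]] = []  # (level, zone size)
    for g in range(1, n_bins + 1):
        blob = level_box == g
        if not blob.any():
            continue
        lab, nlab = ndimage.label(blob, structure=structure)
        counts = np.bincount(lab.ravel())[1:]
        sizes += [(g, int(s)) for s in counts if s > 0]
    if not sizes:
        return {k: 0.0 for k in GLSZM}
    max_size = max(s for _, s in sizes)
    mat = np.zeros((n_bins, max_size))
    for g, s in sizes:
        mat[g - 1, s - 1] += 1.0
    nz = mat.sum()
    n_vox = int((level_box > 0).sum())
    i = np.arange(1, n_bins + 1)[:, None].astype(float)
    j = np.arange(1, max_size + 1)[None, :].astype(float)
    return {
        "sae": float(np.sum(mat / j ** 2) / nz),
        "lae": float(np.sum(mat * j ** 2) / nz),
        "gln": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "zsn": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "zp": float(nz / n_vox),
        "lglze": float(np.sum(mat / i ** 2) / nz),
        "hglze": float(np.sum(mat * i ** 2) / nz),
    }


def _neighbor_shifts():
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    out.append((dx, dy, dz))
    return out


def _shifted(box: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """box sampled at v + d, zero-padded outside."""
    out = np.zeros_like(box)
    src = tuple(slice(max(dd, 0), box.shape[a] + min(dd, 0)) for a, dd in enumerate(d))
    dst = tuple(slice(max(-dd, 0), box.shape[a] + min(-dd, 0)) for a, dd in enumerate(d))
    out[dst] = box[src]
    return out


def gldm_region(level_box: np.ndarray, n_bins: int, alpha: int = 0) -> dict[str, float]:
    """Dependence-matrix statistics (26-neighbourhood, tolerance ``alpha``)."""
    inmask = level_box > 0
    dep = np.zeros(level_box.shape, dtype=np.int64)
    for d in _neighbor_shifts():
        nb = _shifted(level_box, d)
        dep += (inmask & (nb > 0) & (np.abs(nb - level_box) <= alpha)).astype(np.int64)
    levels = level_box[inmask]
    deps = dep[inmask] + 1  # dependence counts indexed from 1 (self included)
    max_dep = int(deps.max())
    mat = np.zeros((n_bins, max_dep))
    np.add.at(mat, (levels - 1, deps - 1), 1.0)
    nd = mat.sum()
    i = np.arange(1, n_bins + 1)[:, None].astype(float)
    j = np.arange(1, max_dep + 1)[None, :].astype(float)
    p = mat / nd
    pn = p[p > 0]
    return {
        "sde": float(np.sum(mat / j ** 2) / nd),
        "lde": float(np.sum(mat * j ** 2) / nd),
        "gln": float(np.sum(mat.sum(axis=1) ** 2) / nd),
        "dn": float(np.sum(mat.sum(axis=0) ** 2) / nd),
        "lgle": float(np.sum(mat / i ** 2) / nd),
        "hgle": float(np.sum(mat * i ** 2) / nd),
        "dependence_entropy": float(-np.sum(pn * np.log2(pn))),
    }


def ngtdm_region(level_box: np.ndarray, n_bins: int) -> dict[str, float]:
    """Neighbourhood grey-tone difference statistics."""
    inmask = level_box > 0
    nb_sum = np.zeros(level_box.shape, dtype=np.float64)
    nb_cnt = np.zeros(level_box.shape, dtype=np.float64)
    for d in _neighbor_shifts():
        nb = _shifted(level_box, d)
        has = nb > 0
        nb_sum += np.where(has, nb, 0.0)
        nb_cnt += has.astype(float)
    use = inmask & (nb_cnt > 0)
    avg = np.zeros_like(nb_sum)
    avg[use] = nb_sum[use] / nb_cnt[use]
    n_total = int(use.sum())
    if n_total == 0:
        return {k: 0.0 for k in NGTDM}
    s = np.zeros(n_bins)
    n_i = np.zeros(n_bins)
    for g in range(1, n_bins + 1):
        sel = use & (level_box == g)
        n_i[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - avg[sel]).sum()
    p = n_i / n_total
    present = np.flatnonzero(p > 0)
    ngp = len(present)
    lv = present + 1.0
    ps, ss = p[present], s[present]
    sum_ps = float(np.sum(ps * ss))
    coarseness = NGTDM_COARSENESS_CAP if sum_ps < 1 / NGTDM_COARSENESS_CAP \
        else min(1.0 / sum_ps, NGTDM_COARSENESS_CAP)
    if ngp > 1:
        dif2 = (lv[:, None] - lv[None, :]) ** 2
        contrast = float(np.sum(ps[:, None] * ps[None, :] * dif2)
                         / (ngp * (ngp - 1)) * ss.sum() / n_total)
        denom = float(np.sum(np.abs(lv[:, None] * ps[:, None] - lv[None, :] * ps[None, :])))
        busyness = sum_ps / denom if denom > 0 else 0.0
        pp = ps[:, None] + ps[None, :]
        complexity = float(np.sum(np.abs(lv[:, None] - lv[None, :])
                                  * (ps[:, None] * ss[:, None] + ps[None, :] * ss[None, :])
                                  / pp) / n_total)
        strength = float(np.sum(pp * dif2) / ss.sum()) if ss.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _max_diameter(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    try:
        hull = ConvexHull(points)
        pts = points[hull.vertices]
    except Exception:  # degenerate (coplanar/collinear) point sets
        pts = points if len(points) <= 2000 else points[:: len(points) // 2000 + 1]
    return float(pdist(pts).max())


def shape3d_region(mask_box: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """3-D shape descriptors: voxel volume, face-counted surface, PCA axes."""
    n = int(mask_box.sum())
    voxvol = float(np.prod(spacing))
    volume = n * voxvol
    # surface area by counting exposed voxel faces
    area = 0.0
    face = (spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1])
    for axis in range(3):
        for sign in (-1, 1):
            nb = _shifted(mask_box.astype(np.int8),
                          tuple(sign if a == axis else 0 for a in range(3)))
            area += float(((mask_box) & (nb == 0)).sum()) * face[axis]
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area) if area > 0 else 0.0
    pts = np.argwhere(mask_box).astype(float) * np.asarray(spacing)
    if n > 1:
        cov = np.cov(pts.T)
        eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    return {
        "volume": volume,
        "surface_area": area,
        "sphericity": sphericity,
        "max_diameter": _max_diameter(pts),
        "major_axis": major,
        "minor_axis": minor,
        "least_axis": least,
        "elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }


def shape2d_region(mask_box: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """2-D shape descriptors on the largest-area axial slice."""
    counts = mask_box.sum(axis=(0, 1))
    z = int(np.argmax(counts))
    sl = mask_box[:, :, z]
    px = spacing[0] * spacing[1]
    area = float(sl.sum()) * px
    perim = float(measure.perimeter(sl)) * float(np.sqrt(px))
    circ = float(4 * np.pi * area / perim ** 2) if perim > 0 else 1.0
    pts = np.argwhere(sl).astype(float) * np.asarray(spacing[:2])
    if len(pts) > 1:
        eig = np.sort(np.clip(np.linalg.eigvalsh(np.cov(pts.T)), 0, None))[::-1]
    else:
        eig = np.zeros(2)
    return {
        "area": area,
        "perimeter": perim,
        "circularity": min(circ, 1.5),
        "max_diameter": _max_diameter(pts),
        "major_axis": float(4 * np.sqrt(eig[0])),
        "minor_axis": float(4 * np.sqrt(eig[1])),
    }


# ---------------------------------------------------------------------------
# region and table assembly
# ---------------------------------------------------------------------------

TEXTURE_FAMILIES = {
    "firstorder": FIRSTORDER, "glcm": GLCM, "glrlm": GLRLM,
    "glszm": GLSZM, "gldm": GLDM, "ngtdm": NGTDM,
}


def region_feature_names() -> list[tuple[str, str, str]]:
    """(modality, family, feature) triples in fixed extraction order."""
    out = []
    for modality in ("T2", "ADC"):
        for family, feats in TEXTURE_FAMILIES.items():
            out += [(modality, family, f) for f in feats]
    out += [("shape", "shape3D", f) for f in SHAPE3D]
    out += [("shape", "shape2D", f) for f in SHAPE2D]
    return out


def extract_region_features(
    pair: VolumePair,
    region_mask: np.ndarray,
    n_bins: int = 32,
    min_region_voxels: int = 5,
) -> dict[tuple[str, str, str], float]:
    """All families for one region of one patient.

    Returns ``{(modality, family, feature): value}``; raises
    :class:`RegionTooSmallError` below ``min_region_voxels`` voxels so the
    caller can impute.
    """
    region_mask = np.asarray(region_mask).astype(bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("empty region mask")
    if n < min_region_voxels:
        raise RegionTooSmallError(f"region has {n} < {min_region_voxels} voxels")
    lo = np.argwhere(region_mask).min(axis=0)
    hi = np.argwhere(region_mask).max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask_box = region_mask[box]
    out: dict[tuple[str, str, str], float] = {}
    for modality, vol in (("T2", pair.t2), ("ADC", pair.adc)):
        vals_box = vol[box]
        values = vals_box[mask_box]
        lev = _level_box(vals_box, mask_box, n_bins)
        fam_values = {
            "firstorder": first_order_region(values, n_bins),
            "glcm": glcm_region(lev, n_bins),
            "glrlm": glrlm_region(lev, n_bins),
            "glszm": glszm_region(lev, n_bins),
            "gldm": gldm_region(lev, n_bins),
            "ngtdm": ngtdm_region(lev, n_bins),
        }
        for family, feats in fam_values.items():
            for name, value in feats.items():
                out[(modality, family, name)] = value
    for family, feats in (("shape3D", shape3d_region(mask_box, pair.spacing)),
                          ("shape2D", shape2d_region(mask_box, pair.spacing))):
        for name, value in feats.items():
            out[("shape", family, name)] = value
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite features: {bad}")
    return out


@dataclass
class FeatureTable:
    """Patients x named region features, with per-cell missingness reasons."""

    frame: pd.DataFrame
    manifest: dict[str, dict] = field(default_factory=dict)
    missing: dict[tuple[str, str], str] = field(default_factory=dict)  # (patient, region) -> reason

    def impute_training_median(self, train_ids: list[str]) -> "FeatureTable":
        """Fill flagged cells with the training-set column median."""
        frame = self.frame.copy()
        med = frame.loc[frame.index.intersection(train_ids)].median()
        frame = frame.fillna(med)
        return FeatureTable(frame=frame, manifest=self.manifest, missing=self.missing)


def _colname(region: str, modality: str, family: str, feature: str) -> str:
    return f"{region}_{modality}_{family}_{feature}"


def build_feature_tables(
    pairs: list[VolumePair],
    habitat_maps: list,
    n_bins: int = 32,
    min_region_voxels: int = 5,
    extractor=None,
) -> tuple[FeatureTable, FeatureTable]:
    """Whole-lesion and per-habitat feature tables for a cohort.

    ``habitat_maps`` holds one :class:`~habitatrx.habitats.HabitatMap` per
    pair.  Habitat regions a patient lacks (or that are below the size
    floor) are left NaN here, recorded in ``missing``, and filled with the
    training median by :meth:`FeatureTable.impute_training_median`.
    ``extractor(pair, region_mask)`` may replace the native feature set.
    """
    extract = extractor or (
        lambda pair, m: extract_region_features(pair, m, n_bins, min_region_voxels)
    )
    k = int(max(hm.labels.max() for hm in habitat_maps))
    regions = ["whole"] + [f"hab{h}" for h in range(1, k + 1)]
    whole_rows, habitat_rows = {}, {}
    missing: dict[tuple[str, str], str] = {}
    for pair, hm in zip(pairs, habitat_maps):
        whole_rows[pair.patient_id] = {
            _colname("whole", *kk): v for kk, v in extract(pair, pair.lesion_mask).items()
        }
        hrow = {}
        for h in range(1, k + 1):
            mask = hm.labels == h
            try:
                feats = extract(pair, mask)
                hrow.update({_colname(f"hab{h}", *kk): v for kk, v in feats.items()})
            except (RegionTooSmallError, ValueError) as exc:
                missing[(pair.patient_id, f"hab{h}")] = str(exc)
                hrow.update({_colname(f"hab{h}", *kk): np.nan
                             for kk in region_feature_names()})
        habitat_rows[pair.patient_id] = hrow
    manifest = {}
    for region in regions:
        for modality, family, feat in region_feature_names():
            manifest[_colname(region, modality, family, feat)] = {
                "region": region, "modality": modality, "family": family,
                "feature": feat, "n_bins": n_bins,
            }
    whole = FeatureTable(frame=pd.DataFrame.from_dict(whole_rows, orient="index"),
                         manifest={c: m for c, m in manifest.items() if m["region"] == "whole"})
    habitat = FeatureTable(
        frame=pd.DataFrame.from_dict(habitat_rows, orient="index"),
        manifest={c: m for c, m in manifest.items() if m["region"] != "whole"},
        missing=missing,
    )
    return whole, habitat
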