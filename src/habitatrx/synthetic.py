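"""Synthetic bp-MRI phantom cohorts with known habitat structure.

The patient cohort behind the analysis is not publicly deposited, so this
module generates phantoms that carry the statistical structure the method
assumes: each lesion is composed of ``k_true`` spatially contiguous texture
habitats, the habitat *composition* differs between clinically significant
(csPCa, Gleason >= 3+4) and non-significant (Gleason 3+3) lesions, and the
clinical covariates are calibrated to published per-class median/(Q1,Q3)
summaries.  Every phantom comes with its ground-truth habitat label map, so
clustering and classification stages can be tested as parameter-recovery
experiments.

Seeding is counter-based: patient ``i`` of a cohort with master seed ``s``
draws from ``SeedSequence(s, spawn_key=(1, i))`` and the clinical table from
``SeedSequence(s, spawn_key=(0,))``; the rule is recorded in the cohort
manifest.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm, truncnorm

from .config import ClinicalSpec, ClassClinicalSpec, PhantomSpec, QuartileSummary
from .image import VolumePair, save_nifti

PV_ELLIPSOID_FACTOR = 0.52  # prostate volume = width * length * height * 0.52

CLINICAL_COLUMNS = [
    "patient_id", "age", "width", "length", "height", "PV",
    "tPSA", "fPSA", "f_t_ratio", "PSAD", "gleason", "label",
]

_Z75 = norm.ppf(0.75)


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and pathology label."""

    patient_id: str
    age: float
    width: float
    length: float
    height: float
    pv: float
    tpsa: float
    fpsa: float
    gleason: int
    label: str  # "csPCa" or "non-csPCa"

    @property
    def f_t_ratio(self) -> float:
        return self.fpsa / self.tpsa

    @property
    def psad(self) -> float:
        return self.tpsa / self.pv


@dataclass
class GroundTruth:
    """True generative state of one phantom lesion."""

    habitat_labels: np.ndarray  # int volume, 0 outside lesion, 1..k inside
    label: str
    proportions: np.ndarray  # realised habitat fractions, sums to 1


@dataclass
class Cohort:
    """Phantom volumes, ground truth and the clinical table of one cohort."""

    pairs: list[VolumePair]
    truths: list[GroundTruth]
    clinical: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return (self.clinical["label"] == "csPCa").to_numpy().astype(int)


def compute_prostate_volume(width: float, length: float, height: float) -> float:
    """Ellipsoid prostate volume (mL) from the three axes in cm."""
    if min(width, length, height) <= 0:
        raise ValueError("prostate dimensions must be positive")
    return width * length * height * PV_ELLIPSOID_FACTOR


def compute_psad(tpsa: float, pv: float) -> float:
    """PSA density: total PSA divided by prostate volume."""
    if pv <= 0:
        raise ValueError("prostate volume must be positive")
    return tpsa / pv


def fit_lognormal_from_quartiles(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """Calibrate a lognormal to a median/(Q1,Q3) summary.

    ``mu = ln(median)`` fixes the median exactly; ``sigma`` is the least
    squares fit of the two quartile equations ``ln q = mu -/+ z75*sigma``,
    which has the closed form ``ln(q3/q1) / (2*z75)``.
    """
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"quartiles must satisfy 0 < q1 < median < q3, got ({q1}, {median}, {q3})"
        )
    mu = float(np.log(median))
    sigma = float(np.log(q3 / q1) / (2.0 * _Z75))
    return mu, sigma


def _truncnorm_from_quartiles(
    q: QuartileSummary, bounds: tuple[float, float], rng: np.random.Generator, n: int
) -> np.ndarray:
    loc = q.median
    scale = max((q.q3 - q.q1) / (2.0 * _Z75), 1e-6)
    a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _draw_class_records(
    cls: ClassClinicalSpec,
    n: int,
    label: str,
    spec: ClinicalSpec,
    rng: np.random.Generator,
    id_offset: int,
) -> list[ClinicalRecord]:
    mu_pv, sd_pv = fit_lognormal_from_quartiles(cls.pv.median, cls.pv.q1, cls.pv.q3)
    mu_t, sd_t = fit_lognormal_from_quartiles(cls.tpsa.median, cls.tpsa.q1, cls.tpsa.q3)
    mu_f, sd_f = fit_lognormal_from_quartiles(cls.fpsa.median, cls.fpsa.q1, cls.fpsa.q3)

    ages = _truncnorm_from_quartiles(cls.age, spec.age_bounds, rng, n)
    pvs = np.exp(rng.normal(mu_pv, sd_pv, n))
    tpsas = np.exp(rng.normal(mu_t, sd_t, n))

    if label == "csPCa":
        w = np.asarray(spec.gleason_weights_cs, dtype=float)
        gleasons = rng.choice(np.arange(7, 11), size=n, p=w / w.sum())
    else:
        gleasons = np.full(n, 6)

    records = []
    for i in range(n):
        # free PSA must stay below total PSA (ratio in (0, 1])
        fpsa = float(np.exp(rng.normal(mu_f, sd_f)))
        for _ in range(20):
            if fpsa < tpsas[i]:
                break
            fpsa = float(np.exp(rng.normal(mu_f, sd_f)))
        fpsa = min(fpsa, 0.95 * tpsas[i])
        # factor PV into axes with a log-normal anisotropy jitter; the
        # ellipsoid identity PV = w*l*h*0.52 then holds exactly
        base = (pvs[i] / PV_ELLIPSOID_FACTOR) ** (1.0 / 3.0)
        width = base * float(np.exp(rng.normal(0.0, 0.08)))
        height = base * float(np.exp(rng.normal(-0.05, 0.08)))
        length = pvs[i] / PV_ELLIPSOID_FACTOR / (width * height)
        records.append(
            ClinicalRecord(
                patient_id=f"P{id_offset + i:04d}",
                age=float(ages[i]),
                width=width,
                length=length,
                height=height,
                pv=float(pvs[i]),
                tpsa=float(tpsas[i]),
                fpsa=fpsa,
                gleason=int(gleasons[i]),
                label=label,
            )
        )
    return records


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "width": r.width,
            "length": r.length,
            "height": r.height,
            "PV": r.pv,
            "tPSA": r.tpsa,
            "fPSA": r.fpsa,
            "f_t_ratio": r.f_t_ratio,
            "PSAD": r.psad,
            "gleason": r.gleason,
            "label": r.label,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def generate_clinical_table(
    spec: ClinicalSpec | None = None, seed: int | np.random.SeedSequence = 0
) -> list[ClinicalRecord]:
    """Draw a class-balanced-by-spec clinical cohort.

    PSA-type variables are lognormal (matching the right-skewed published
    summaries), age truncated normal; PSAD and the free/total ratio are
    computed from the identity formulas, never drawn independently.
    """
    spec = spec or ClinicalSpec()
    if spec.n_cs < 1 or spec.n_noncs < 1:
        raise ValueError("both classes need at least one patient")
    rng = np.random.default_rng(seed)
    recs = _draw_class_records(spec.cs, spec.n_cs, "csPCa", spec, rng, 0)
    recs += _draw_class_records(
        spec.noncs, spec.n_noncs, "non-csPCa", spec, rng, spec.n_cs
    )
    return recs


# ---------------------------------------------------------------------------
# phantom images
# ---------------------------------------------------------------------------

_NEIGHBORS6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def _grow_habitats(
    lesion_idx: np.ndarray,
    shape: tuple[int, int, int],
    proportions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition lesion voxels into contiguous blobs with given quotas.

    Quota-constrained multi-seed region growing: each habitat grows from a
    far-apart seed, always consuming its cheapest frontier voxel (priority =
    smoothed noise + jitter), and the habitat furthest below its quota moves
    next.  This yields exact-size, connected subregions.
    """
    k = len(proportions)
    n = len(lesion_idx)
    inside = np.full(shape, -1, dtype=np.int32)
    for row, (x, y, z) in enumerate(lesion_idx):
        inside[x, y, z] = row

    # smoothed noise priority field over the bounding box
    lo = lesion_idx.min(axis=0)
    hi = lesion_idx.max(axis=0) + 1
    box = rng.standard_normal(tuple(hi - lo))
    box = ndimage.gaussian_filter(box, sigma=2.0)
    noise_prio = box[tuple((lesion_idx - lo).T)] + 0.05 * rng.standard_normal(n)
    noise_prio /= max(noise_prio.std(), 1e-9)

    # farthest-point seeds
    seeds = [int(rng.integers(n))]
    d2 = np.sum((lesion_idx - lesion_idx[seeds[0]]) ** 2, axis=1).astype(float)
    for _ in range(k - 1):
        seeds.append(int(np.argmax(d2)))
        d2 = np.minimum(d2, np.sum((lesion_idx - lesion_idx[seeds[-1]]) ** 2, axis=1))

    # priority = distance to own seed (compact blobs, small interface area)
    # + noise (irregular borders)
    extent = float(np.linalg.norm(hi - lo))
    dist_to_seed = [
        np.sqrt(np.sum((lesion_idx - lesion_idx[s]) ** 2, axis=1)) / extent
        for s in seeds
    ]

    quotas = np.maximum(np.round(proportions * n).astype(int), 1)
    quotas[np.argmax(quotas)] += n - quotas.sum()  # exact total

    labels = np.zeros(n, dtype=np.int32)
    heaps: list[list] = [[] for _ in range(k)]
    filled = np.zeros(k, dtype=int)
    prio = [3.0 * dist_to_seed[h] + 0.15 * noise_prio for h in range(k)]
    for h, s in enumerate(seeds):
        heapq.heappush(heaps[h], (prio[h][s], s))

    def push_neighbors(h: int, row: int) -> None:
        x, y, z = lesion_idx[row]
        for dx, dy, dz in _NEIGHBORS6:
            q = inside[x + dx, y + dy, z + dz] if (
                0 <= x + dx < shape[0] and 0 <= y + dy < shape[1] and 0 <= z + dz < shape[2]
            ) else -1
            if q >= 0 and labels[q] == 0:
                heapq.heappush(heaps[h], (prio[h][q], q))

    assigned = 0
    while assigned < n:
        # habitat most behind on its quota that still has a frontier
        order = np.argsort(filled / quotas)
        moved = False
        for h in order:
            if filled[h] >= quotas[h]:
                continue
            while heaps[h]:
                _, row = heapq.heappop(heaps[h])
                if labels[row] == 0:
                    labels[row] = h + 1
                    filled[h] += 1
                    assigned += 1
                    push_neighbors(h, row)
                    moved = True
                    break
            if moved:
                break
        if not moved:
            # frontiers exhausted (quota unreachable): attach leftovers to
            # the nearest already-labelled habitat
            left = np.flatnonzero(labels == 0)
            done = np.flatnonzero(labels > 0)
            for row in left:
                d = np.sum((lesion_idx[done] - lesion_idx[row]) ** 2, axis=1)
                labels[row] = labels[done[np.argmin(d)]]
                assigned += 1

    vol = np.zeros(shape, dtype=np.int16)
    vol[tuple(lesion_idx.T)] = labels
    return vol


def _grf(shape: tuple[int, ...], mean: float, variance: float, corr_len: float,
         rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field with the stated pointwise moments."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_len)
    sd = f.std()
    if sd < 1e-12:
        return np.full(shape, mean)
    return mean + np.sqrt(variance) * f / sd


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-order polynomial bias, mean ~1, range ~±amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    ax = [np.linspace(-1, 1, s) for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    c = rng.normal(0, 1, 9)
    poly = (c[0] * gx + c[1] * gy + c[2] * gz + c[3] * gx * gy + c[4] * gx * gz
            + c[5] * gy * gz + c[6] * gx**2 + c[7] * gy**2 + c[8] * gz**2)
    poly -= poly.mean()
    peak = np.abs(poly).max()
    if peak > 1e-12:
        poly *= amplitude / peak
    return np.clip(1.0 + poly, 0.2, None)


def generate_phantom(
    spec: PhantomSpec,
    patient_seed: int | np.random.SeedSequence,
    is_cs: bool = True,
    patient_id: str = "P0000",
) -> tuple[VolumePair, GroundTruth]:
    """Generate one phantom bp-MRI pair with ground-truth habitats.

    The lesion is an ellipsoid inside an ellipsoidal gland, partitioned into
    ``k_true`` contiguous habitats whose mixture is a Dirichlet draw around
    the class mixture; each habitat's voxels come from its Gaussian random
    field per modality; optional multiplicative polynomial bias and additive
    noise are applied afterwards.
    """
    rng = np.random.default_rng(patient_seed)
    shape = spec.image_shape
    k = spec.k_true

    # gland: centred ellipsoid filling ~60% of the FOV
    half = np.array([shape[0] * 0.38, shape[1] * 0.38, shape[2] * 0.36])
    centre = np.array(shape) / 2.0 - 0.5
    gi = np.indices(shape).astype(float)
    gland = (
        ((gi[0] - centre[0]) / half[0]) ** 2
        + ((gi[1] - centre[1]) / half[1]) ** 2
        + ((gi[2] - centre[2]) / half[2]) ** 2
    ) <= 1.0

    # lesion ellipsoid, jittered centre, sized to hold the habitats
    for attempt in range(10):
        ax = rng.uniform(*spec.lesion_halfaxis_xy)
        ay = rng.uniform(*spec.lesion_halfaxis_xy)
        az = rng.uniform(*spec.lesion_halfaxis_z)
        off = rng.uniform(-0.25, 0.25, 3) * half
        lc = centre + off
        lesion = (
            ((gi[0] - lc[0]) / ax) ** 2
            + ((gi[1] - lc[1]) / ay) ** 2
            + ((gi[2] - lc[2]) / az) ** 2
        ) <= 1.0
        lesion &= gland
        if lesion.sum() >= 30 * k:
            break
    else:
        raise RuntimeError(f"lesion too small to host {k} habitats")

    lesion_idx = np.argwhere(lesion)

    mixture = np.asarray(spec.mixture_cs if is_cs else spec.mixture_noncs)
    proportions = rng.dirichlet(mixture * spec.mixture_concentration)
    habitat_vol = _grow_habitats(lesion_idx, shape, proportions, rng)
    realised = np.array([(habitat_vol == h + 1).sum() for h in range(k)], float)
    realised /= realised.sum()

    # compose modality volumes: background gland + per-habitat fields
    t2 = np.where(gland, 420.0, 60.0) + 15.0 * rng.standard_normal(shape)
    adc = np.where(gland, 1600.0, 600.0) + 40.0 * rng.standard_normal(shape)
    lo = lesion_idx.min(axis=0)
    hi = lesion_idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    box_shape = tuple(hi - lo)
    # smooth abundance weights: habitats blend over a transition zone of
    # ~blend_sigma voxels instead of meeting at a step edge
    weights = np.stack([
        ndimage.gaussian_filter((habitat_vol[box] == h + 1).astype(float),
                                spec.blend_sigma)
        for h in range(k)
    ])
    weights /= np.maximum(weights.sum(axis=0), 1e-12)
    in_lesion = lesion[box]
    sign = -1.0 if is_cs else 1.0
    adc_shift = [sign * c for c in spec.class_adc_contrast]
    for vol, texs, shifts in ((t2, spec.t2_textures, [0.0] * k),
                              (adc, spec.adc_textures, adc_shift)):
        mix = np.zeros(box_shape)
        for h in range(k):
            f = _grf(box_shape, texs[h].mean + shifts[h], texs[h].variance,
                     texs[h].corr_len, rng)
            mix += weights[h] * f
        vol[box][in_lesion] = mix[in_lesion]

    # finite scanner resolution: blur softens habitat interfaces into
    # gradients instead of step edges
    if spec.psf_sigma > 0:
        t2 = ndimage.gaussian_filter(t2, spec.psf_sigma)
        adc = ndimage.gaussian_filter(adc, spec.psf_sigma)
    for vol, texs in ((t2, spec.t2_textures), (adc, spec.adc_textures)):
        mean_range = max(t.mean for t in texs) - min(t.mean for t in texs)
        if spec.noise_sd > 0:
            vol += spec.noise_sd * mean_range * rng.standard_normal(shape)

    bias = _bias_field(shape, spec.bias_amplitude, rng)
    t2 *= bias * float(np.exp(rng.normal(0.0, spec.gain_sd_t2)))
    adc *= bias * float(np.exp(rng.normal(0.0, spec.gain_sd_adc)))
    np.clip(t2, 1.0, None, out=t2)
    np.clip(adc, 1.0, None, out=adc)

    pair = VolumePair(
        t2=t2, adc=adc, spacing=spec.spacing, lesion_mask=lesion,
        patient_id=patient_id, gland_mask=gland,
    )
    truth = GroundTruth(
        habitat_labels=habitat_vol,
        label="csPCa" if is_cs else "non-csPCa",
        proportions=realised,
    )
    return pair, truth


def generate_cohort(
    phantom_spec: PhantomSpec | None = None,
    clinical_spec: ClinicalSpec | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a full phantom cohort: one volume pair per clinical record."""
    phantom_spec = phantom_spec or PhantomSpec()
    clinical_spec = clinical_spec or ClinicalSpec()
    records = generate_clinical_table(
        clinical_spec, np.random.SeedSequence(seed, spawn_key=(0,))
    )
    pairs, truths = [], []
    for i, rec in enumerate(records):
        pair, truth = generate_phantom(
            phantom_spec,
            np.random.SeedSequence(seed, spawn_key=(1, i)),
            is_cs=(rec.label == "csPCa"),
            patient_id=rec.patient_id,
        )
        pairs.append(pair)
        truths.append(truth)
    manifest = {
        "seed": seed,
        "seed_rule": "clinical: SeedSequence(seed, spawn_key=(0,)); "
                     "patient i: SeedSequence(seed, spawn_key=(1, i))",
        "n_cs": clinical_spec.n_cs,
        "n_noncs": clinical_spec.n_noncs,
        "k_true": phantom_spec.k_true,
    }
    return Cohort(pairs, truths, records_to_frame(records), manifest)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: NIfTI volumes/masks/truth + clinical CSV."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair, truth in zip(cohort.pairs, cohort.truths):
        pdir = out / pair.patient_id
        pdir.mkdir(exist_ok=True)
        save_nifti(pair.t2.astype(np.float32), pair.spacing, pdir / "t2.nii.gz")
        save_nifti(pair.adc.astype(np.float32), pair.spacing, pdir / "adc.nii.gz")
        save_nifti(pair.lesion_mask, pair.spacing, pdir / "lesion_mask.nii.gz")
        save_nifti(truth.habitat_labels, pair.spacing, pdir / "habitat_truth.nii.gz")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2))
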