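"""Validated configuration objects for the phantom generator and the pipeline.

All knobs that the analysis exposes live here so that a run is fully
described by one serialisable object (written into the run manifest).
Unknown keys are rejected everywhere (``extra="forbid"``).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator


class HabitatTexture(BaseModel):
    """Gaussian-random-field parameters of one habitat, one modality.

    ``corr_len`` is the Gaussian smoothing length in voxels; larger values
    give coarser, more slowly varying texture.
    """

    model_config = ConfigDict(extra="forbid")

    mean: float
    variance: float = Field(gt=0)
    corr_len: float = Field(gt=0)


class QuartileSummary(BaseModel):
    """A median/(Q1,Q3) summary used to calibrate a generator."""

    model_config = ConfigDict(extra="forbid")

    median: float
    q1: float
    q3: float

    @model_validator(mode="after")
    def _ordered(self) -> "QuartileSummary":
        if not (0 < self.q1 < self.median < self.q3):
            raise ValueError(
                f"quartiles must satisfy 0 < q1 < median < q3, got "
                f"({self.q1}, {self.median}, {self.q3})"
            )
        return self


class ClassClinicalSpec(BaseModel):
    """Per-class clinical marginals (median/quartile summaries)."""

    model_config = ConfigDict(extra="forbid")

    age: QuartileSummary
    pv: QuartileSummary
    tpsa: QuartileSummary
    fpsa: QuartileSummary


class ClinicalSpec(BaseModel):
    """Cohort-level clinical generator specification.

    Defaults reproduce the reported class sizes (134 clinically significant
    vs 41 non-significant) and the per-class median/(Q1,Q3) summaries of
    age, prostate volume, total and free PSA.  Gleason scores for the
    significant class follow the reported grade distribution; the
    non-significant class is Gleason 3+3=6 by definition.
    """

    model_config = ConfigDict(extra="forbid")

    n_cs: int = Field(default=134, ge=1)
    n_noncs: int = Field(default=41, ge=1)
    cs: ClassClinicalSpec = ClassClinicalSpec(
        age=QuartileSummary(median=74, q1=67, q3=80.8),
        pv=QuartileSummary(median=38.8, q1=27.4, q3=58.4),
        tpsa=QuartileSummary(median=55.1, q1=20.4, q3=113.1),
        fpsa=QuartileSummary(median=5.3, q1=1.9, q3=16.5),
    )
    noncs: ClassClinicalSpec = ClassClinicalSpec(
        age=QuartileSummary(median=74, q1=71, q3=78),
        pv=QuartileSummary(median=40.6, q1=32, q3=49.3),
        tpsa=QuartileSummary(median=12.1, q1=8.8, q3=18),
        fpsa=QuartileSummary(median=1.2, q1=0.9, q3=2.2),
    )
    # Gleason 7/8/9/10 counts among the significant class, used as weights.
    gleason_weights_cs: Sequence[float] = (56, 41, 28, 9)
    age_bounds: tuple[float, float] = (45.0, 95.0)


class PhantomSpec(BaseModel):
    """Specification of the synthetic bp-MRI phantom cohort.

    A lesion is an ellipsoid inside an ellipsoidal gland, partitioned into
    ``k_true`` spatially contiguous habitats by quota-constrained region
    growing on a smoothed noise field.  Habitats are ordered by ascending
    ADC mean; the class effect enters only through the per-class habitat
    mixture (and the clinical PSA shift), so subregional composition — not
    lesion size — carries the discriminative signal.
    """

    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    k_true: int = Field(default=3, ge=2)
    # Habitats are ordered by ascending ADC mean and model three phenotypes:
    # 1 = densely cellular (low ADC, fine-grained heterogeneous texture),
    # 2 = stromal/fibrotic (mid ADC, dark smooth T2),
    # 3 = necrotic/cystic (high ADC, bright coarse texture).
    adc_textures: tuple[HabitatTexture, ...] = (
        HabitatTexture(mean=800.0, variance=130.0**2, corr_len=0.7),
        HabitatTexture(mean=1100.0, variance=35.0**2, corr_len=2.5),
        HabitatTexture(mean=1400.0, variance=85.0**2, corr_len=1.3),
    )
    t2_textures: tuple[HabitatTexture, ...] = (
        HabitatTexture(mean=400.0, variance=104.0**2, corr_len=0.7),
        HabitatTexture(mean=270.0, variance=28.0**2, corr_len=2.5),
        HabitatTexture(mean=490.0, variance=68.0**2, corr_len=1.3),
    )
    mixture_cs: tuple[float, ...] = (0.2, 0.3, 0.5)
    mixture_noncs: tuple[float, ...] = (0.5, 0.3, 0.2)
    mixture_concentration: float = Field(default=10.0, gt=0)
    lesion_halfaxis_xy: tuple[float, float] = (10.0, 14.0)
    lesion_halfaxis_z: tuple[float, float] = (5.5, 7.5)
    bias_amplitude: float = Field(default=0.2, ge=0)
    # per-patient multiplicative gain jitter (lognormal sd); off by default
    # because the pipeline applies no per-patient intensity normalisation,
    # so pooled clustering assumes a consistent intensity scale
    gain_sd_t2: float = Field(default=0.0, ge=0)
    gain_sd_adc: float = Field(default=0.0, ge=0)
    # class effect on the cellular habitat: csPCa lesions are shifted down
    # in ADC by class_adc_contrast[h], non-csPCa up, per habitat (denser
    # cellularity in aggressive disease) — a subregional signal that
    # whole-lesion aggregates dilute
    class_adc_contrast: tuple[float, ...] = (40.0, 0.0, 0.0)
    blend_sigma: float = Field(default=0.8, ge=0)  # habitat transition width, voxels
    psf_sigma: float = Field(default=0.4, ge=0)  # scanner blur, voxels
    noise_sd: float = Field(default=0.05, ge=0)  # fraction of habitat-mean range

    @model_validator(mode="after")
    def _consistent(self) -> "PhantomSpec":
        k = self.k_true
        for name in ("adc_textures", "t2_textures"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have k_true={k} entries")
        if len(self.class_adc_contrast) != k:
            raise ValueError(f"class_adc_contrast must have k_true={k} entries")
        for name in ("mixture_cs", "mixture_noncs"):
            mix = getattr(self, name)
            if len(mix) != k:
                raise ValueError(f"{name} must have k_true={k} entries")
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"{name} must be a probability vector")
        return self


class SelectionConfig(BaseModel):
    """Knobs of the four-stage feature-selection cascade."""

    model_config = ConfigDict(extra="forbid")

    mi_keep_top: int = Field(default=300, ge=1)
    mi_bins: int = Field(default=10, ge=2)
    mrmr_m: int = Field(default=30, ge=1)
    lasso_folds: int = Field(default=10, ge=2)
    lasso_n_lambda: int = Field(default=100, ge=2)
    lasso_lambda_decades: float = Field(default=4.0, gt=0)
    lasso_loss: Literal["mse", "deviance"] = "mse"
    pearson_threshold: float = Field(default=0.8, gt=0, le=1)


class VoxelFeatureConfig(BaseModel):
    """Per-voxel feature map settings (window texture features)."""

    model_config = ConfigDict(extra="forbid")

    kernel_radius: int = Field(default=2, ge=1)
    n_bins: int = Field(default=16, ge=2)
    glcm_mode: Literal["3d", "2d"] = "3d"


class RegionFeatureConfig(BaseModel):
    """Region-level radiomics settings."""

    model_config = ConfigDict(extra="forbid")

    n_bins: int = Field(default=32, ge=2)  # fixed bin count over region range
    min_region_voxels: int = Field(default=5, ge=1)


class ClusteringConfig(BaseModel):
    """Habitat clustering settings."""

    model_config = ConfigDict(extra="forbid")

    k_min: int = Field(default=2, ge=2)
    k_max: int = Field(default=9, ge=2)
    n_init: int = Field(default=10, ge=1)
    subsample_cap: int = Field(default=100_000, ge=100)


class CVConfig(BaseModel):
    """Repeated stratified cross-validation settings."""

    model_config = ConfigDict(extra="forbid")

    enabled: bool = False
    repeats: int = Field(default=5, ge=1)
    folds: int = Field(default=4, ge=2)


class RunConfig(BaseModel):
    """Full configuration of an end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 42
    output_dir: Optional[str] = None
    phantom: PhantomSpec = PhantomSpec()
    clinical: ClinicalSpec = ClinicalSpec()
    voxel_features: VoxelFeatureConfig = VoxelFeatureConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    region_features: RegionFeatureConfig = RegionFeatureConfig()
    selection: SelectionConfig = SelectionConfig()
    learner: str = "random_forest"
    train_ratio: float = Field(default=0.7, gt=0, lt=1)
    # "full" corrects the bias field and resamples to isotropic 1 mm (the
    # standard recipe); "bias" corrects on the native grid; "none" skips
    preprocess: Literal["none", "bias", "full"] = "full"
    cv: CVConfig = CVConfig()

    def config_hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
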