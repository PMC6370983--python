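"""Synthetic lesion cohorts: smoothed-Gaussian-field 61 x 61 fragments.

Real prostate MRI cannot be redistributed, so the pipeline is exercised on
synthetic cohorts whose statistical structure matches what the analysis
assumes: per-Grade-Group differences expressible through first-order
(histogram) and second-order (co-occurrence / run-length) statistics. Each
fragment is a Gaussian white-noise field smoothed by an isotropic Gaussian
kernel whose scale sets the spatial correlation length, re-standardized to
unit SD, then scaled and shifted to the class intensity; an optional focal
blob adds a lesion-like bright core. Mean/SD shifts drive the histogram
features, correlation-length differences drive the texture features, so
first- and second-order signal can be planted independently.

Cohort sizes default to the study's class imbalance: peripheral zone
14/21/9/3/3 and transitional zone + anterior fibromuscular stroma
22/20/11/5/4 lesions for Grade Groups 1-5 (112 lesions in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import DEFAULT_ROI_SIZE, LesionRecord, ROIFragment

__all__ = [
    "ClassTextureSpec",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "TABLE1_COUNTS",
    "ZONE_GROUPS",
    "default_texture_specs",
    "planted_cohort_spec",
    "null_cohort_spec",
    "generate_fragment",
    "generate_cohort",
    "null_cohort",
]

#: lesions per Grade Group for each zone group (the study cohort's imbalance)
TABLE1_COUNTS: dict[str, tuple[int, ...]] = {
    "PZ": (14, 21, 9, 3, 3),
    "TZAFS": (22, 20, 11, 5, 4),
}
ZONE_GROUPS = ("PZ", "TZAFS")
_MODALITY = {"PZ": "DWI_B800", "TZAFS": "T2W"}

# default class model: modest graded intensity and smoothness increase
# with Grade Group (0.5 pooled-SD mean steps; correlation length in pixels)
_BASE_MEAN = 100.0
_BASE_SD = 10.0
_MEAN_STEP = 5.0
_CORR_BASE = 1.0
_CORR_STEP = 0.4


@dataclass(frozen=True)
class ClassTextureSpec:
    """Generative parameters for one Grade Group in one zone."""

    gg: int
    mean_intensity: float = _BASE_MEAN
    sd_intensity: float = _BASE_SD
    correlation_length: float = _CORR_BASE
    blob_contrast: float = 0.0
    blob_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.sd_intensity <= 0:
            raise ValueError("sd_intensity must be positive")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be non-negative")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Per-zone, per-GG counts and texture specs plus the master seed."""

    counts: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(TABLE1_COUNTS))
    specs: dict[str, tuple[ClassTextureSpec, ...]] = field(default_factory=dict)
    seed: int = 0
    roi_size: int = DEFAULT_ROI_SIZE

    def __post_init__(self) -> None:
        if not self.specs:
            object.__setattr__(self, "specs", {
                z: default_texture_specs() for z in self.counts})
        total = sum(sum(c) for c in self.counts.values())
        if total <= 0 or any(c < 0 for cs in self.counts.values() for c in cs):
            raise ValueError("counts must be non-negative with positive total")


@dataclass(frozen=True)
class SyntheticCohort:
    records: tuple[LesionRecord, ...]
    fragments: tuple[ROIFragment, ...]
    spec: SyntheticCohortSpec

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gg(self) -> np.ndarray:
        return np.array([r.gg for r in self.records])

    def zone_group(self, group: str) -> "SyntheticCohort":
        """Sub-cohort for one zone group ('PZ' or 'TZAFS')."""
        zones = ("PZ",) if group == "PZ" else ("TZ", "AFS")
        keep = [i for i, r in enumerate(self.records) if r.zone in zones]
        return SyntheticCohort(tuple(self.records[i] for i in keep),
                               tuple(self.fragments[i] for i in keep),
                               self.spec)


def default_texture_specs() -> tuple[ClassTextureSpec, ...]:
    """The default graded class model (one spec per Grade Group 1-5)."""
    return tuple(
        ClassTextureSpec(gg=g,
                         mean_intensity=_BASE_MEAN + _MEAN_STEP * (g - 1),
                         correlation_length=_CORR_BASE + _CORR_STEP * (g - 1))
        for g in range(1, 6))


def planted_cohort_spec(effect_sd: float = 0.0, texture_ratio: float = 1.0,
                        seed: int = 0,
                        high_groups: frozenset[int] = frozenset({3, 4, 5}),
                        counts: dict[str, tuple[int, ...]] | None = None,
                        ) -> SyntheticCohortSpec:
    """A two-group planted-effect cohort.

    Grade Groups in ``high_groups`` get a mean shift of ``effect_sd``
    pooled SDs (driving the histogram-mean feature) and a correlation
    length multiplied by ``texture_ratio`` (driving co-occurrence contrast
    and run-length statistics); all other parameters are identical across
    classes.
    """
    def spec_for(g: int) -> ClassTextureSpec:
        hi = g in high_groups
        return ClassTextureSpec(
            gg=g,
            mean_intensity=_BASE_MEAN + (effect_sd * _BASE_SD if hi else 0.0),
            correlation_length=_CORR_BASE * (texture_ratio if hi else 1.0))

    counts = dict(counts) if counts is not None else dict(TABLE1_COUNTS)
    specs = {z: tuple(spec_for(g) for g in range(1, 6)) for z in counts}
    return SyntheticCohortSpec(counts=counts, specs=specs, seed=seed)


def null_cohort_spec(seed: int = 0,
                     counts: dict[str, tuple[int, ...]] | None = None,
                     ) -> SyntheticCohortSpec:
    """A cohort whose labels carry no signal (identical spec for all GG)."""
    return planted_cohort_spec(effect_sd=0.0, texture_ratio=1.0, seed=seed,
                               counts=counts)


def generate_fragment(spec: ClassTextureSpec, seed, size: int = DEFAULT_ROI_SIZE,
                      modality: str = "T2W", patient_id: str = "",
                      lesion_id: str = "") -> ROIFragment:
    """One fragment: smoothed, re-standardized Gaussian field plus blob.

    Deterministic given (spec, seed); ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    field_ = rng.standard_normal((size, size))
    if spec.correlation_length > 0:
        field_ = gaussian_filter(field_, sigma=spec.correlation_length,
                                 mode="reflect")
    field_ = (field_ - field_.mean()) / field_.std()
    px = spec.mean_intensity + spec.sd_intensity * field_
    if spec.blob_contrast != 0.0:
        c = (size - 1) / 2
        rr, cc = np.ogrid[:size, :size]
        mask = (rr - c) ** 2 + (cc - c) ** 2 <= spec.blob_radius ** 2
        px = px + spec.blob_contrast * mask
    return ROIFragment(px, modality=modality, patient_id=patient_id,
                       lesion_id=lesion_id)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """One fragment + lesion record per lesion, per zone-group counts.

    Per-lesion seeds are spawned from the master seed, so cohorts are
    reproducible and adding lesions at the end does not perturb earlier
    ones. Every third lesion of the TZ+AFS group is labeled AFS to
    exercise the AFS-grouped-with-TZ path.
    """
    records: list[LesionRecord] = []
    fragments: list[ROIFragment] = []
    total = sum(sum(c) for c in spec.counts.values())
    seeds = np.random.SeedSequence(spec.seed).spawn(total)
    idx = 0
    for group in spec.counts:
        for gg, n in zip(range(1, 6), spec.counts[group]):
            cspec = spec.specs[group][gg - 1]
            for rep in range(n):
                if group == "PZ":
                    zone = "PZ"
                else:
                    zone = "AFS" if idx % 3 == 2 else "TZ"
                pid = f"P{idx:03d}"
                lid = f"L{idx:03d}"
                frag = generate_fragment(cspec, seeds[idx], size=spec.roi_size,
                                         modality=_MODALITY[group],
                                         patient_id=pid, lesion_id=lid)
                center = ((spec.roi_size - 1) / 2, (spec.roi_size - 1) / 2)
                records.append(LesionRecord(
                    patient_id=pid, lesion_id=lid, zone=zone, center=center,
                    gg=gg, center_in_world=False))
                fragments.append(frag)
                idx += 1
    return SyntheticCohort(tuple(records), tuple(fragments), spec)


def null_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate a cohort whose class labels carry no generative signal.

    All Grade Groups share the spec's GG1 texture spec; counts, zones and
    labels are kept, so label permutations leave the feature distribution
    unchanged by construction.
    """
    flat = {z: tuple(replace(specs[0], gg=g) for g in range(1, 6))
            for z, specs in spec.specs.items()}
    return generate_cohort(replace(spec, specs=flat))
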