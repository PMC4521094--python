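"""Synthetic phantoms and cohorts with the statistical structure of amyloid-PET studies.

Two generators live here.

``generate_phantom`` builds a labeled 3-D uptake volume — the stand-in for a
spatially normalized PET scan plus atlas: each region receives a true uptake
ratio relative to the reference region, then additive Gaussian noise and an
optional Gaussian blur emulating resolution-driven spill-over (e.g. white
matter into adjacent grey matter).

``generate_cohort`` draws per-subject tables for a six-stratum design:
diagnosis (HC / MCI / AD) crossed with age group (younger 55-75 y, older
76-93 y). Each stratum's composite neocortical ratio (CCTXR) follows a one-
or two-component Gaussian mixture; the shipped default calibration is the
set of mixture parameters reported for a large Florbetapir cohort —
bimodal younger HC (1.23 +/- 0.08 with weight 110/123 and 1.52 +/- 0.08 with
weight 13/123), unimodal older HC (1.26 +/- 0.16), unimodal younger AD
(1.48 +/- 0.17), bimodal older AD (1.08 +/- 0.13 w=15/69 and 1.48 +/- 0.13
w=54/69), and unimodal MCI in both age groups (1.36 +/- 0.19 / 1.35 +/- 0.20).
ApoE4 carrier status is drawn per latent component, so carriers are enriched
in the high-amyloid component while the marginal CCTXR distribution stays
exactly the configured mixture. Regional SUVRs are linear transforms of the
CCTXR plus correlated noise, anchored to published group-level regional
means. Latent component membership is recorded for recovery scoring but is
never consumed by the analysis stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .quant import LabeledVolume, RegionInfo

__all__ = [
    "PhantomRegion",
    "PhantomSpec",
    "StratumConfig",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "apply_tracer_transform",
    "default_phantom_spec",
    "default_cohort_config",
    "default_roi_model",
    "ROI_NAMES",
    "AGE_BOUNDS",
]

logger = logging.getLogger("amypet")

#: The 12 bilateral grey-matter ROIs of the atlas.
ROI_NAMES: tuple[str, ...] = (
    "temporal",
    "frontal",
    "occipital",
    "parietal",
    "insula",
    "anterior_cingulate",
    "posterior_cingulate",
    "caudate",
    "putamen",
    "thalamus",
    "hippocampus",
    "parahippocampal",
)

#: Inclusive age bounds per age group (years).
AGE_BOUNDS: dict[str, tuple[float, float]] = {
    "younger": (55.0, 75.0),
    "older": (76.0, 93.0),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Phantom volumes


@dataclass(frozen=True)
class PhantomRegion:
    """One phantom region: label id, name, true uptake ratio vs reference.

    ``box`` is an optional ``((z0,z1),(y0,y1),(x0,x1))`` half-open voxel box;
    regions without a box are laid out as consecutive slabs along axis 0.
    """

    label: int
    name: str
    ratio: float
    tissue: str = "GM"
    box: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: Sequence[PhantomRegion] = ()
    reference_label: int = 1
    reference_value: float = 1.0  # absolute uptake of the reference region
    noise_sd: float = 0.0
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels")
        if self.reference_label not in labels:
            raise ValueError(f"reference label {self.reference_label} not among regions")
        if any(r.ratio <= 0 for r in self.regions):
            raise ValueError("uptake ratios must be positive")
        if self.noise_sd < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("noise_sd and smoothing_fwhm_mm must be non-negative")
        if self.reference_value <= 0:
            raise ValueError("reference_value must be positive")


def _paint_labels(spec: PhantomSpec) -> np.ndarray:
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    boxed = [r for r in spec.regions if r.box is not None]
    slabbed = [r for r in spec.regions if r.box is None]
    for r in boxed:
        (z0, z1), (y0, y1), (x0, x1) = r.box  # type: ignore[misc]
        view = labels[z0:z1, y0:y1, x0:x1]
        if view.size == 0:
            raise ValueError(f"region {r.name!r} has an empty box")
        if np.any(view != 0):
            raise ValueError(f"region {r.name!r} overlaps a previously placed region")
        view[...] = r.label
    if slabbed:
        free = np.flatnonzero(~labels.any(axis=(1, 2)))
        # consecutive free slabs along axis 0, split evenly among regions
        if len(free) < len(slabbed):
            raise ValueError("grid too small for slab layout")
        chunks = np.array_split(free, len(slabbed))
        for r, rows in zip(slabbed, chunks):
            if rows.size == 0:
                raise ValueError(f"region {r.name!r} received no voxels")
            labels[rows] = r.label
    return labels


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Build the labeled uptake volume for ``spec``.

    Noise-free voxel value in each region = true ratio x reference value;
    Gaussian noise (SD ``noise_sd``) is added, then an optional Gaussian
    blur of FWHM ``smoothing_fwhm_mm`` mixes uptake across region borders.
    The label grid is never touched by noise or blur.
    """
    spec.validate()
    labels = _paint_labels(spec)
    uptake = np.zeros(spec.grid_shape, dtype=float)
    for r in spec.regions:
        uptake[labels == r.label] = r.ratio * spec.reference_value
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        uptake = uptake + rng.normal(0.0, spec.noise_sd, size=uptake.shape)
    if spec.smoothing_fwhm_mm > 0:
        sigma_vox = [
            spec.smoothing_fwhm_mm * _FWHM_TO_SIGMA / vs for vs in spec.voxel_size
        ]
        uptake = gaussian_filter(uptake, sigma=sigma_vox)
    uptake = np.clip(uptake, 0.0, None)
    region_map = {
        r.label: RegionInfo(r.name, r.tissue, "bilateral") for r in spec.regions
    }
    return LabeledVolume(uptake, labels, region_map, spec.voxel_size)


def default_phantom_spec(**overrides) -> PhantomSpec:
    """A 12-ROI atlas phantom with left/right labels, cerebellum and WM.

    Left/right halves of each ROI share a name but carry distinct labels
    (odd = left, even = right). Label 101 is cerebellar GM (the PIB
    reference), 102 cerebellar WM (their union is the whole cerebellum),
    103 cerebral WM. ROI ratios follow the healthy-control regional pattern.
    """
    hc_ratios = {
        "temporal": 1.26, "frontal": 1.27, "occipital": 1.31, "parietal": 1.26,
        "insula": 1.15, "anterior_cingulate": 1.22, "posterior_cingulate": 1.26,
        "caudate": 0.83, "putamen": 1.17, "thalamus": 0.94,
        "hippocampus": 1.08, "parahippocampal": 1.09,
    }
    shape = overrides.pop("grid_shape", (30, 12, 12))
    nz = shape[0]
    regions: list[PhantomRegion] = []
    half = shape[2] // 2
    # 12 ROI slabs of 2 planes each, split left/right along x
    for i, name in enumerate(ROI_NAMES):
        z0, z1 = 2 * i, 2 * i + 2
        regions.append(
            PhantomRegion(2 * i + 1, name, hc_ratios[name], "GM",
                          ((z0, z1), (0, shape[1]), (0, half))))
        regions.append(
            PhantomRegion(2 * i + 2, name, hc_ratios[name], "GM",
                          ((z0, z1), (0, shape[1]), (half, shape[2]))))
    z = 24
    regions.append(PhantomRegion(101, "cerebellum_gm", 1.0, "ref",
                                 ((z, z + 2), (0, shape[1]), (0, shape[2]))))
    regions.append(PhantomRegion(102, "cerebellum_wm", 1.4, "WM",
                                 ((z + 2, z + 4), (0, shape[1]), (0, shape[2]))))
    regions.append(PhantomRegion(103, "cerebral_wm", 1.6, "WM",
                                 ((z + 4, nz), (0, shape[1]), (0, shape[2]))))
    return PhantomSpec(grid_shape=shape, regions=tuple(regions),
                       reference_label=101, **overrides)


def default_roi_defs() -> dict[str, tuple[int, ...]]:
    """ROI name -> (left label, right label) for the default phantom atlas."""
    return {name: (2 * i + 1, 2 * i + 2) for i, name in enumerate(ROI_NAMES)}


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass(frozen=True)
class StratumConfig:
    """Generating distribution for one diagnosis x age-group stratum.

    ``weights/means/sds`` define the CCTXR Gaussian mixture (1 or 2
    components, low-amyloid first). ``apoe4_rates`` is the carrier
    probability per component; ``apoe4_shift`` is an optional additive
    CCTXR effect of carriership (0 keeps the marginal CCTXR exactly the
    configured mixture).
    """

    n: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    apoe4_rates: tuple[float, ...]
    apoe4_shift: float = 0.0
    mmse_mean: float = 27.0
    mmse_sd: float = 2.0
    male_frac: float = 0.5
    edu_mean: float = 16.0
    edu_sd: float = 2.7

    def validate(self) -> None:
        k = len(self.means)
        if not (len(self.weights) == len(self.sds) == len(self.apoe4_rates) == k):
            raise ValueError("weights, means, sds, apoe4_rates must share length")
        if k not in (1, 2):
            raise ValueError("mixtures are limited to 1 or 2 components")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w <= 0 for w in self.weights) or any(s < 0 for s in self.sds):
            raise ValueError("weights must be positive and SDs non-negative")
        if self.n < 1:
            raise ValueError("stratum size must be at least 1")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort design: strata plus the regional-SUVR generation model.

    ``roi_model`` maps each ROI to ``(offset, scale, resid_sd)``:
    SUVR_roi = offset + scale * CCTXR + noise. ``roi_correlation`` is the
    shared fraction of residual variance common to all ROIs of one subject
    (left free by design; the source data constrain only group-level
    regional means, not intra-subject correlation).
    """

    strata: Mapping[tuple[str, str], StratumConfig]
    roi_model: Mapping[str, tuple[float, float, float]]
    roi_correlation: float = 0.5
    tracer: str = "florbetapir"
    seed: int = 0

    def validate(self) -> None:
        if not self.strata:
            raise ValueError("no strata configured")
        for key, s in self.strata.items():
            diagnosis, age_group = key
            if diagnosis not in ("HC", "MCI", "AD"):
                raise ValueError(f"unknown diagnosis {diagnosis!r}")
            if age_group not in AGE_BOUNDS:
                raise ValueError(f"unknown age group {age_group!r}")
            s.validate()
        if not 0.0 <= self.roi_correlation <= 1.0:
            raise ValueError("roi_correlation must be in [0, 1]")


def default_roi_model() -> dict[str, tuple[float, float, float]]:
    """Per-ROI (offset, scale, residual SD) anchored to group-level regional means."""
    return {
        "frontal": (0.0140, 0.9877, 0.0534),
        "temporal": (0.0085, 0.9993, 0.0300),
        "parietal": (-0.0995, 1.0757, 0.0300),
        "occipital": (0.2544, 0.8464, 0.0300),
        "anterior_cingulate": (-0.5735, 1.4182, 0.0586),
        "posterior_cingulate": (-0.7445, 1.6063, 0.0300),
        "insula": (-0.0009, 0.9005, 0.0522),
        "caudate": (-0.2049, 0.7996, 0.1403),
        "putamen": (-1.0752, 1.8183, 0.0300),
        "thalamus": (0.9872, -0.0721, 0.1197),
        "parahippocampal": (0.7820, 0.2415, 0.0746),
        "hippocampus": (1.1821, -0.0981, 0.0791),
    }


def default_cohort_config(seed: int = 0, tracer: str = "florbetapir") -> CohortConfig:
    """The calibrated six-stratum Florbetapir design (see module docstring).

    Carrier rates for the bimodal strata are the per-component rates
    reported for the recovered subpopulations (younger HC: 26 % low /
    69 % high; older AD: 7 % low / 74 % high); unimodal strata use the
    group-level carrier rates.
    """
    strata = {
        ("HC", "younger"): StratumConfig(
            n=123, weights=(110 / 123, 13 / 123), means=(1.23, 1.52),
            sds=(0.08, 0.08), apoe4_rates=(0.26, 0.69),
            mmse_mean=29.1, mmse_sd=1.1, male_frac=55 / 123,
            edu_mean=16.3, edu_sd=2.7),
        ("HC", "older"): StratumConfig(
            n=123, weights=(1.0,), means=(1.26,), sds=(0.16,),
            apoe4_rates=(28 / 123,),
            mmse_mean=29.0, mmse_sd=1.2, male_frac=66 / 123,
            edu_mean=16.4, edu_sd=2.8),
        ("MCI", "younger"): StratumConfig(
            n=171, weights=(1.0,), means=(1.36,), sds=(0.19,),
            apoe4_rates=(89 / 170,),
            mmse_mean=27.9, mmse_sd=1.8, male_frac=105 / 171,
            edu_mean=16.3, edu_sd=2.7),
        ("MCI", "older"): StratumConfig(
            n=171, weights=(1.0,), means=(1.35,), sds=(0.20,),
            apoe4_rates=(63 / 169,),
            mmse_mean=27.7, mmse_sd=1.7, male_frac=106 / 171,
            edu_mean=15.6, edu_sd=2.9),
        ("AD", "younger"): StratumConfig(
            n=69, weights=(1.0,), means=(1.48,), sds=(0.17,),
            apoe4_rates=(53 / 67,),
            mmse_mean=22.6, mmse_sd=3.4, male_frac=35 / 69,
            edu_mean=15.9, edu_sd=2.6),
        ("AD", "older"): StratumConfig(
            n=69, weights=(15 / 69, 54 / 69), means=(1.08, 1.48),
            sds=(0.13, 0.13), apoe4_rates=(0.07, 0.74),
            mmse_mean=22.3, mmse_sd=2.7, male_frac=45 / 69,
            edu_mean=15.7, edu_sd=2.8),
    }
    return CohortConfig(
        strata=strata, roi_model=default_roi_model(), seed=seed, tracer=tracer
    )


_STRATUM_ORDER = [("HC", "younger"), ("HC", "older"), ("MCI", "younger"),
                  ("MCI", "older"), ("AD", "younger"), ("AD", "older")]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw the full cohort table for ``config``.

    One row per subject: demographics, latent mixture component
    (``true_component``), CCTXR and the 12 regional SUVRs
    (columns ``suvr_<roi>``). Negative CCTXR or SUVR draws are redrawn
    (truncation at 0) and the redraw count is logged. Deterministic under a
    fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rho = config.roi_correlation
    rois = list(config.roi_model)
    frames = []
    n_truncated = 0
    ordered = [k for k in _STRATUM_ORDER if k in config.strata]
    ordered += [k for k in sorted(config.strata) if k not in ordered]
    for diagnosis, age_group in ordered:
        s = config.strata[(diagnosis, age_group)]
        n = s.n
        comp = rng.choice(len(s.means), size=n, p=np.asarray(s.weights))
        cctxr = rng.normal(np.take(s.means, comp), np.take(s.sds, comp))
        bad = cctxr <= 0
        while bad.any():
            n_truncated += int(bad.sum())
            cctxr[bad] = rng.normal(
                np.take(s.means, comp[bad]), np.take(s.sds, comp[bad])
            )
            bad = cctxr <= 0
        apoe4 = rng.random(n) < np.take(s.apoe4_rates, comp)
        cctxr = cctxr + s.apoe4_shift * apoe4
        lo, hi = AGE_BOUNDS[age_group]
        age = rng.uniform(lo, hi, size=n)
        sex = np.where(rng.random(n) < s.male_frac, "m", "f")
        mmse = np.clip(np.round(rng.normal(s.mmse_mean, s.mmse_sd, n)), 0, 30)
        edu = np.clip(np.round(rng.normal(s.edu_mean, s.edu_sd, n)), 0, None)
        # regional SUVRs: shared + independent residuals on top of the linear map
        z_shared = rng.normal(size=n)
        suvr = {}
        for roi in rois:
            a, b, resid = config.roi_model[roi]
            noise = resid * (
                np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * rng.normal(size=n)
            )
            vals = a + b * cctxr + noise
            bad = vals <= 0
            while bad.any():
                n_truncated += int(bad.sum())
                vals[bad] = a + b * cctxr[bad] + resid * rng.normal(size=int(bad.sum()))
                bad = vals <= 0
            suvr[f"suvr_{roi}"] = vals
        frames.append(
            pd.DataFrame({
                "diagnosis": diagnosis, "age_group": age_group, "age": age,
                "sex": sex, "education": edu, "apoe4": apoe4,
                "mmse": mmse, "tracer": config.tracer,
                "true_component": comp, "cctxr": cctxr, **suvr,
            })
        )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])
    if n_truncated:
        logger.info("generate_cohort: %d negative draws redrawn", n_truncated)
    return table


def apply_tracer_transform(
    values,
    slope: float,
    intercept: float,
    residual_sd: float = 0.0,
    seed: int | None = None,
):
    """Map CCTXR values onto another tracer's scale: slope*x + intercept (+ noise).

    The canonical use is the PIB -> Florbetapir dynamic-range compression
    (slope 1.13, intercept -0.28 on the healthy-control regional means).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    values = np.asarray(values, dtype=float)
    out = slope * values + intercept
    if residual_sd > 0:
        out = out + np.random.default_rng(seed).normal(0.0, residual_sd, out.shape)
    return out
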