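"""Regional SUVR quantification from labeled uptake volumes.

A spatially normalized amyloid-PET scan is represented here as a
:class:`LabeledVolume`: a 3-D uptake grid plus an integer atlas-label grid
of the same shape. Quantification divides every voxel by a reference-region
statistic (median cerebellar grey-matter uptake for [11C]PIB, mean
whole-cerebellum uptake for [18F]Florbetapir), averages the resulting SUVR
over bilateral regions of interest, and condenses the neocortex into a
single composite neocortical ratio (CCTXR) — the weighted-average SUVR over
the frontal, parietal and lateral-temporal regions that serves as the
headline amyloid score.

No spatial normalization, segmentation or partial-volume correction happens
here; volumes are assumed already in a common space with a voxel-aligned
label map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionInfo",
    "LabeledVolume",
    "compute_reference_value",
    "compute_suvr_image",
    "extract_roi_means",
    "compute_cctxr",
    "evaluate_reference_regions",
    "save_labeled_volume",
    "load_labeled_volume",
    "COMPOSITE_ROIS",
]

#: ROIs entering the composite neocortical ratio: frontal, parietal and the
#: (basal/)lateral temporal cortex, here the temporal-lobe ROI of the atlas.
COMPOSITE_ROIS: tuple[str, ...] = ("frontal", "parietal", "temporal")


@dataclass(frozen=True)
class RegionInfo:
    """Atlas metadata for one label: name, tissue class, laterality."""

    name: str
    tissue: str = "GM"  # "GM", "WM" or "ref"
    laterality: str = "bilateral"  # "left", "right" or "bilateral"


@dataclass
class LabeledVolume:
    """Uptake grid plus voxel-aligned integer label grid.

    Label 0 is background and needs no entry in ``region_map``; every other
    label present in ``labels`` must be described there.
    """

    uptake: np.ndarray
    labels: np.ndarray
    region_map: Mapping[int, RegionInfo]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.uptake = np.asarray(self.uptake, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.uptake.shape != self.labels.shape:
            raise ValueError(
                f"uptake shape {self.uptake.shape} != labels shape {self.labels.shape}"
            )
        if self.uptake.ndim != 3:
            raise ValueError("volumes must be 3-D")
        if np.any(self.uptake < 0):
            raise ValueError("uptake values must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.region_map)
        if missing:
            raise ValueError(f"labels missing from region_map: {sorted(missing)}")

    def mask(self, labels: int | Iterable[int]) -> np.ndarray:
        if np.isscalar(labels):
            labels = [int(labels)]  # type: ignore[list-item]
        return np.isin(self.labels, np.asarray(list(labels)))


def compute_reference_value(
    vol: LabeledVolume,
    reference_labels: int | Iterable[int],
    statistic: str = "median",
) -> float:
    """Reference-region uptake statistic over all voxels with any reference label.

    ``statistic`` is ``"median"`` (cerebellar GM convention for PIB) or
    ``"mean"`` (whole-cerebellum convention for Florbetapir).
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    voxels = vol.uptake[vol.mask(reference_labels)]
    if voxels.size == 0:
        raise ValueError(
            f"reference labels {reference_labels!r} select no voxels — misconfigured atlas"
        )
    return float(np.median(voxels) if statistic == "median" else np.mean(voxels))


def compute_suvr_image(vol: LabeledVolume, reference_value: float) -> LabeledVolume:
    """Divide every uptake voxel by the reference value; labels untouched.

    Not idempotent: applying twice divides twice.
    """
    if reference_value <= 0:
        raise ValueError(f"reference value must be positive, got {reference_value}")
    return replace(vol, uptake=vol.uptake / reference_value)


def extract_roi_means(
    suvr_vol: LabeledVolume, roi_defs: Mapping[str, Sequence[int]]
) -> dict[str, float]:
    """Mean SUVR per bilateral ROI over the union of its (left+right) labels.

    The union mean weights hemispheres by voxel count — it is NOT the mean
    of the two hemispheric means.
    """
    out: dict[str, float] = {}
    for roi, labels in roi_defs.items():
        m = suvr_vol.mask(labels)
        if not m.any():
            raise ValueError(f"ROI {roi!r}: labels {list(labels)} select no voxels")
        out[roi] = float(suvr_vol.uptake[m].mean())
    return out


def compute_cctxr(
    roi_values: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Composite neocortical ratio: weighted-average SUVR of the composite ROIs.

    With ``weights=None`` the composite ROIs are weighted equally. Weights
    must cover exactly the composite ROIs and be positive; weighting by ROI
    voxel count reproduces the direct voxel-level mean over the union.
    """
    if weights is None:
        weights = {r: 1.0 for r in COMPOSITE_ROIS}
    if set(weights) != set(COMPOSITE_ROIS):
        raise ValueError(
            f"weights must cover exactly {COMPOSITE_ROIS}, got {sorted(weights)}"
        )
    if any(w <= 0 for w in weights.values()):
        raise ValueError("composite weights must be positive")
    total = sum(weights.values())
    return float(sum(weights[r] * roi_values[r] for r in COMPOSITE_ROIS) / total)


def _cctxr_from_volume(
    vol: LabeledVolume,
    reference_labels: Sequence[int],
    statistic: str,
    roi_defs: Mapping[str, Sequence[int]],
    weights: Mapping[str, float] | None,
) -> float:
    ref = compute_reference_value(vol, reference_labels, statistic)
    suvr = compute_suvr_image(vol, ref)
    rois = extract_roi_means(suvr, {r: roi_defs[r] for r in COMPOSITE_ROIS})
    return compute_cctxr(rois, weights)


def evaluate_reference_regions(
    hc_vols: Sequence[LabeledVolume],
    ad_vols: Sequence[LabeledVolume],
    candidates: Sequence[tuple[str, Sequence[int], str]],
    roi_defs: Mapping[str, Sequence[int]],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Benchmark candidate reference regions by HC spread and HC-vs-AD effect size.

    Each candidate is ``(name, reference label set, statistic)``. For every
    candidate the CCTXR is recomputed per subject; the table reports the
    coefficient of variation of the healthy controls (lower is better: a
    stable denominator) and Cohen's d between HC and AD CCTXR (larger
    magnitude is better: preserved disease contrast). The candidate
    minimizing HC CV and the one maximizing |d| are flagged.
    """
    from .cohortstats import cohens_d

    if len(hc_vols) < 2 or len(ad_vols) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for name, labels, stat in candidates:
        hc = np.array(
            [_cctxr_from_volume(v, labels, stat, roi_defs, weights) for v in hc_vols]
        )
        ad = np.array(
            [_cctxr_from_volume(v, labels, stat, roi_defs, weights) for v in ad_vols]
        )
        cv = float(hc.std(ddof=1) / hc.mean())
        d = cohens_d(ad, hc)
        rows.append({"candidate": name, "statistic": stat, "hc_cv": cv, "cohens_d": d})
    table = pd.DataFrame(rows)
    table["min_cv"] = table["hc_cv"] == table["hc_cv"].min()
    with np.errstate(invalid="ignore"):
        abs_d = table["cohens_d"].abs()
    table["max_d"] = abs_d == abs_d.max()
    return table


# ---------------------------------------------------------------------------
# NIfTI-1 I/O: uptake and label grids as paired volumes, region metadata as a
# JSON sidecar. The affine is diagonal from the voxel size (RAS, 0-based
# voxel indices); laterality comes from the region map, never from
# coordinate signs.

def save_labeled_volume(vol: LabeledVolume, prefix: str) -> dict[str, str]:
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size) + [1.0])
    paths = {
        "uptake": f"{prefix}_uptake.nii",
        "labels": f"{prefix}_labels.nii",
        "regions": f"{prefix}_regions.json",
    }
    nib.save(nib.Nifti1Image(vol.uptake.astype(np.float32), affine), paths["uptake"])
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine), paths["labels"])
    meta = {
        str(lab): {"name": r.name, "tissue": r.tissue, "laterality": r.laterality}
        for lab, r in vol.region_map.items()
    }
    with open(paths["regions"], "w") as fh:
        json.dump({"voxel_size": list(vol.voxel_size), "regions": meta}, fh, indent=1)
    return paths


def load_labeled_volume(prefix: str) -> LabeledVolume:
    import nibabel as nib

    uptake = np.asarray(nib.load(f"{prefix}_uptake.nii").dataobj, dtype=float)
    labels = np.asarray(nib.load(f"{prefix}_labels.nii").dataobj).astype(int)
    with open(f"{prefix}_regions.json") as fh:
        meta = json.load(fh)
    region_map = {
        int(lab): RegionInfo(r["name"], r["tissue"], r["laterality"])
        for lab, r in meta["regions"].items()
    }
    return LabeledVolume(uptake, labels, region_map, tuple(meta["voxel_size"]))
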