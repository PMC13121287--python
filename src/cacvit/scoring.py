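"""Agatston scoring: lesion extraction, density weighting, risk categories.

A lesion is an in-plane 8-connected component of segmented pixels whose raw
attenuation is at least 130 HU; components smaller than 1 mm^2 are dropped.
The score is the plain sum over lesions of area (mm^2) times the density
weight of the lesion's peak HU:

    weight 1 for 130-199 HU, 2 for 200-299, 3 for 300-399, 4 for >=400.

Scores map to risk categories 0-10 (low), 11-100 (moderate), 101-400 (high)
and >400 (very high).  Scoring always reads raw HU — never normalized
values — and lesions are per-slice (no through-plane merging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct_io import ARTERY_NAMES, AnnotationMask, CTVolume

HU_THRESHOLD = 130.0
MIN_AREA_MM2 = 1.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class Lesion:
    """One connected calcified component on a single slice."""

    slice_index: int
    artery_class: int  # 1..4
    pixel_coords: list[tuple[int, int]]
    area_mm2: float
    peak_hu: float
    density_weight: int

    @property
    def artery(self) -> str:
        return ARTERY_NAMES[self.artery_class - 1]

    @property
    def score(self) -> float:
        return self.area_mm2 * self.density_weight


@dataclass
class CACReport:
    """Per-patient calcium-scoring result."""

    patient_id: str
    agatston: float
    risk: str
    per_artery_scores: dict[str, float]
    lesions: list[Lesion] = field(default_factory=list)
    slices_scored: list[int] = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.per_artery_scores.values())
        if abs(total - self.agatston) > 1e-6 * max(1.0, self.agatston):
            raise ValueError("per-artery scores do not sum to the total score")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "agatston": self.agatston,
            "risk": self.risk,
            "per_artery_scores": dict(self.per_artery_scores),
            "n_lesions": len(self.lesions),
            "slices_scored": list(map(int, self.slices_scored)),
        }


def density_weight(peak_hu: float) -> int:
    """Agatston density weighting factor for a lesion's peak HU."""
    if peak_hu < HU_THRESHOLD:
        raise ValueError(f"peak HU {peak_hu} is below the {HU_THRESHOLD} HU lesion "
                         "threshold; such components must be filtered out")
    if peak_hu < 200.0:
        return 1
    if peak_hu < 300.0:
        return 2
    if peak_hu < 400.0:
        return 3
    return 4


def extract_lesions(raw_hu_slice: np.ndarray, seg_mask_slice: np.ndarray,
                    pixel_spacing: tuple[float, float],
                    slice_index: int = 0) -> list[Lesion]:
    """Connected calcified components on one slice.

    Candidate pixels are those both segmented (label != 0) and >=130 HU;
    components are found per artery class with 8-connectivity, and any
    component below 1 mm^2 is discarded.
    """
    raw = np.asarray(raw_hu_slice, dtype=np.float64)
    seg = np.asarray(seg_mask_slice)
    if raw.shape != seg.shape:
        raise ValueError(f"slice shape {raw.shape} != mask shape {seg.shape}")
    rs, cs = pixel_spacing
    if rs <= 0 or cs <= 0:
        raise ValueError("pixel spacing must be strictly positive")
    pixel_area = rs * cs

    lesions: list[Lesion] = []
    for cls in range(1, 5):
        candidate = (seg == cls) & (raw >= HU_THRESHOLD)
        if not candidate.any():
            continue
        comp, n_comp = ndimage.label(candidate, structure=_EIGHT_CONNECTED)
        for cid in range(1, n_comp + 1):
            rows, cols = np.nonzero(comp == cid)
            area = rows.size * pixel_area
            if area < MIN_AREA_MM2:
                continue
            peak = float(raw[rows, cols].max())
            lesions.append(Lesion(slice_index=slice_index, artery_class=cls,
                                  pixel_coords=list(zip(rows.tolist(), cols.tolist())),
                                  area_mm2=area, peak_hu=peak,
                                  density_weight=density_weight(peak)))
    return lesions


def agatston_score(lesions: list[Lesion]) -> float:
    """Sum of area x density weight over lesions; 0 for an empty list."""
    return float(sum(l.area_mm2 * l.density_weight for l in lesions))


def risk_category(score: float) -> str:
    """Risk category for an Agatston score.

    Fractional scores use the convention: low if <=10, moderate if <=100,
    high if <=400, else very high.
    """
    if score < 0:
        raise ValueError("Agatston score cannot be negative")
    if score <= 10.0:
        return "low"
    if score <= 100.0:
        return "moderate"
    if score <= 400.0:
        return "high"
    return "very_high"


def score_patient(volume: CTVolume, seg_masks: AnnotationMask,
                  slice_filter: list[int] | np.ndarray | None = None) -> CACReport:
    """Full per-patient Agatston report from raw HU and segmentation masks.

    ``slice_filter`` optionally restricts scoring to the listed slice
    indices (the classifier's positive slices); ``None`` scores every slice.
    """
    seg_masks.validate_against(volume)
    if slice_filter is None:
        indices = list(range(volume.n_slices))
    else:
        indices = sorted(int(i) for i in np.asarray(slice_filter).ravel())
        out_of_range = [i for i in indices if i < 0 or i >= volume.n_slices]
        if out_of_range:
            raise ValueError(f"slice_filter indices out of range: {out_of_range}")

    lesions: list[Lesion] = []
    for i in indices:
        lesions.extend(extract_lesions(volume.voxels[i], seg_masks.labels[i],
                                       volume.pixel_spacing, slice_index=i))
    per_artery = {name: 0.0 for name in ARTERY_NAMES}
    for l in lesions:
        per_artery[l.artery] += l.score
    total = agatston_score(lesions)
    return CACReport(patient_id=volume.patient_id, agatston=total,
                     risk=risk_category(total), per_artery_scores=per_artery,
                     lesions=lesions, slices_scored=indices)
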