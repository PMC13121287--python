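"""Synthetic chest-CT phantom generator with ground-truth calcified lesions.

Each phantom slice is an air background with a soft-tissue body ellipse,
bone-density rib blobs around the periphery, and a central "heart" region in
which small bright lesions (>=130 HU) are planted.  Every lesion is assigned
to one of the four coronary-artery classes (RCA/LAD/LCA/LCX), each confined
to a fixed quadrant of the heart region so per-artery metrics are meaningful.

The generator mirrors the summary statistics of real calcium-scoring CT
collections: ~10% of slices contain calcification, mean lesion area ~0.04%
of the slice (119 px at 512x512, scaled quadratically for smaller grids),
3 mm slice thickness, and lesion densities spread over the four Agatston
bins.  Ground-truth Agatston scores are computed by construction-time
bookkeeping that is fully independent of the scoring module, so the two can
be checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .ct_io import ARTERY_NAMES, AnnotationMask, CTVolume

RISK_CATEGORIES = ("low", "moderate", "high", "very_high")

#: Agatston density bins as (low HU, high HU, weight); the last bin is open-ended
DENSITY_BINS = ((130.0, 199.0, 1), (200.0, 299.0, 2), (300.0, 399.0, 3), (400.0, 600.0, 4))

#: risk ranges (inclusive upper bounds; very_high unbounded)
RISK_RANGES = {"low": (0.0, 10.0), "moderate": (11.0, 100.0),
               "high": (101.0, 400.0), "very_high": (401.0, np.inf)}


@dataclass
class PhantomConfig:
    """Study conditions for the phantom generator.

    Defaults are desk-scale: 64x64 slices with the field of view of a
    512x512 scan (so pixel spacing grows as the grid shrinks) and lesion
    areas scaled quadratically to preserve the ~0.04% area fraction.
    """

    image_size: int = 64
    pixel_spacing_mm: float | None = None  # default: 0.49 mm * (512 / image_size)
    slice_thickness_mm: float = 3.0
    slices_per_patient: int = 10
    positive_slice_fraction: float = 0.10
    lesion_area_px_mean: float | None = None  # default: 119 * (image_size/512)^2
    lesion_hu_bin_weights: tuple[float, float, float, float] = (0.35, 0.30, 0.20, 0.15)
    artery_class_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    background_hu_range: tuple[float, float] = (20.0, 60.0)
    lesions_per_positive_slice_mean: float = 1.7
    max_lesions_per_patient: int = 120
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.positive_slice_fraction < 1.0:
            raise ValueError("positive_slice_fraction must be in [0, 1)")
        if self.pixel_spacing_mm is None:
            self.pixel_spacing_mm = 0.49 * 512.0 / self.image_size
        if self.lesion_area_px_mean is None:
            self.lesion_area_px_mean = 119.0 * (self.image_size / 512.0) ** 2
        lo, hi = self.background_hu_range
        if hi >= 130.0:
            raise ValueError("background tissue must stay strictly below 130 HU")
        if any(b[0] < 130.0 for b in DENSITY_BINS):
            raise AssertionError("density bins must start at >=130 HU")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm ** 2


@dataclass
class TruthLesion:
    slice_index: int
    artery: str
    area_mm2: float
    peak_hu: float
    density_weight: int


@dataclass
class PhantomCase:
    volume: CTVolume
    mask: AnnotationMask
    truth_lesions: list[TruthLesion]
    truth_agatston: float
    truth_risk: str
    seed: int = 0

    def __post_init__(self):
        expected = sum(l.area_mm2 * l.density_weight for l in self.truth_lesions)
        if abs(expected - self.truth_agatston) > 1e-9:
            raise ValueError("truth_agatston inconsistent with truth lesion list")


def _truth_risk(score: float) -> str:
    if score <= 10.0:
        return "low"
    if score <= 100.0:
        return "moderate"
    if score <= 400.0:
        return "high"
    return "very_high"


class _SliceBuilder:
    """Geometry helper shared by all slices of one patient."""

    def __init__(self, config: PhantomConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        n = config.image_size
        self.body_center = (n / 2.0, n / 2.0)
        self.body_axes = (0.42 * n, 0.36 * n)
        self.heart_center = (0.52 * n, 0.48 * n)
        self.heart_axes = (0.17 * n, 0.15 * n)
        yy, xx = np.mgrid[0:n, 0:n]
        self.body_mask = (((yy - self.body_center[0]) / self.body_axes[0]) ** 2
                          + ((xx - self.body_center[1]) / self.body_axes[1]) ** 2) <= 1.0
        # heart interior shrunk slightly so lesions stay clear of the border
        self.heart_mask = (((yy - self.heart_center[0]) / (self.heart_axes[0] - 1)) ** 2
                           + ((xx - self.heart_center[1]) / (self.heart_axes[1] - 1)) ** 2) <= 1.0
        # four artery quadrants around the heart center
        self.quadrants = {
            "RCA": (yy < self.heart_center[0]) & (xx < self.heart_center[1]),
            "LAD": (yy < self.heart_center[0]) & (xx >= self.heart_center[1]),
            "LCA": (yy >= self.heart_center[0]) & (xx < self.heart_center[1]),
            "LCX": (yy >= self.heart_center[0]) & (xx >= self.heart_center[1]),
        }

        # rib geometry is fixed per patient (anatomy persists across slices);
        # each slice adds only small positional jitter and intensity noise
        n = config.image_size
        self.n_ribs = int(rng.integers(6, 10))
        self.rib_angles = [2 * np.pi * (k + rng.uniform(-0.2, 0.2)) / self.n_ribs
                           for k in range(self.n_ribs)]
        self.rib_hu = [rng.uniform(700.0, 1200.0) for _ in range(self.n_ribs)]
        self.tissue_hu = rng.uniform(*config.background_hu_range)

    def background_slice(self) -> np.ndarray:
        cfg, rng, n = self.cfg, self.rng, self.cfg.image_size
        hu = np.full((n, n), -1000.0)
        tissue = self.tissue_hu + rng.normal(0.0, 6.0, size=(n, n))
        hu[self.body_mask] = np.clip(tissue, -80.0, 125.0)[self.body_mask]
        for ang0, rib_hu in zip(self.rib_angles, self.rib_hu):
            ang = ang0 + rng.normal(0.0, 0.02)
            ry = self.body_center[0] + 0.88 * self.body_axes[0] * np.sin(ang)
            rx = self.body_center[1] + 0.88 * self.body_axes[1] * np.cos(ang)
            rr, cc = draw_ellipse(ry, rx, max(1.5, 0.02 * n), max(1.5, 0.035 * n), shape=(n, n))
            keep = self.body_mask[rr, cc] & ~self.heart_mask[rr, cc]
            hu[rr[keep], cc[keep]] = rib_hu + rng.normal(0.0, 20.0, size=int(keep.sum()))
        return hu

    def place_lesion(self, hu: np.ndarray, labels: np.ndarray, occupied: np.ndarray,
                     artery: str, area_px: int, bin_index: int) -> dict | None:
        """Rasterize one compact lesion blob of exactly ``area_px`` pixels.

        The anchor is drawn from the artery's heart quadrant; the footprint
        may extend anywhere inside the heart region.  Returns bookkeeping or
        None if no admissible placement is found.
        """
        cfg, rng, n = self.cfg, self.rng, self.cfg.image_size
        region = self.heart_mask & self.quadrants[artery]
        cand_rows, cand_cols = np.nonzero(region)
        if cand_rows.size == 0:
            return None
        lo_hu, hi_hu, weight = DENSITY_BINS[bin_index]
        heart_rows, heart_cols = np.nonzero(self.heart_mask)
        for attempt in range(120):
            j = rng.integers(cand_rows.size)
            cy, cx = float(cand_rows[j]), float(cand_cols[j])
            # elliptical neighbourhood, trimmed to the exact pixel budget
            elong = rng.uniform(0.7, 1.4)
            rot = rng.uniform(0, np.pi)
            dy = heart_rows - cy
            dx = heart_cols - cx
            ry = dy * np.cos(rot) - dx * np.sin(rot)
            rx = dy * np.sin(rot) + dx * np.cos(rot)
            dist = (ry * elong) ** 2 + (rx / elong) ** 2
            order = np.argsort(dist, kind="stable")[:area_px]
            if order.size < area_px:
                continue
            rr, cc = heart_rows[order], heart_cols[order]
            footprint = np.zeros((n, n), dtype=bool)
            footprint[rr, cc] = True
            # one-pixel separation from previously placed lesions
            from scipy.ndimage import binary_dilation

            if np.any(binary_dilation(footprint, np.ones((3, 3))) & occupied):
                continue
            base = rng.uniform(lo_hu + 5.0, hi_hu - 5.0)
            vals = np.clip(base + rng.normal(0.0, 4.0, size=rr.size), lo_hu, hi_hu)
            hu[rr, cc] = vals
            labels[rr, cc] = ARTERY_NAMES.index(artery) + 1
            occupied |= footprint
            return {"n_px": int(rr.size), "peak_hu": float(vals.max()), "artery": artery,
                    "weight": int(weight)}
        return None


def _sample_lesion_area(cfg: PhantomConfig, rng: np.random.Generator) -> int:
    """Shifted-Poisson pixel count: 1 + Poisson(mean - 1), so the expected
    area equals the configured mean while the minimum stays one pixel."""
    mean = cfg.lesion_area_px_mean
    area = 1 + rng.poisson(max(mean - 1.0, 0.0))
    cap = max(2, int(0.01 * cfg.image_size ** 2))
    return int(np.clip(area, 1, cap))


def _finalize_case(cfg, volume_slices, label_slices, records, seed) -> PhantomCase:
    voxels = np.stack(volume_slices)
    labels = np.stack(label_slices)
    sp = cfg.pixel_spacing_mm
    lesions = []
    for rec in records:
        area_mm2 = rec["n_px"] * cfg.pixel_area_mm2
        if area_mm2 < 1.0:
            continue  # below the minimum-area rule; not scoreable, stays in the mask
        lesions.append(TruthLesion(slice_index=rec["slice"], artery=rec["artery"],
                                   area_mm2=area_mm2, peak_hu=rec["peak_hu"],
                                   density_weight=rec["weight"]))
    score = float(sum(l.area_mm2 * l.density_weight for l in lesions))
    volume = CTVolume(voxels=voxels, pixel_spacing=(sp, sp),
                      slice_thickness=cfg.slice_thickness_mm,
                      patient_id=f"pt{seed:06d}")
    return PhantomCase(volume=volume, mask=AnnotationMask(labels=labels),
                       truth_lesions=lesions, truth_agatston=score,
                       truth_risk=_truth_risk(score), seed=seed)


def generate_patient(config: PhantomConfig, seed: int) -> PhantomCase:
    """Generate one phantom patient; deterministic under (config, seed)."""
    rng = np.random.default_rng([config.seed, seed])
    builder = _SliceBuilder(config, rng)
    n_slices = config.slices_per_patient
    positive = rng.random(n_slices) < config.positive_slice_fraction
    vol, lab, records = [], [], []
    for s in range(n_slices):
        hu = builder.background_slice()
        labels = np.zeros_like(hu, dtype=np.uint8)
        if positive[s]:
            occupied = np.zeros_like(labels, dtype=bool)
            n_lesions = 1 + rng.poisson(max(config.lesions_per_positive_slice_mean - 1.0, 0.0))
            for _ in range(int(n_lesions)):
                artery = str(rng.choice(ARTERY_NAMES, p=np.asarray(config.artery_class_weights)
                                        / np.sum(config.artery_class_weights)))
                bin_index = int(rng.choice(4, p=np.asarray(config.lesion_hu_bin_weights)
                                           / np.sum(config.lesion_hu_bin_weights)))
                area = _sample_lesion_area(config, rng)
                rec = builder.place_lesion(hu, labels, occupied, artery, area, bin_index)
                if rec is None:
                    raise RuntimeError("could not place lesion inside the heart region; "
                                       "requested lesion area too large for the image size")
                rec["slice"] = s
                records.append(rec)
        vol.append(hu)
        lab.append(labels)
    return _finalize_case(config, vol, lab, records, seed)


def _generate_patient_with_target(config: PhantomConfig, seed: int,
                                  category: str) -> PhantomCase:
    """Generate a patient whose truth Agatston score lands in a risk range."""
    rng = np.random.default_rng([config.seed, seed, 1])
    builder = _SliceBuilder(config, rng)
    n_slices = config.slices_per_patient
    lo, hi = RISK_RANGES[category]
    px_area = config.pixel_area_mm2

    vol = [builder.background_slice() for _ in range(n_slices)]
    lab = [np.zeros((config.image_size,) * 2, dtype=np.uint8) for _ in range(n_slices)]
    occ = [np.zeros((config.image_size,) * 2, dtype=bool) for _ in range(n_slices)]
    records: list[dict] = []

    if category == "low":
        return _finalize_case(config, vol, lab, records, seed)

    # feasibility: the largest admissible score from the lesion budget
    cap_px = max(2, int(0.01 * config.image_size ** 2))
    max_score = config.max_lesions_per_patient * cap_px * px_area * 4
    if max_score < lo:
        raise ValueError(f"risk category {category!r} infeasible: lesion budget caps the "
                         f"score at {max_score:.1f} < {lo}")

    min_unit = max(px_area, 1.0)  # one D=1 pixel-lesion (and the 1 mm^2 floor)
    if min_unit > hi:
        raise ValueError(f"risk category {category!r} infeasible: smallest scoreable lesion "
                         f"adds {min_unit:.1f} > upper bound {hi}")

    n_pos = max(1, int(rng.binomial(n_slices, config.positive_slice_fraction)))
    pos_slices = list(rng.choice(n_slices, size=n_pos, replace=False))
    target = rng.uniform(lo, min(hi, lo * 2.5 if np.isfinite(hi) else lo * 2.5))
    score = 0.0
    k = 0
    while score < lo and len(records) < config.max_lesions_per_patient:
        remaining = hi - score
        # choose a lesion whose contribution cannot overshoot the range top
        for attempt in range(40):
            bin_index = int(rng.choice(4, p=np.asarray(config.lesion_hu_bin_weights)
                                       / np.sum(config.lesion_hu_bin_weights)))
            area_px = _sample_lesion_area(config, rng)
            weight = DENSITY_BINS[bin_index][2]
            contrib = area_px * px_area * weight
            if contrib <= remaining and area_px * px_area >= 1.0:
                break
            bin_index, area_px = 0, max(1, int(np.ceil(1.0 / px_area)))
            contrib = area_px * px_area * 1
            if contrib <= remaining:
                break
        else:
            break
        s = pos_slices[k % len(pos_slices)]
        rec = builder.place_lesion(vol[s], lab[s], occ[s],
                                   str(rng.choice(ARTERY_NAMES)), area_px, bin_index)
        if rec is None:
            # slice is crowded; open another positive slice
            free = [i for i in range(n_slices) if i not in pos_slices]
            if not free:
                break
            pos_slices.append(free[int(rng.integers(len(free)))])
            k += 1
            continue
        rec["slice"] = s
        if rec["n_px"] * px_area >= 1.0:
            score += rec["n_px"] * px_area * rec["weight"]
        records.append(rec)
        k += 1
        if score >= target:
            break
    if not (lo <= score <= hi):
        raise ValueError(f"could not reach risk category {category!r} "
                         f"(achieved score {score:.1f}, range [{lo}, {hi}])")
    return _finalize_case(config, vol, lab, records, seed)


def _counts_from_proportions(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n items."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = n * p
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_cohort(config: PhantomConfig, n_patients: int,
                    risk_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
                    seed: int = 0) -> list[PhantomCase]:
    """Generate a cohort whose realized risk categories match ``risk_mix`` exactly."""
    counts = _counts_from_proportions(n_patients, risk_mix)
    cases = []
    pid = 0
    for category, count in zip(RISK_CATEGORIES, counts):
        for _ in range(count):
            case = _generate_patient_with_target(config, seed * 100003 + pid, category)
            if case.truth_risk != category:
                raise AssertionError(
                    f"phantom bookkeeping produced {case.truth_risk}, wanted {category}")
            cases.append(case)
            pid += 1
    return cases


def stratified_split(cases: list[PhantomCase], fractions: tuple[float, float, float],
                     seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Split patient ids into train/val/test, stratified by risk category.

    Within each category the counts follow largest-remainder rounding of the
    fractions.  The result depends only on the set of patient ids and the
    seed, not on input order.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    import warnings

    by_cat: dict[str, list[str]] = {c: [] for c in RISK_CATEGORIES}
    for case in cases:
        by_cat[case.truth_risk].append(case.volume.patient_id)
    splits: tuple[list[str], ...] = ([], [], [])
    rng = np.random.default_rng(seed)
    for cat in RISK_CATEGORIES:
        ids = sorted(by_cat[cat])
        if not ids:
            continue
        n_parts = sum(1 for f in fractions if f > 0)
        if len(ids) < n_parts:
            warnings.warn(f"risk category {cat!r} has only {len(ids)} case(s) for "
                          f"{n_parts} split parts; assignment is degenerate")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        counts = _counts_from_proportions(len(ids), fractions)
        a, b = counts[0], counts[0] + counts[1]
        splits[0].extend(ids[:a])
        splits[1].extend(ids[a:b])
        splits[2].extend(ids[b:])
    return splits


def cohort_manifest(cases: list[PhantomCase],
                    split: tuple[list[str], list[str], list[str]] | None = None):
    """Cohort summary as a pandas DataFrame (patient, score, risk, split)."""
    import pandas as pd

    assignment = {}
    if split is not None:
        for name, ids in zip(("train", "val", "test"), split):
            for pid in ids:
                assignment[pid] = name
    rows = [{"patient_id": c.volume.patient_id, "truth_agatston": c.truth_agatston,
             "truth_risk": c.truth_risk, "n_lesions": len(c.truth_lesions),
             "split": assignment.get(c.volume.patient_id, "")} for c in cases]
    return pd.DataFrame(rows)
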