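"""Fluorescence-image quantification of expression pattern.

A GFP channel is segmented with two filters: a broad one (Gaussian smooth +
Otsu) giving the whole-cell mask, and a bright one (Gaussian smooth + in-cell
percentile threshold) giving candidate bright regions. Nuclei are selected
among bright connected components by area and roundness (4*pi*A / P^2). The
expression-pattern statistic is the Jaccard index of the nuclear mask against
the whole-cell mask: diffuse expression with nuclear enrichment yields a
sizeable nuclear mask (higher Jaccard), whereas punctate, nucleus-excluded
aggregation yields little or no accepted nuclear component (lower Jaccard).

Groups of per-image Jaccard values are compared with the two-sided,
equal-variance (pooled) Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import filters, measure

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "segment",
    "detect_nuclei",
    "jaccard",
    "JaccardRecord",
    "analyze_image",
    "compare_groups",
]


@dataclass(frozen=True)
class SegmentationConfig:
    sigma_cell: float = 4.0          # broad filter: whole-cell smoothing (px)
    sigma_nuclear: float = 2.0       # bright filter smoothing (px)
    bright_percentile: float = 90.0  # threshold percentile within the cell mask
    nucleus_area_range: tuple[float, float] = (80.0, 5000.0)  # px^2
    roundness_min: float = 0.6       # 4*pi*A/P^2; 1 = perfect disk

    def __post_init__(self):
        if not 0.0 < self.bright_percentile < 100.0:
            raise ValueError("bright_percentile must be in (0, 100)")
        lo, hi = self.nucleus_area_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid nucleus_area_range")


@dataclass
class SegmentationResult:
    cell_mask: np.ndarray
    bright_mask: np.ndarray
    nuclear_mask: np.ndarray | None = None
    nuclei: list[dict] = field(default_factory=list)


def segment(image: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()
            ) -> SegmentationResult:
    """Two-filter segmentation into whole-cell and bright binary masks."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("intensities must be finite and non-negative")
    if img.std() == 0:
        raise ValueError("no foreground: image has zero variance")

    smooth_cell = filters.gaussian(img, sigma=cfg.sigma_cell, preserve_range=True)
    cell_mask = smooth_cell > filters.threshold_otsu(smooth_cell)
    if not cell_mask.any():
        raise ValueError("no foreground: empty cell mask")

    smooth_nuc = filters.gaussian(img, sigma=cfg.sigma_nuclear, preserve_range=True)
    thr = np.percentile(smooth_nuc[cell_mask], cfg.bright_percentile)
    bright_mask = (smooth_nuc >= thr) & cell_mask
    return SegmentationResult(cell_mask=cell_mask, bright_mask=bright_mask)


def _roundness(region) -> float:
    p = region.perimeter
    if p == 0:
        return 1.0  # single-pixel / degenerate component: treat as round
    return 4.0 * np.pi * region.area / (p * p)


def detect_nuclei(result: SegmentationResult,
                  area_range: tuple[float, float] = SegmentationConfig().nucleus_area_range,
                  roundness_min: float = SegmentationConfig().roundness_min
                  ) -> np.ndarray:
    """Select nuclear components of the bright mask by size and roundness.

    Fills ``result.nuclear_mask`` and ``result.nuclei`` and returns the mask
    (possibly empty; punctate aggregates typically fail both rules).
    """
    lo, hi = area_range
    labels = measure.label(result.bright_mask, connectivity=2)
    nuclear = np.zeros_like(result.bright_mask, dtype=bool)
    kept = []
    for region in measure.regionprops(labels):
        r = _roundness(region)
        if lo <= region.area <= hi and r >= roundness_min:
            nuclear[labels == region.label] = True
            kept.append({"label": region.label, "area": int(region.area),
                         "roundness": float(r)})
    result.nuclear_mask = nuclear
    result.nuclei = kept
    return nuclear


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|a & b| / |a | b| for binary masks; 0 when the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class JaccardRecord:
    cell_id: str
    jaccard: float
    group: str            # "WT" or "variant"
    construct: str = ""   # e.g. "Ig-54 Q7023P"

    def __post_init__(self):
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError(f"Jaccard out of [0,1]: {self.jaccard}")


def analyze_image(image: np.ndarray, cfg: SegmentationConfig = SegmentationConfig(),
                  *, cell_id: str = "", group: str = "WT", construct: str = ""
                  ) -> JaccardRecord:
    """Full per-image pipeline: segment, detect nuclei, score nuclear overlap."""
    res = segment(image, cfg)
    detect_nuclei(res, cfg.nucleus_area_range, cfg.roundness_min)
    j = jaccard(res.nuclear_mask, res.cell_mask)
    return JaccardRecord(cell_id=cell_id, jaccard=j, group=group, construct=construct)


def compare_groups(wt: list[JaccardRecord], var: list[JaccardRecord]
                   ) -> dict[str, float]:
    """Two-sided pooled-variance Student's t-test between Jaccard groups."""
    if len(wt) < 2 or len(var) < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    x = np.array([r.jaccard for r in wt])
    y = np.array([r.jaccard for r in var])
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {"t": float(t), "p": float(p),
            "mean_wt": float(x.mean()), "mean_variant": float(y.mean()),
            "n_wt": len(x), "n_variant": len(y)}
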