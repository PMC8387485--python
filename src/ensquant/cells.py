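"""Automated soma counting: threshold, components, size/circularity filter.

Mirrors a threshold-plus-"Analyze Particles" workflow: Otsu auto-threshold,
8-connected components, particle areas in um^2, circularity
4*pi*area/perimeter^2 (Crofton perimeter, clamped to [0, 1]), then a size
and circularity filter — by default 10 um^2 to infinity and 0.00-1.00.
Touching somata are not split; counts are averaged per subject so the
animal, not the field, is the unit of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .segment import auto_threshold

__all__ = ["ParticleFilter", "count_somata", "average_counts"]


@dataclass(frozen=True)
class ParticleFilter:
    """Size (um^2) and circularity window for accepted particles."""

    min_area_um2: float = 10.0
    max_area_um2: float = float("inf")
    circularity_min: float = 0.0
    circularity_max: float = 1.0

    def __post_init__(self):
        if self.min_area_um2 > self.max_area_um2:
            raise ValueError("min_area_um2 must be <= max_area_um2")
        if not 0.0 <= self.circularity_min <= self.circularity_max <= 1.0:
            raise ValueError("circularity window must satisfy 0 <= min <= max <= 1")


def count_somata(
    image: np.ndarray,
    pixel_size_um: float,
    particle_filter: ParticleFilter = ParticleFilter(),
    threshold_method: str = "otsu",
    split_touching: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Count soma-like particles in a calibrated 2D image.

    Returns the accepted-particle count and a per-particle table (area in
    um^2, circularity, centroid).  ``split_touching`` enables an optional
    distance-transform watershed; off by default since the standard
    workflow does not separate touching somata.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("count_somata expects a 2D image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = auto_threshold(image, method=threshold_method)
    if split_touching:
        dist = ndimage.distance_transform_edt(mask)
        markers, _ = ndimage.label(
            dist > 0.5 * dist.max(), structure=np.ones((3, 3), bool)
        )
        labels = watershed(-dist, markers, mask=mask)
    else:
        labels = cc_label(mask, connectivity=2)
    px2 = pixel_size_um**2
    rows = []
    for rp in regionprops(labels):
        area_um2 = rp.area * px2
        perim = rp.perimeter_crofton
        circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 1.0
        circ = float(np.clip(circ, 0.0, 1.0))
        keep = (
            particle_filter.min_area_um2 <= area_um2 <= particle_filter.max_area_um2
            and particle_filter.circularity_min <= circ <= particle_filter.circularity_max
        )
        if keep:
            rows.append(
                {
                    "label": rp.label,
                    "area_um2": float(area_um2),
                    "area_px": int(rp.area),
                    "circularity": circ,
                    "centroid_row": float(rp.centroid[0]),
                    "centroid_col": float(rp.centroid[1]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["label", "area_um2", "area_px", "circularity", "centroid_row", "centroid_col"],
    )
    return len(rows), table


def average_counts(per_field: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject mean counts and group summaries (mean, sem over subjects).

    ``per_field`` needs columns ``group``, ``subject``, ``count`` — one row
    per analysed field.  The subject mean is the arithmetic mean of its
    fields; group statistics are computed over subject means, so the
    subject is the statistical unit.
    """
    required = {"group", "subject", "count"}
    if not required.issubset(per_field.columns):
        raise ValueError(f"per_field must have columns {sorted(required)}")
    if per_field.empty:
        raise ValueError("no field counts supplied")
    subj = (
        per_field.groupby(["group", "subject"], sort=True)["count"]
        .mean()
        .rename("subject_mean")
        .reset_index()
    )
    group = (
        subj.groupby("group", sort=True)["subject_mean"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return subj, group
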