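"""Network density and the binned interganglionic ("negative-space") census.

Interganglionic areas are the connected components of the background of a
segmented network mask — a proxy for the space between ganglia.  Areas are
binned into seven size classes (px^2): 0-50, 51-200, 201-400, 401-600,
601-800, 801-1000, >1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AreaBinScheme",
    "DEFAULT_BINS",
    "network_density",
    "interganglionic_areas",
    "bin_areas",
]


@dataclass(frozen=True)
class AreaBinScheme:
    """Integer-inclusive upper edges of the area bins, plus an open top bin."""

    upper_edges: tuple[int, ...] = (50, 200, 400, 600, 800, 1000)
    labels: tuple[str, ...] = (
        "very_small_0_50",
        "small_51_200",
        "small_201_400",
        "medium_401_600",
        "medium_601_800",
        "large_801_1000",
        "large_gt_1000",
    )

    def __post_init__(self):
        edges = self.upper_edges
        if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(edges) + 1:
            raise ValueError("need one label per bin (edges + open top bin)")

    @property
    def n_bins(self) -> int:
        return len(self.upper_edges) + 1


DEFAULT_BINS = AreaBinScheme()


def network_density(mask: np.ndarray) -> float:
    """Percent of the field covered by network foreground."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    return 100.0 * float(mask.mean())


def interganglionic_areas(
    mask: np.ndarray, connectivity: int = 1, include_border: bool = True
) -> list[int]:
    """Areas (px^2) of background connected components, centroid-ordered.

    Background uses 4-connectivity by default (the dual of 8-connected
    foreground).  Components touching the image border are included unless
    ``include_border`` is False.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(~mask, structure=structure)
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int)
    if not include_border:
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        drop = set(border[border > 0])
    else:
        drop = set()
    centroids = ndimage.center_of_mass(~mask, labels, ids)
    order = sorted(range(n), key=lambda i: centroids[i])
    return [int(areas[i]) for i in order if ids[i] not in drop]


def bin_areas(areas, scheme: AreaBinScheme = DEFAULT_BINS) -> np.ndarray:
    """Count areas per size bin; counts always sum to ``len(areas)``."""
    areas = np.asarray(list(areas), dtype=np.int64)
    if areas.size and areas.min() < 0:
        raise ValueError("areas must be non-negative integers")
    counts = np.zeros(scheme.n_bins, dtype=np.int64)
    if areas.size:
        idx = np.searchsorted(np.asarray(scheme.upper_edges), areas, side="left")
        counts += np.bincount(idx, minlength=scheme.n_bins)
    return counts
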